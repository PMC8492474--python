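#!/usr/bin/env python
"""Generate the demo cohort: a synthetic reference, two polymerase-mutant
patients with crypt phylogenies, and read-level variant tables.

Writes FASTA/BED reference files, per-patient VCFs, and the truth table to
results/cohort/.  Rates are scaled to the demo genome (see docs/methods.md);
downstream scripts (02-04) consume these outputs.
"""

import os

from polclock import io, simulate as sim
from polclock.reference import build_reference

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "cohort")
SEED = 11


def main():
    io.ensure_dir(OUT)
    ref = build_reference(SEED, {"chr1": 400_000}, n_genes=40)
    io.write_fasta(ref.chromosomes, os.path.join(OUT, "reference.fa"))
    io.write_bed([(g.chrom, s, e, g.name, g.strand, g.role)
                  for g in ref.genes for s, e in g.cds],
                 os.path.join(OUT, "genes.bed"))
    io.write_bed(ref.replication, os.path.join(OUT, "replication.bed"))

    cfg = sim.CohortConfig(
        patients=[
            sim.PatientConfig("P1", 45.0, "POLE_L424V", n_crypts=6),
            sim.PatientConfig("P2", 55.0, "POLD1_S478N", n_crypts=6),
        ],
        sbs_rate={g: r / 10 for g, r in sim.SBS_RATE.items()},
        id_rate={g: max(r / 10, 0.1) for g, r in sim.ID_RATE.items()},
        germline_het=300, germline_hom=100, seed=SEED)
    truth = sim.simulate_cohort(ref, cfg)
    truth.mutations.to_csv(os.path.join(OUT, "truth_mutations.tsv"),
                           sep="\t", index=False)
    for i, p in enumerate(cfg.patients):
        vt = sim.simulate_reads(truth, p.id, coverage_mean=30,
                                seed=SEED + 100 * (i + 1), ref=ref)
        vt.to_csv(os.path.join(OUT, f"{p.id}.variants.tsv"), sep="\t",
                  index=False)
        io.write_variant_vcf(vt, truth.samples[p.id],
                             os.path.join(OUT, f"{p.id}.variants.vcf"),
                             contigs={c: len(s) for c, s in
                                      ref.chromosomes.items()})
        print(f"{p.id}: {len(vt)} variant records "
              f"({(vt['truth'] == 'somatic').sum()} somatic, "
              f"{(vt['truth'] == 'germline').sum()} germline)")


if __name__ == "__main__":
    main()
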