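"""End-to-end orchestration: simulate -> filter -> tree -> signatures ->
rates, with a machine-readable report.

A single seed fans out to per-stage seeds (stage-name hashed) so stages are
independently reproducible.  Stage outputs are written as the declared file
formats; the report JSON aggregates per-stage counts and headline estimates
and is byte-identical across re-runs with the same config.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import filtering, io, phylogeny, rates, refsigs, signatures, simulate
from .reference import build_reference
from .signatures import SignatureModel

KNOWN_KEYS = {
    "seed", "out_dir", "genome", "cohort", "stages", "coverage_mean",
    "n_bootstrap",
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "polclock_run"
    genome: dict = field(default_factory=lambda: {
        "chrom_sizes": {"chr1": 300_000}, "n_genes": 20})
    #: the bundled demo cohort runs on a small genome, so demo rates are
    #: scaled well below the study conditions to avoid saturating it
    cohort: dict = field(default_factory=lambda: {
        "patients": [
            {"id": "P1", "age": 40.0, "genotype": "POLE_L424V", "n_crypts": 4},
            {"id": "P2", "age": 55.0, "genotype": "POLD1_S478N", "n_crypts": 4},
        ],
        "sbs_rate": {g: r / 20 for g, r in simulate.SBS_RATE.items()},
        "id_rate": {g: max(r / 20, 0.1) for g, r in simulate.ID_RATE.items()},
    })
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "filter", "tree", "signatures", "rates"])
    coverage_mean: float = 30.0
    n_bootstrap: int = 50

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


STAGE_ORDER = ["simulate", "filter", "tree", "signatures", "rates"]
STAGE_DEPS = {
    "filter": ["simulate"],
    "tree": ["filter"],
    "signatures": ["tree"],
    "rates": ["filter"],
}


def stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    for s in config.stages:
        for dep in STAGE_DEPS.get(s, []):
            if dep not in config.stages:
                raise ValueError(f"stage '{s}' requires '{dep}'")
    out = io.ensure_dir(config.out_dir)
    report: dict = {"schema_version": 1, "seed": config.seed, "stages": {}}

    rate_cv = config.cohort.get("rate_cv", 0.10)
    patients = [simulate.PatientConfig(**p) for p in config.cohort["patients"]]
    ref = build_reference(stage_seed(config.seed, "reference"),
                          dict(config.genome["chrom_sizes"]),
                          n_genes=config.genome.get("n_genes", 0))
    truth = None
    tables = {}
    kept = {}
    phylos = {}

    for stage in [s for s in STAGE_ORDER if s in config.stages]:
        t0 = time.time()
        if stage == "simulate":
            cfg = simulate.CohortConfig(
                patients=patients, rate_cv=rate_cv,
                coverage_mean=config.coverage_mean,
                sbs_rate={**simulate.SBS_RATE,
                          **config.cohort.get("sbs_rate", {})},
                id_rate={**simulate.ID_RATE,
                         **config.cohort.get("id_rate", {})},
                seed=stage_seed(config.seed, "simulate"))
            truth = simulate.simulate_cohort(ref, cfg)
            for p in patients:
                tables[p.id] = simulate.simulate_reads(
                    truth, p.id, coverage_mean=config.coverage_mean,
                    seed=stage_seed(config.seed, f"reads:{p.id}"), ref=ref)
                io.write_variant_vcf(
                    tables[p.id], truth.samples[p.id],
                    os.path.join(out, f"{p.id}.variants.vcf"),
                    contigs={c: len(s) for c, s in ref.chromosomes.items()})
            report["stages"]["simulate"] = {
                "n_mutations": int(len(truth.mutations)),
                "n_germline": int(len(truth.germline)),
            }
        elif stage == "filter":
            n_kept = {}
            for p in patients:
                k, rep = filtering.filter_chain(tables[p.id], truth.samples[p.id])
                kept[p.id] = k
                rep.to_csv(os.path.join(out, f"{p.id}.filter_report.tsv"),
                           sep="\t", index=False)
                n_kept[p.id] = int(len(k))
            report["stages"]["filter"] = {"retained": n_kept}
        elif stage == "tree":
            for p in patients:
                somatic = kept[p.id]
                geno = pd.DataFrame({
                    s: (somatic[f"NV_{s}"] / somatic[f"NR_{s}"].clip(lower=1) > 0.2)
                    .astype(int)
                    for s in truth.samples[p.id]}).T
                phylo = phylogeny.build_tree(
                    geno, n_bootstrap=config.n_bootstrap,
                    seed=stage_seed(config.seed, f"tree:{p.id}"))
                phylo = phylogeny.assign_mutations(phylo, somatic)
                phylos[p.id] = phylo
                lengths = phylo.branch_counts["SBS"].to_dict()
                io.write_newick(phylo.tree,
                                os.path.join(out, f"{p.id}.tree.nwk"), lengths)
            report["stages"]["tree"] = {
                p.id: int(phylos[p.id].parsimony_score) for p in patients}
        elif stage == "signatures":
            sigs = refsigs.synthetic_sbs_signatures()
            model = SignatureModel(sigs, {c: "reference" for c in sigs.columns})
            summaries = {}
            for p in patients:
                cats = signatures.build_catalogs(phylos[p.id], kept[p.id], ref)
                allowed = list(simulate.SIG_WEIGHTS[p.genotype])
                exp = signatures.fit_exposures(cats, model, allowed=allowed)
                exp.to_csv(os.path.join(out, f"{p.id}.exposures.tsv"), sep="\t")
                tot = exp[allowed].sum()
                summaries[p.id] = (tot / max(tot.sum(), 1)).round(4).to_dict()
            report["stages"]["signatures"] = summaries
        elif stage == "rates":
            burdens = []
            for p in patients:
                for s in truth.samples[p.id]:
                    n = int(((kept[p.id][f"NV_{s}"] > 0) &
                             (kept[p.id]["vclass"] == "SBS")).sum())
                    burdens.append(dict(sample=s, patient=p.id, age=p.age,
                                        genotype=p.genotype, burden=n))
            bdf = pd.DataFrame(burdens)
            bdf.to_csv(os.path.join(out, "burdens.tsv"), sep="\t", index=False)
            fits = {}
            for geno, sub in bdf.groupby("genotype"):
                if sub["patient"].nunique() >= 2 and sub["age"].nunique() >= 2:
                    f = rates.fit_rate_lme(sub)
                    fits[geno] = {"slope": round(f.slope, 3),
                                  "ci": [round(f.ci_low, 3), round(f.ci_high, 3)]}
            report["stages"]["rates"] = fits
        # timing is logged, not reported, so the report stays byte-identical
        print(f"[polclock] stage {stage}: {time.time() - t0:.1f}s")

    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
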