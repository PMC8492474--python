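#!/usr/bin/env python
"""Per-branch signature catalogs and constrained exposure refits for the
demo cohort; POLE branches should load on SBS10a/SBS10b/SBS28 and POLD1
branches on SBS10c over the SBS1/SBS5 clock.

Reads 01-03 outputs; writes exposures per patient.
"""

import os

import pandas as pd

from polclock import io, phylogeny, refsigs, signatures
from polclock.reference import build_reference
from polclock.signatures import SignatureModel
from polclock.simulate import SIG_WEIGHTS

BASE = os.path.join(os.path.dirname(__file__), "..", "results", "cohort")
GENOTYPE = {"P1": "POLE_L424V", "P2": "POLD1_S478N"}


def main():
    ref = build_reference(11, {"chr1": 400_000}, n_genes=40)
    profiles = refsigs.synthetic_sbs_signatures()
    model = SignatureModel(profiles, {c: "reference" for c in profiles})
    for pid in ("P1", "P2"):
        vt = pd.read_csv(os.path.join(BASE, f"{pid}.somatic.tsv"), sep="\t")
        samples = sorted(c[3:] for c in vt.columns if c.startswith("NV_"))
        geno = pd.DataFrame({
            s: ((vt[f"NV_{s}"] / vt[f"NR_{s}"].clip(lower=1)) > 0.2).astype(int)
            for s in samples}).T
        phylo = phylogeny.build_tree(geno, n_bootstrap=0, seed=17)
        phylo = phylogeny.assign_mutations(phylo, vt)
        cats = signatures.build_catalogs(phylo, vt, ref)
        allowed = list(SIG_WEIGHTS[GENOTYPE[pid]])
        exp = signatures.fit_exposures(cats, model, allowed=allowed)
        exp.to_csv(os.path.join(BASE, f"{pid}.exposures.tsv"), sep="\t",
                   index_label="branch")
        tot = exp[allowed].sum()
        frac = (tot / tot.sum()).round(3)
        print(f"{pid} ({GENOTYPE[pid]}): exposure fractions "
              f"{frac.to_dict()}")


if __name__ == "__main__":
    main()
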