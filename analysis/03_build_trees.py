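#!/usr/bin/env python
"""Reconstruct each patient's crypt phylogeny by maximum parsimony and map
the filtered somatic mutations onto branches.

Reads the filtered tables from 02; writes Newick trees (branch lengths =
SBS counts, labels = bootstrap support) and per-branch counts.
"""

import os

import pandas as pd

from polclock import io, phylogeny

BASE = os.path.join(os.path.dirname(__file__), "..", "results", "cohort")


def main():
    for pid in ("P1", "P2"):
        vt = pd.read_csv(os.path.join(BASE, f"{pid}.somatic.tsv"), sep="\t")
        samples = sorted(c[3:] for c in vt.columns if c.startswith("NV_"))
        geno = pd.DataFrame({
            s: ((vt[f"NV_{s}"] / vt[f"NR_{s}"].clip(lower=1)) > 0.2).astype(int)
            for s in samples}).T
        phylo = phylogeny.build_tree(geno, n_bootstrap=100, seed=17)
        phylo = phylogeny.assign_mutations(phylo, vt)
        lengths = phylo.branch_counts["SBS"].to_dict()
        io.write_newick(phylo.tree, os.path.join(BASE, f"{pid}.tree.nwk"),
                        lengths)
        phylo.branch_counts.to_csv(
            os.path.join(BASE, f"{pid}.branch_counts.tsv"), sep="\t",
            index_label="branch")
        print(f"{pid}: parsimony score {phylo.parsimony_score}, "
              f"{len(phylo.unassigned)} unassigned; "
              f"tree {phylo.tree.newick()}")


if __name__ == "__main__":
    main()
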