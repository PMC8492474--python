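"""Readers/writers for the interchange formats between pipeline stages.

Variant tables travel as VCF v4.2 (NV/NR FORMAT fields) with a TSV mirror;
references as FASTA + BED annotation; trees as Newick (branch lengths = SBS
counts, internal labels = bootstrap support); catalogs, signatures and
exposures as label-keyed TSV.  write -> read is the identity on the domain
objects.
"""

from __future__ import annotations

import os

import dendropy
import numpy as np
import pandas as pd

from .phylogeny import Node
from .reference import ReferenceModel


def write_fasta(chromosomes: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_bed(intervals, path: str) -> None:
    """Intervals as (chrom, start, end, name[, ...]) rows, 0-based half-open."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_variant_vcf(df: pd.DataFrame, samples: list[str], path: str,
                      contigs: dict[str, int] | None = None) -> None:
    """VCF v4.2 with per-sample NV (variant reads) and NR (total reads)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, n in (contigs or {}).items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write('##FORMAT=<ID=NV,Number=1,Type=Integer,Description="Variant reads">\n')
        fh.write('##FORMAT=<ID=NR,Number=1,Type=Integer,Description="Total reads">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="SBS or ID">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for _, r in df.iterrows():
            cells = [str(r["chrom"]), str(int(r["pos"]) + 1),
                     str(r.get("mut_id", ".")) or ".", r["ref"], r["alt"],
                     ".", "PASS", f"CLASS={r['vclass']}", "NV:NR"]
            for s in samples:
                cells.append(f"{int(r[f'NV_{s}'])}:{int(r[f'NR_{s}'])}")
            fh.write("\t".join(cells) + "\n")


def read_variant_vcf(path: str) -> pd.DataFrame:
    """Parse a variant VCF back to the wide table (0-based positions)."""
    import pysam

    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    rows = []
    for rec in vf:
        row = dict(chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref,
                   alt=rec.alts[0], vclass=rec.info.get("CLASS", "SBS"),
                   mut_id=rec.id or "")
        for s in samples:
            row[f"NV_{s}"] = rec.samples[s]["NV"]
            row[f"NR_{s}"] = rec.samples[s]["NR"]
        rows.append(row)
    return pd.DataFrame(rows)


def write_newick(tree: Node, path: str,
                 branch_lengths: dict[str, float] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(branch_lengths) + "\n")


def read_newick(path: str) -> Node:
    dt = dendropy.Tree.get(path=path, schema="newick")

    def conv(dn) -> Node:
        if dn.is_leaf():
            return Node(name=dn.taxon.label.replace(" ", "_") if dn.taxon else None)
        node = Node(children=[conv(c) for c in dn.child_nodes()])
        if dn.label is not None:
            try:
                node.support = float(dn.label)
            except ValueError:
                pass
        return node

    return conv(dt.seed_node)


def write_catalog_tsv(catalogs: pd.DataFrame, path: str) -> None:
    catalogs.to_csv(path, sep="\t", index_label="unit")


def read_catalog_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="unit")


def write_trinuc_tsv(t: np.ndarray, path: str) -> None:
    from .reference import TRINUC_32

    pd.Series(t, index=list(TRINUC_32), name="count").to_csv(
        path, sep="\t", index_label="trinucleotide")


def read_trinuc_tsv(path: str) -> np.ndarray:
    from .reference import TRINUC_32

    s = pd.read_csv(path, sep="\t", index_col="trinucleotide")["count"]
    return s.reindex(list(TRINUC_32)).to_numpy(dtype=float)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
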