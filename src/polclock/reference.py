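"""Synthetic reference genomes with gene and replication-strand annotation.

The analyses downstream (signature catalogs, duplex-burden correction,
context-corrected selection) all key on pyrimidine-centred trinucleotide
contexts.  This module owns those conventions: the 32 trinucleotide contexts,
the 96 substitution channels in COSMIC-style ordering, and reverse-complement
collapse onto the pyrimidine-centred strand.

Coordinates are 0-based half-open internally; VCF output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 32 pyrimidine-centred trinucleotides: 16 with central C, then 16 with
#: central T, flanks in lexicographic order (ACA, ACC, ... TTT).
TRINUC_32 = tuple(
    f"{five}{center}{three}"
    for center in "CT"
    for five in BASES
    for three in BASES
)
TRINUC_INDEX = {t: i for i, t in enumerate(TRINUC_32)}

#: 96 SBS channels, substitution-major (C>A x 16 flanks, C>G x 16, ...).
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_context(trinuc: str) -> str:
    """Map a trinucleotide onto its pyrimidine-centred representative."""
    if trinuc[1] in "CT":
        return trinuc
    return revcomp(trinuc)


def sbs_channel(trinuc: str, alt: str) -> str:
    """96-channel label for a substitution ``trinuc[1] -> alt``.

    Purine-centred contexts are collapsed by reverse complement, so e.g.
    G>A at CGT and C>T at ACG land on the same channel A[C>T]G.
    """
    if trinuc[1] not in "CT":
        trinuc = revcomp(trinuc)
        alt = COMPLEMENT[alt]
    return f"{trinuc[0]}[{trinuc[1]}>{alt}]{trinuc[2]}"


def channel_context(channel: str) -> str:
    """Trinucleotide context of a 96-channel label ('A[C>T]G' -> 'ACG')."""
    return channel[0] + channel[2] + channel[6]


def channel_alt(channel: str) -> str:
    return channel[4]


_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i

# 64 -> 32 collapse lookup: index of pyrimidine-centred representative.
_COLLAPSE64 = np.empty(64, dtype=np.int64)
for _a in range(4):
    for _b in range(4):
        for _c in range(4):
            t = BASES[_a] + BASES[_b] + BASES[_c]
            _COLLAPSE64[16 * _a + 4 * _b + _c] = TRINUC_INDEX[collapse_context(t)]


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)


def trinuc_counts(seq: str) -> np.ndarray:
    """32-vector of pyrimidine-collapsed trinucleotide counts of ``seq``."""
    a = encode(seq)
    if a.size < 3:
        return np.zeros(32, dtype=np.int64)
    idx64 = 16 * a[:-2] + 4 * a[1:-1] + a[2:]
    return np.bincount(_COLLAPSE64[idx64], minlength=32)


@dataclass
class Gene:
    """A protein-coding gene model on the synthetic reference.

    ``cds`` is a list of 0-based half-open intervals on one chromosome whose
    total length is a multiple of 3; ``role`` mirrors the dominant/recessive/
    intermediate behaviour classes used by the driver-annotation rules.
    """

    name: str
    chrom: str
    cds: list[tuple[int, int]]
    strand: str = "+"
    role: str = "recessive"
    panel: str = "colorectal-90"

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def coding_sequence(self, chromosomes: dict[str, str]) -> str:
        seq = "".join(chromosomes[self.chrom][s:e] for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class ReferenceModel:
    chromosomes: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    replication: list[tuple[str, int, int, str]] = field(default_factory=list)
    trinuc_genome: np.ndarray = field(default_factory=lambda: np.zeros(32, dtype=np.int64))
    trinuc_exome: np.ndarray = field(default_factory=lambda: np.zeros(32, dtype=np.int64))
    _context_sites: dict | None = field(default=None, repr=False)
    _coding_mask: dict | None = field(default=None, repr=False)

    def base(self, chrom: str, pos: int) -> str:
        return self.chromosomes[chrom][pos]

    def trinuc(self, chrom: str, pos: int) -> str:
        """Reference trinucleotide centred on ``pos`` (0-based)."""
        return self.chromosomes[chrom][pos - 1 : pos + 2]

    def context_sites(self) -> dict[int, list[tuple[str, int]]]:
        """Positions of every internal site, grouped by collapsed context."""
        if self._context_sites is None:
            sites: dict[int, list] = {i: [] for i in range(32)}
            for chrom, seq in self.chromosomes.items():
                a = encode(seq)
                idx64 = 16 * a[:-2] + 4 * a[1:-1] + a[2:]
                ctx = _COLLAPSE64[idx64]
                for i in range(32):
                    pos = np.nonzero(ctx == i)[0] + 1
                    sites[i].extend((chrom, int(p)) for p in pos)
            self._context_sites = sites
        return self._context_sites

    def coding_mask(self) -> dict[str, np.ndarray]:
        if self._coding_mask is None:
            masks = {c: np.zeros(len(s), dtype=bool) for c, s in self.chromosomes.items()}
            for g in self.genes:
                for s, e in g.cds:
                    masks[g.chrom][s:e] = True
            self._coding_mask = masks
        return self._coding_mask

    def is_coding(self, chrom: str, pos: int) -> bool:
        return bool(self.coding_mask()[chrom][pos])

    def replication_strand(self, chrom: str, pos: int) -> str | None:
        for c, s, e, label in self.replication:
            if c == chrom and s <= pos < e:
                return label
        return None

    def t_homopolymer_runs(self, min_len: int = 1) -> list[tuple[str, int, int]]:
        """Maximal runs of reference T of length >= min_len (chrom, start, end)."""
        runs = []
        for chrom, seq in self.chromosomes.items():
            a = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T")
            if not a.any():
                continue
            d = np.diff(a.astype(np.int8))
            starts = list(np.nonzero(d == 1)[0] + 1)
            ends = list(np.nonzero(d == -1)[0] + 1)
            if a[0]:
                starts.insert(0, 0)
            if a[-1]:
                ends.append(len(a))
            for s, e in zip(starts, ends):
                if e - s >= min_len:
                    runs.append((chrom, int(s), int(e)))
        return runs


class ReferenceSizingError(ValueError):
    """Requested gene complement does not fit on the chromosomes."""


def build_reference(
    seed: int,
    chrom_sizes: dict[str, int],
    n_genes: int = 0,
    gc_bias: float = 0.0,
    gene_length_range: tuple[int, int] = (300, 1500),
    replication_segment: int = 50_000,
    codon_usage_sd: float = 0.8,
) -> ReferenceModel:
    """Generate a random reference genome with gene models.

    Genes are single-CDS, non-overlapping, with lengths that are multiples
    of 3 drawn from ``gene_length_range``.  Replication-strand annotation
    alternates leading/lagging in fixed-size segments, emulating replicons
    with alternating fork direction.  Deterministic for a fixed seed.
    """
    for c, n in chrom_sizes.items():
        if n < 10_000:
            raise ReferenceSizingError(f"chromosome {c} shorter than 10 kb")
    rng = np.random.default_rng(seed)
    p_gc = min(max(0.4 + gc_bias, 0.05), 0.95)
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    chrom_arrays = {
        c: np.array(list(BASES))[rng.choice(4, size=n, p=probs)]
        for c, n in chrom_sizes.items()
    }

    genes: list[Gene] = []
    if n_genes:
        chrom_names = list(chrom_sizes)
        weights = np.array([chrom_sizes[c] for c in chrom_names], dtype=float)
        weights /= weights.sum()
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
        roles = ["recessive", "dominant", "intermediate"]
        for i in range(n_genes):
            length = 3 * int(rng.integers(gene_length_range[0] // 3, gene_length_range[1] // 3 + 1))
            placed = False
            for _ in range(200):
                chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
                start = int(rng.integers(2, chrom_sizes[chrom] - length - 2))
                end = start + length
                if all(e <= start or s >= end for s, e in occupied[chrom]):
                    occupied[chrom].append((start, end))
                    genes.append(
                        Gene(
                            name=f"G{i:04d}",
                            chrom=chrom,
                            cds=[(start, end)],
                            strand="+" if rng.random() < 0.5 else "-",
                            role=roles[rng.choice(3, p=[0.5, 0.35, 0.15])],
                        )
                    )
                    placed = True
                    break
            if not placed:
                raise ReferenceSizingError(
                    f"could not place gene {i} of {n_genes}: chromosomes too crowded"
                )
        # genes are open reading frames: overwrite each CDS with stop-free
        # codons (on the coding strand) so nonsense classes are meaningful.
        # Per-gene codon-usage bias (lognormal codon weights) gives genes
        # heterogeneous trinucleotide composition, as in real genomes.
        stops = {"TAA", "TAG", "TGA"}
        sense_codons = [a + b + c for a in BASES for b in BASES for c in BASES
                        if a + b + c not in stops]
        for g in genes:
            s, e = g.cds[0]
            usage = np.exp(rng.normal(0.0, codon_usage_sd, len(sense_codons)))
            usage /= usage.sum()
            codons = rng.choice(len(sense_codons), size=(e - s) // 3, p=usage)
            orf = "".join(sense_codons[i] for i in codons)
            if g.strand == "-":
                orf = revcomp(orf)
            chrom_arrays[g.chrom][s:e] = list(orf)

    chromosomes = {c: "".join(a) for c, a in chrom_arrays.items()}

    replication = []
    for c, n in chrom_sizes.items():
        label = "leading"
        for s in range(0, n, replication_segment):
            replication.append((c, s, min(s + replication_segment, n), label))
            label = "lagging" if label == "leading" else "leading"

    trinuc_genome = sum(
        (trinuc_counts(seq) for seq in chromosomes.values()),
        np.zeros(32, dtype=np.int64),
    )
    trinuc_exome = np.zeros(32, dtype=np.int64)
    for g in genes:
        for s, e in g.cds:
            # include one flanking base for context of terminal CDS bases
            seq = chromosomes[g.chrom][max(s - 1, 0) : e + 1]
            trinuc_exome += trinuc_counts(seq)

    return ReferenceModel(
        chromosomes=chromosomes,
        genes=genes,
        replication=replication,
        trinuc_genome=trinuc_genome,
        trinuc_exome=trinuc_exome,
    )
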