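"""Synthetic cohorts of clonal crypts from polymerase-proofreading carriers.

The generator encodes the study conditions: per-genotype, per-year SBS and
indel accumulation (POLE L424V 331 SBS/yr, POLD1 S478N 152, POLD1 L474P and
D316N 58, wild type 49; indels 13 / 44 / 12 / 1 per year; endometrial glands
148 vs 29 SBS/yr), genotype-specific signature mixtures (POLE dominated by
SBS10a/SBS10b/SBS28 over the SBS1/SBS5 clock, POLD1 by SBS10c), clonal crypt
phylogenies with truncal VAF near 0.5, ~30x per-crypt coverage aggregating to
~340x per patient, germline SNPs, early-embryonic mutations whose signature
content depends on parental inheritance, and restriction-digest trinucleotide
bias for duplex counts.

Between-patient rate heterogeneity defaults to a 10% coefficient of
variation (lognormal multiplier on the genotype rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import refsigs
from .phylogeny import Node
from .reference import (
    CHANNELS_96,
    COMPLEMENT,
    ReferenceModel,
    TRINUC_INDEX,
    channel_alt,
    channel_context,
    revcomp,
)

#: Per-genotype genome-wide rates (mutations per year) — the study conditions.
SBS_RATE = {
    "POLE_L424V": 331.0,
    "POLD1_S478N": 152.0,
    "POLD1_L474P": 58.0,
    "POLD1_D316N": 58.0,
    "WT": 49.0,
}
ID_RATE = {
    "POLE_L424V": 13.0,
    "POLD1_S478N": 44.0,
    "POLD1_L474P": 12.0,
    "POLD1_D316N": 12.0,
    "WT": 1.0,
}
#: Endometrial gland SBS rates per year (carrier vs healthy).
ENDOMETRIUM_SBS_RATE = {"POLE_L424V": 148.0, "WT": 29.0}

#: Signature mixture weights per genotype.  POLE excess is attributed to
#: SBS10a/SBS10b/SBS28 over the SBS1/SBS5 clock; POLD1 excess to SBS10c.
#: Clock shares approximate the wild-type 49/yr share of each total rate.
SIG_WEIGHTS = {
    "POLE_L424V": {"SBS10a": 0.45, "SBS10b": 0.35, "SBS28": 0.05, "SBS1": 0.05, "SBS5": 0.10},
    "POLD1_S478N": {"SBS10c": 0.62, "SBS1": 0.12, "SBS5": 0.26},
    "POLD1_L474P": {"SBS10c": 0.20, "SBS1": 0.25, "SBS5": 0.55},
    "POLD1_D316N": {"SBS10c": 0.20, "SBS1": 0.25, "SBS5": 0.55},
    "WT": {"SBS1": 0.35, "SBS5": 0.65},
}
#: Indel channel mixtures: polymerase genotypes dominated by 1-bp T
#: insertions at T homopolymers (ID1-like).
ID_WEIGHTS = {
    "POLE_L424V": {"ID1": 0.85, "ID_flat": 0.15},
    "POLD1_S478N": {"ID1": 0.90, "ID_flat": 0.10},
    "POLD1_L474P": {"ID1": 0.80, "ID_flat": 0.20},
    "POLD1_D316N": {"ID1": 0.80, "ID_flat": 0.20},
    "WT": {"ID1": 0.45, "ID_flat": 0.55},
}


@dataclass
class PatientConfig:
    id: str
    age: float
    genotype: str = "WT"
    inheritance: str = "maternal"
    n_crypts: int = 10


@dataclass
class CohortConfig:
    patients: list[PatientConfig]
    sbs_rate: dict[str, float] = field(default_factory=lambda: dict(SBS_RATE))
    id_rate: dict[str, float] = field(default_factory=lambda: dict(ID_RATE))
    sig_weights: dict[str, dict[str, float]] = field(default_factory=lambda: {
        g: dict(w) for g, w in SIG_WEIGHTS.items()})
    id_weights: dict[str, dict[str, float]] = field(default_factory=lambda: {
        g: dict(w) for g, w in ID_WEIGHTS.items()})
    coverage_mean: float = 30.0
    rate_cv: float = 0.10
    #: crypt lineages separate during early development; the trunk
    #: (conception -> crypt MRCA) is correspondingly short (<= 10 years
    #: is configurable, default well under 1 year)
    split_age_max: float = 0.5
    germline_het: int = 300
    germline_hom: int = 150
    pon_sensitivity: float = 0.95
    fp_rate: float = 1e-6
    embryonic_divisions: int = 3
    zga_divisions: int = 3
    seed: int = 0

    def validate(self) -> None:
        for g, r in {**self.sbs_rate, **self.id_rate}.items():
            if r < 0:
                raise ValueError(f"negative rate for {g}")
        for g, w in self.sig_weights.items():
            if abs(sum(w.values()) - 1) > 1e-9:
                raise ValueError(f"signature weights for {g} do not sum to 1")
        for p in self.patients:
            if p.age <= 0:
                raise ValueError(f"patient {p.id} has non-positive age")


@dataclass
class TruthSet:
    mutations: pd.DataFrame
    trees: dict[str, Node]
    germline: pd.DataFrame
    samples: dict[str, list[str]]


class SaturationError(RuntimeError):
    """Requested mutation burden exceeds available reference sites."""


def simulate_burdens(
    patients: list[PatientConfig],
    rates: dict[str, float],
    seed: int,
    rate_cv: float = 0.10,
) -> pd.DataFrame:
    """Lightweight per-crypt burden generator (no variant-level detail).

    Burden per crypt ~ Poisson(rate_genotype x patient_factor x age), with a
    lognormal patient factor of the given coefficient of variation.  Returns
    a tidy table of BurdenRecords for the mixed-model rate fit.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + rate_cv**2))
    rows = []
    for p in patients:
        factor = rng.lognormal(-sigma**2 / 2, sigma) if rate_cv > 0 else 1.0
        lam = rates[p.genotype] * factor * p.age
        for c in range(p.n_crypts):
            rows.append({
                "sample": f"{p.id}_c{c}",
                "patient": p.id,
                "age": p.age,
                "genotype": p.genotype,
                "burden": int(rng.poisson(lam)),
            })
    return pd.DataFrame(rows)


def _sample_tree(patient: PatientConfig, rng: np.random.Generator,
                 split_age_max: float) -> Node:
    """Random crypt coalescence: trunk from conception to a split age <= 10
    years, then random binary divergence shortly after."""
    names = [f"{patient.id}_c{i}" for i in range(patient.n_crypts)]
    t_mrca = rng.uniform(0.05, min(split_age_max, patient.age * 0.5))
    if patient.n_crypts == 1:
        leaf = Node(name=names[0], time=patient.age)
        root = Node(children=[leaf], time=t_mrca)
        return root

    def build(leafset: list[str], t_parent: float) -> Node:
        if len(leafset) == 1:
            return Node(name=leafset[0], time=patient.age)
        t = t_parent + rng.exponential(0.5)
        t = min(t, (t_parent + patient.age) / 2)
        k = int(rng.integers(1, len(leafset)))
        left, right = leafset[:k], leafset[k:]
        node = Node(children=[build(left, t), build(right, t)], time=t)
        return node

    order = list(rng.permutation(names))
    root = build(order, t_mrca)
    root.time = t_mrca
    return root


def _mixed_spectrum(weights: dict[str, float], sigs: pd.DataFrame) -> np.ndarray:
    v = np.zeros(96)
    for name, w in weights.items():
        v += w * sigs[name].to_numpy()
    return v / v.sum()


def _channel_probs(spectrum: np.ndarray, ref: ReferenceModel) -> np.ndarray:
    """Reweight channel probabilities by reference trinucleotide availability."""
    avail = np.array([
        ref.trinuc_genome[TRINUC_INDEX[channel_context(c)]] for c in CHANNELS_96
    ], dtype=float)
    f = avail / avail.sum()
    w = spectrum * f * 32  # relative availability vs uniform composition
    return w / w.sum()


def _per_signature_probs(weights: dict[str, float], sigs: pd.DataFrame,
                         ref: ReferenceModel) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Mutation draws go signature-first: the generating signature follows the
    configured mixture weights exactly, then the channel is drawn within the
    signature with availability reweighting.  Returns (names, weight vector,
    names x 96 channel probability matrix)."""
    names = list(weights)
    wv = np.array([weights[n] for n in names], dtype=float)
    wv = wv / wv.sum()
    mat = np.vstack([_channel_probs(sigs[n].to_numpy(), ref) for n in names])
    return names, wv, mat


def _draw_sbs(ref, n, probs, rng, used: set, channels=None):
    """Draw n SBS records at sites matching the drawn channels' contexts."""
    sites = ref.context_sites()
    if channels is None:
        channels = rng.choice(96, size=n, p=probs)
    out = []
    for c in channels:
        label = CHANNELS_96[c]
        ctx = channel_context(label)
        pool = sites[TRINUC_INDEX[ctx]]
        if not pool:
            raise SaturationError(f"no sites with context {ctx}")
        for _ in range(20):
            chrom, pos = pool[int(rng.integers(len(pool)))]
            if (chrom, pos) not in used:
                break
        else:
            raise SaturationError("reference saturated: cannot place mutation")
        used.add((chrom, pos))
        refbase = ref.base(chrom, pos)
        alt = channel_alt(label)
        if refbase not in "CT":  # site is purine-centred; emit opposite strand
            alt = COMPLEMENT[alt]
        out.append((chrom, pos, refbase, alt, label))
    return out


def _draw_ids(ref, n, id_probs, rng, used: set):
    """Draw n indel records from the reduced 24-channel mixture."""
    runs = ref.t_homopolymer_runs(min_len=1)
    run_by_len: dict[int, list] = {}
    for chrom, s, e in runs:
        run_by_len.setdefault(min(e - s, 5), []).append((chrom, s, e))
    chroms = list(ref.chromosomes)
    out = []
    channels = rng.choice(len(refsigs.ID_CHANNELS), size=n, p=id_probs)
    for c in channels:
        label = refsigs.ID_CHANNELS[c]
        if label.startswith("ins_T_hp"):
            want = 5 if label.endswith("5+") else int(label[-1])
            pool = run_by_len.get(want) or next(
                (run_by_len[k] for k in sorted(run_by_len) if run_by_len[k]), None)
            if not pool:
                raise SaturationError("no T homopolymers available")
            chrom, s, e = pool[int(rng.integers(len(pool)))]
            pos = max(s - 1, 0)
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            refbase = ref.base(chrom, pos)
            out.append((chrom, pos, refbase, refbase + "T", label))
        else:
            # generic 1-bp or multi-bp event at a random site
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, len(ref.chromosomes[chrom]) - 3))
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            refbase = ref.base(chrom, pos)
            if label.startswith("ins"):
                ins = "A" if "other" in label else "T"
                if label == "ins_multi":
                    ins = "AC"
                out.append((chrom, pos, refbase, refbase + ins, label))
            else:
                ndel = 2 if label == "del_multi" else 1
                refseq = ref.chromosomes[chrom][pos : pos + 1 + ndel]
                out.append((chrom, pos, refseq, refbase, label))
    return out


def simulate_embryonic(
    patient: PatientConfig,
    n_divisions: int,
    ref: ReferenceModel,
    rng: np.random.Generator,
    sig_weights: dict[str, dict[str, float]] | None = None,
    id_weights: dict[str, dict[str, float]] | None = None,
    zga_divisions: int = 3,
    clock_per_division: float = 3.0,
    pol_per_division: float = 12.0,
    ins_per_division: float = 2.5,
    used: set | None = None,
) -> pd.DataFrame:
    """Early-embryonic mutations with inheritance-dependent signatures.

    A mutation arising at division k is carried by a 2^-k cell fraction.
    Maternal inheritance exposes the zygote to the defective polymerase from
    division 1 (the protein is in the ovum cytoplasm); paternal inheritance
    applies the clock-only mixture until zygotic genome activation
    (``zga_divisions``), the polymerase mixture afterwards.
    """
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    sig_weights = sig_weights or SIG_WEIGHTS
    id_weights = id_weights or ID_WEIGHTS
    sigs = refsigs.synthetic_sbs_signatures()
    idsigs = refsigs.synthetic_id_signatures()
    used = set() if used is None else used
    carrier = patient.genotype != "WT"
    rows = []
    for k in range(1, n_divisions + 1):
        pol_active = carrier and (
            patient.inheritance == "maternal" or k > zga_divisions
        )
        weights = sig_weights[patient.genotype] if pol_active else SIG_WEIGHTS["WT"]
        idw = id_weights[patient.genotype] if pol_active else ID_WEIGHTS["WT"]
        rate = pol_per_division if pol_active else clock_per_division
        names, wv, mat = _per_signature_probs(weights, sigs, ref)
        n_sbs = rng.poisson(rate * 2 ** (k - 1))  # per-cell rate x cells
        sig_idx = rng.choice(len(names), size=n_sbs, p=wv)
        channels = np.array([rng.choice(96, p=mat[i]) for i in sig_idx], dtype=int)
        recs = _draw_sbs(ref, n_sbs, None, rng, used, channels=channels)
        for (chrom, pos, refb, alt, ch), i in zip(recs, sig_idx):
            rows.append(dict(chrom=chrom, pos=pos, ref=refb, alt=alt,
                             vclass="SBS", signature=names[i], channel=ch,
                             division=k, cell_fraction=2.0 ** -k))
        n_ins = rng.poisson((ins_per_division if pol_active else 0.3) * 2 ** (k - 1))
        idp = np.zeros(len(refsigs.ID_CHANNELS))
        for name, w in idw.items():
            idp += w * idsigs[name].to_numpy()
        idp /= idp.sum()
        for chrom, pos, refb, alt, ch in _draw_ids(ref, n_ins, idp, rng, used):
            rows.append(dict(chrom=chrom, pos=pos, ref=refb, alt=alt,
                             vclass="ID", signature="ID1" if ch.startswith("ins_T") else "ID_other",
                             channel=ch, division=k, cell_fraction=2.0 ** -k))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass",
                                       "signature", "channel", "division",
                                       "cell_fraction"])


def simulate_cohort(ref: ReferenceModel, cfg: CohortConfig) -> TruthSet:
    """Full variant-level cohort: phylogenies, somatic SBS/ID along branches,
    embryonic mutations and germline SNPs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sigs = refsigs.synthetic_sbs_signatures()
    idsigs = refsigs.synthetic_id_signatures()
    sigma = np.sqrt(np.log(1 + cfg.rate_cv**2))

    all_rows = []
    trees: dict[str, Node] = {}
    samples: dict[str, list[str]] = {}
    used: set = set()
    mut_counter = 0
    for p in cfg.patients:
        tree = _sample_tree(p, rng, cfg.split_age_max)
        trees[p.id] = tree
        leaves = [l.name for l in tree.leaves()]
        samples[p.id] = leaves
        factor = rng.lognormal(-sigma**2 / 2, sigma) if cfg.rate_cv > 0 else 1.0
        sbs_rate = cfg.sbs_rate[p.genotype] * factor
        id_rate = cfg.id_rate[p.genotype] * factor
        names, wv, mat = _per_signature_probs(cfg.sig_weights[p.genotype], sigs, ref)
        idp = np.zeros(len(refsigs.ID_CHANNELS))
        for name, w in cfg.id_weights[p.genotype].items():
            idp += w * idsigs[name].to_numpy()
        idp /= idp.sum()

        # branch durations: walk the tree; branch above node spans parent
        # time -> node time (root: conception -> t_mrca)
        branch_counter = [0]

        def walk(node, t_parent):
            nonlocal mut_counter
            duration = max(node.time - t_parent, 0.0)
            if not node.branch_id:
                if node.is_leaf():
                    node.branch_id = node.name
                else:
                    branch_counter[0] += 1
                    node.branch_id = f"{p.id}_b{branch_counter[0]}"
            carriers = tuple(sorted(l.name for l in node.leaves()))
            n_sbs = rng.poisson(sbs_rate * duration)
            sig_idx = rng.choice(len(names), size=n_sbs, p=wv)
            channels = np.array([rng.choice(96, p=mat[i]) for i in sig_idx],
                                dtype=int)
            recs = _draw_sbs(ref, n_sbs, None, rng, used, channels=channels)
            for (chrom, pos, refb, alt, ch), i in zip(recs, sig_idx):
                all_rows.append(dict(
                    mut_id=f"m{mut_counter}", patient=p.id, chrom=chrom, pos=pos,
                    ref=refb, alt=alt, vclass="SBS", signature=names[i],
                    channel=ch, branch=node.branch_id, embryonic=False,
                    cell_fraction=1.0, carriers=";".join(carriers)))
                mut_counter += 1
            n_id = rng.poisson(id_rate * duration)
            for chrom, pos, refb, alt, ch in _draw_ids(ref, n_id, idp, rng, used):
                all_rows.append(dict(
                    mut_id=f"m{mut_counter}", patient=p.id, chrom=chrom, pos=pos,
                    ref=refb, alt=alt, vclass="ID",
                    signature="ID1" if ch.startswith("ins_T") else "ID_other",
                    channel=ch, branch=node.branch_id, embryonic=False,
                    cell_fraction=1.0, carriers=";".join(carriers)))
                mut_counter += 1
            for c in node.children:
                walk(c, node.time)

        tree.branch_id = "trunk"
        walk(tree, 0.0)

        if cfg.embryonic_divisions:
            emb = simulate_embryonic(
                p, cfg.embryonic_divisions, ref, rng,
                sig_weights=cfg.sig_weights, id_weights=cfg.id_weights,
                zga_divisions=cfg.zga_divisions, used=used)
            for _, r in emb.iterrows():
                # each crypt descends from one embryonic cell: it carries the
                # mutation with probability equal to the cell fraction
                cf = float(r.cell_fraction)
                carry = sorted(l for l in leaves if rng.random() < cf)
                all_rows.append(dict(
                    mut_id=f"m{mut_counter}", patient=p.id, chrom=r.chrom,
                    pos=int(r.pos), ref=r.ref, alt=r.alt, vclass=r.vclass,
                    signature=r.signature, channel=r.channel, branch="embryonic",
                    embryonic=True, cell_fraction=cf,
                    carriers=";".join(carry)))
                mut_counter += 1

    germ_rows = []
    chroms = list(ref.chromosomes)
    sizes = np.array([len(ref.chromosomes[c]) for c in chroms], dtype=float)
    for i in range(cfg.germline_het + cfg.germline_hom):
        ci = rng.choice(len(chroms), p=sizes / sizes.sum())
        chrom = chroms[ci]
        pos = int(rng.integers(1, sizes[ci] - 2))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        refb = ref.base(chrom, pos)
        alt = rng.choice([b for b in "ACGT" if b != refb])
        germ_rows.append(dict(chrom=chrom, pos=pos, ref=refb, alt=str(alt),
                              vaf_pop=0.5 if i < cfg.germline_het else 1.0))
    mut_cols = ["mut_id", "patient", "chrom", "pos", "ref", "alt", "vclass",
                "signature", "channel", "branch", "embryonic", "cell_fraction",
                "carriers"]
    mutations = pd.DataFrame(all_rows, columns=mut_cols)
    germline = pd.DataFrame(germ_rows, columns=["chrom", "pos", "ref", "alt", "vaf_pop"])
    return TruthSet(mutations=mutations, trees=trees, germline=germline,
                    samples=samples)


def simulate_reads(
    truth: TruthSet,
    patient: str,
    coverage_mean: float = 30.0,
    seed: int = 0,
    fp_rate: float = 1e-6,
    genome_size: int | None = None,
    pon_sensitivity: float = 0.95,
    ref: ReferenceModel | None = None,
    depth_dispersion: float | None = None,
) -> pd.DataFrame:
    """Read-count variant table for one patient's crypts.

    Depth NR ~ Poisson(coverage) per site and sample (negative binomial if
    ``depth_dispersion`` is set); NV ~ Binomial(NR, cell_fraction/2) in
    carrier crypts.  Germline SNPs are included at population VAF; embryonic
    mutations appear in every crypt at VAF cell_fraction/2 of the trunk (they
    predate the crypt MRCA).  Sequencing-error false positives are injected
    as context-independent sites at ``fp_rate`` per bp with NV of 1-2.
    Clean variants get median alignment score >= 140 and clipped median 0.
    """
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    rng = np.random.default_rng(seed)
    crypts = truth.samples[patient]
    muts = truth.mutations[truth.mutations.patient == patient]

    def depth(size):
        if depth_dispersion:
            p = depth_dispersion / (depth_dispersion + coverage_mean)
            return rng.negative_binomial(depth_dispersion, p, size=size)
        return rng.poisson(coverage_mean, size=size)

    rows = []
    for _, m in muts.iterrows():
        carriers = set(m.carriers.split(";"))
        row = dict(chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                   vclass=m.vclass, truth="embryonic" if m.embryonic else "somatic",
                   mut_id=m.mut_id,
                   asmd=140 + int(rng.poisson(20)), clip_med=0.0,
                   indel_qual=300 + float(rng.exponential(250)), pon=False)
        nrs = depth(len(crypts))
        for s, nr in zip(crypts, nrs):
            # embryonic mutations predate the crypt MRCA: clonal in the crypt
            vaf = 0.5 * m.cell_fraction if not m.embryonic else 0.5
            present = s in carriers
            nv = rng.binomial(nr, vaf) if present else 0
            row[f"NV_{s}"] = int(nv)
            row[f"NR_{s}"] = int(nr)
        row["site_depth"] = int(np.median(nrs))
        rows.append(row)

    for _, g in truth.germline.iterrows():
        row = dict(chrom=g.chrom, pos=int(g.pos), ref=g.ref, alt=g.alt,
                   vclass="SBS", truth="germline", mut_id="",
                   asmd=140 + int(rng.poisson(20)), clip_med=0.0,
                   indel_qual=400.0, pon=bool(rng.random() < pon_sensitivity))
        nrs = depth(len(crypts))
        for s, nr in zip(crypts, nrs):
            row[f"NV_{s}"] = int(rng.binomial(nr, g.vaf_pop))
            row[f"NR_{s}"] = int(nr)
        row["site_depth"] = int(np.median(nrs))
        rows.append(row)

    if fp_rate > 0:
        gsize = genome_size or (sum(len(s) for s in ref.chromosomes.values())
                                if ref else 10_000_000)
        for s in crypts:
            n_fp = rng.poisson(fp_rate * gsize)
            for _ in range(n_fp):
                row = dict(chrom="fp", pos=int(rng.integers(1, gsize)),
                           ref="A", alt="T", vclass="SBS", truth="artifact",
                           mut_id="",
                           asmd=float(rng.choice([100, 120, 150])),
                           clip_med=float(rng.choice([0.0, 1.0])),
                           indel_qual=100.0, pon=False)
                for s2 in crypts:
                    nr = int(depth(1)[0])
                    row[f"NV_{s2}"] = int(rng.integers(1, 3)) if s2 == s else 0
                    row[f"NR_{s2}"] = nr
                row["site_depth"] = int(coverage_mean)
                rows.append(row)

    cols = ["chrom", "pos", "ref", "alt", "vclass", "truth", "mut_id",
            "asmd", "clip_med", "indel_qual", "pon", "site_depth"]
    cols += [c for s in crypts for c in (f"NV_{s}", f"NR_{s}")]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols]


def simulate_duplex(
    mu: float | np.ndarray,
    ref: ReferenceModel,
    bias_profile: np.ndarray,
    n_calls: int,
    seed: int = 0,
):
    """Duplex-sequencing trinucleotide and substitution counts.

    Interrogated trinucleotide totals t_i^e are multinomial draws from the
    genome composition tilted by ``bias_profile`` (restriction-digest bias);
    substitution counts s_ij are Poisson with per-base rate ``mu`` (scalar:
    uniform across the 96 channels; vector: per-channel per-base rates).
    """
    from .nanoseq import DuplexCounts

    if n_calls <= 0:
        raise ValueError("n_calls must be positive")
    bias = np.asarray(bias_profile, dtype=float)
    if bias.shape != (32,) or (bias <= 0).any():
        raise ValueError("bias_profile must be a positive 32-vector")
    rng = np.random.default_rng(seed)
    p = ref.trinuc_genome * bias
    p = p / p.sum()
    t_exp = rng.multinomial(n_calls, p)
    if np.isscalar(mu):
        rate = np.full((32, 6), 0.0)
        for i in range(32):
            js = range(3) if i < 16 else range(3, 6)
            for j in js:
                rate[i, j] = float(mu) / 3
    else:
        # 96-vector, substitution-major with 16 lexicographic flanks each
        mu96 = np.asarray(mu, dtype=float)
        rate = np.zeros((32, 6))
        for i in range(32):
            flank = i % 16
            js = range(3) if i < 16 else range(3, 6)
            for j in js:
                rate[i, j] = mu96[j * 16 + flank]
    s = np.zeros((32, 6))
    for i in range(32):
        for j in range(6):
            if rate[i, j] > 0:
                s[i, j] = rng.poisson(t_exp[i] * rate[i, j])
    return DuplexCounts(t_genome=ref.trinuc_genome.astype(float),
                        t_exp=t_exp.astype(float), s=s)
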