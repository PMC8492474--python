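"""Context-corrected selection (dN/dS) analysis and driver annotation.

Hypermutated polymerase spectra concentrate on few trinucleotide contexts,
which distorts the expected proportions of synonymous / missense / nonsense
changes: a naive uniform-rate expectation then produces spurious selection
signals.  Expected counts are therefore computed by exhaustively enumerating
every possible substitution in each gene's CDS, weighting each by the
per-site rate implied by the 96-channel spectrum (channel probability
divided by the genomic count of that trinucleotide), and classifying it with
the standard codon table.  Synonymous sites calibrate the neutral rate; each
protein-altering class is tested per gene against a negative-binomial
background (dispersion shared across genes within a class), p-values are
Fisher-combined across classes and Benjamini-Hochberg corrected over genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency, nbinom, poisson
from statsmodels.stats.multitest import multipletests

from .reference import (
    CHANNEL_INDEX,
    COMPLEMENT,
    Gene,
    ReferenceModel,
    TRINUC_INDEX,
    collapse_context,
    sbs_channel,
)

CODON_TABLE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_bases):
    for _j, _b in enumerate(_bases):
        for _k, _c in enumerate(_bases):
            CODON_TABLE[_a + _b + _c] = _aas[16 * _i + 4 * _j + _k]

IMPACT_CLASSES = ("synonymous", "missense", "nonsense", "splice")
TESTED_CLASSES = ("missense", "nonsense", "splice")


@dataclass
class DndsGeneResult:
    gene: str
    observed: dict
    expected: dict
    p_by_class: dict
    p_fisher: float
    q: float

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def classify_impact(variant, gene: Gene, ref: ReferenceModel,
                    splice_width: int = 2) -> str:
    """Impact class of a variant on a gene model.

    SBS inside the CDS are classified by codon change (stop-gain ->
    nonsense, stop-loss -> missense); indels are 'frameshift' unless the
    length change is a multiple of 3 ('inframe').  Positions within
    ``splice_width`` bp outside a CDS boundary are 'splice'.
    """
    pos = int(variant["pos"]) if not isinstance(variant, tuple) else variant[0]
    refa = variant["ref"] if not isinstance(variant, tuple) else variant[1]
    alt = variant["alt"] if not isinstance(variant, tuple) else variant[2]

    in_cds = any(s <= pos < e for s, e in gene.cds)
    if not in_cds:
        near = any(s - splice_width <= pos < s or e <= pos < e + splice_width
                   for s, e in gene.cds)
        if near:
            return "splice"
        raise ValueError("variant outside gene footprint")

    if len(refa) != len(alt):  # indel
        delta = abs(len(alt) - len(refa))
        return "frameshift" if delta % 3 else "inframe"

    cds_seq = gene.coding_sequence(ref.chromosomes)
    # coding offset of pos
    offset = 0
    for s, e in gene.cds:
        if s <= pos < e:
            offset += pos - s
            break
        offset += e - s
    if gene.strand == "-":
        offset = len(cds_seq) - 1 - offset
        alt_c = COMPLEMENT[alt]
    else:
        alt_c = alt
    codon_i = offset // 3
    within = offset % 3
    codon = cds_seq[3 * codon_i: 3 * codon_i + 3]
    new_codon = codon[:within] + alt_c + codon[within + 1:]
    aa_old = CODON_TABLE[codon]
    aa_new = CODON_TABLE[new_codon]
    if aa_new == aa_old:
        return "synonymous"
    if aa_new == "*":
        return "nonsense"
    return "missense"


def enumerate_coding_substitutions(
    genes: list[Gene],
    ref: ReferenceModel,
    spectrum: np.ndarray,
) -> pd.DataFrame:
    """Exhaustive table of every possible CDS substitution with its
    spectrum-implied per-site rate weight and impact class.

    The weight of a substitution is spectrum[channel] divided by the genomic
    count of the channel's trinucleotide context — the per-site rate implied
    by a 96-channel spectrum that describes genome-wide channel proportions.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if abs(spectrum.sum() - 1) > 1e-6:
        raise ValueError("spectrum must sum to 1")
    rows = []
    for gene in genes:
        chrom_seq = ref.chromosomes[gene.chrom]
        cds_seq = gene.coding_sequence(ref.chromosomes)
        L = len(cds_seq)
        offset = 0
        for s, e in gene.cds:
            for pos in range(s, e):
                refbase = chrom_seq[pos]
                tri = chrom_seq[pos - 1: pos + 2]
                if len(tri) != 3:
                    offset += 1
                    continue
                ctx_count = ref.trinuc_genome[TRINUC_INDEX[collapse_context(tri)]]
                if ctx_count == 0:
                    offset += 1
                    continue
                coff = L - 1 - offset if gene.strand == "-" else offset
                ci, within = divmod(coff, 3)
                codon = cds_seq[3 * ci: 3 * ci + 3]
                aa_old = CODON_TABLE[codon]
                for alt in "ACGT":
                    if alt == refbase:
                        continue
                    p_ch = spectrum[CHANNEL_INDEX[sbs_channel(tri, alt)]]
                    if p_ch == 0:
                        continue
                    alt_c = COMPLEMENT[alt] if gene.strand == "-" else alt
                    aa_new = CODON_TABLE[codon[:within] + alt_c + codon[within + 1:]]
                    cls = ("synonymous" if aa_new == aa_old
                           else "nonsense" if aa_new == "*" else "missense")
                    rows.append((gene.name, gene.chrom, pos, refbase, alt,
                                 cls, p_ch / ctx_count))
                offset += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "ref", "alt",
                                       "impact", "weight"])


def expected_class_weights(
    genes: list[Gene],
    ref: ReferenceModel,
    spectrum: np.ndarray,
) -> pd.DataFrame:
    """Per-gene expected class weights: the enumeration table summed per
    gene and impact class.  Exact (matches brute-force per-site oracles)."""
    tab = enumerate_coding_substitutions(genes, ref, spectrum)
    out = (tab.pivot_table(index="gene", columns="impact", values="weight",
                           aggfunc="sum", fill_value=0.0)
           .reindex([g.name for g in genes], fill_value=0.0))
    for cls in ("synonymous", "missense", "nonsense"):
        if cls not in out.columns:
            out[cls] = 0.0
    return out[["synonymous", "missense", "nonsense"]]


def simulate_coding_mutations(
    genes: list[Gene],
    ref: ReferenceModel,
    spectrum: np.ndarray,
    n_mutations: int,
    n_samples: int,
    seed: int = 0,
    driver_gene: str | None = None,
    driver_excess: float = 10.0,
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Neutral coding mutations under a trinucleotide spectrum, with an
    optional planted driver gene.

    Substitutions are drawn from the exhaustive enumeration table with
    probability proportional to the spectrum-implied per-site rate (neutral:
    impact plays no role).  A planted driver multiplies the sampling weight
    of its truncating (nonsense) substitutions by ``driver_excess``.
    """
    tab = table if table is not None else enumerate_coding_substitutions(
        genes, ref, spectrum)
    w = tab["weight"].to_numpy(dtype=float).copy()
    if driver_gene is not None:
        boost = (tab["gene"] == driver_gene) & (tab["impact"] == "nonsense")
        w[boost.to_numpy()] *= driver_excess
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(tab), size=n_mutations, p=w / w.sum())
    out = tab.iloc[idx].copy().reset_index(drop=True)
    out["sample"] = [f"S{j}" for j in rng.integers(0, n_samples, size=n_mutations)]
    # unique branch-assigned mutations: de-duplicate identical events per sample
    out = out.drop_duplicates(subset=["sample", "chrom", "pos", "alt"])
    return out


def apply_sample_caps(
    mutations: pd.DataFrame,
    max_coding_muts_per_sample: int = 5000,
    max_muts_per_gene_per_sample: int = 20,
) -> pd.DataFrame:
    """Per-sample hypermutation caps applied before counting.

    Samples exceeding the coding-mutation cap are excluded outright; within
    a sample, counts per gene are truncated at the per-gene cap.
    """
    df = mutations.copy()
    totals = df.groupby("sample").size()
    ok_samples = totals[totals <= max_coding_muts_per_sample].index
    df = df[df["sample"].isin(ok_samples)]
    df = df.groupby(["sample", "gene"], group_keys=False).head(
        max_muts_per_gene_per_sample)
    return df


def dnds_modified(
    mutations: pd.DataFrame,
    genes: list[Gene],
    ref: ReferenceModel,
    spectrum: np.ndarray,
    max_coding_muts_per_sample: int = 5000,
    max_muts_per_gene_per_sample: int = 20,
    weights: pd.DataFrame | None = None,
    family: str = "nb",
) -> pd.DataFrame:
    """Per-gene selection test with context-corrected expectations.

    ``mutations`` holds unique branch-assigned coding mutations with columns
    sample, gene, impact.  Synonymous counts calibrate the neutral rate; for
    each protein-altering class a negative binomial with class-shared
    dispersion models the per-gene background, per-gene p-values are the NB
    upper tail, combined across classes by Fisher's method and BH-corrected.
    """
    muts = apply_sample_caps(mutations, max_coding_muts_per_sample,
                             max_muts_per_gene_per_sample)
    # truncating indels count with nonsense for the test
    impact = muts["impact"].replace({"frameshift": "nonsense"})
    obs = (
        pd.crosstab(muts["gene"], impact)
        .reindex([g.name for g in genes], fill_value=0)
    )
    for cls in ("synonymous", "missense", "nonsense", "splice"):
        if cls not in obs.columns:
            obs[cls] = 0

    if weights is None:
        weights = expected_class_weights(genes, ref, spectrum)
    n_syn = obs["synonymous"].sum()
    w_syn = weights["synonymous"].sum()
    if w_syn <= 0:
        raise ValueError("no synonymous sites under this spectrum")
    t = n_syn / w_syn  # neutral mutation-rate scale
    expected = weights * t

    results = {}
    fisher_parts = {g.name: [] for g in genes}
    for cls in ("missense", "nonsense"):
        e = expected[cls].to_numpy(dtype=float)
        o = obs[cls].to_numpy(dtype=float)
        valid = e > 0
        alpha = (_estimate_dispersion(o[valid], e[valid])
                 if family == "nb" else None)
        scale = o[valid].sum() / e[valid].sum() if e[valid].sum() > 0 else 1.0
        mean = e * max(scale, 1e-12)
        p = np.ones(len(e))
        for i in range(len(e)):
            if not valid[i]:
                continue
            if alpha is None:
                p[i] = poisson.sf(o[i] - 1, mean[i])
            else:
                n_nb = 1.0 / alpha
                pr = n_nb / (n_nb + mean[i])
                p[i] = nbinom.sf(o[i] - 1, n_nb, pr)
        results[cls] = p
        for g, pv in zip(obs.index, p):
            fisher_parts[g].append(pv)

    p_fisher = {}
    for g, ps in fisher_parts.items():
        ps = np.clip(ps, 1e-300, 1.0)
        stat = -2 * np.log(ps).sum()
        p_fisher[g] = float(chi2.sf(stat, 2 * len(ps)))
    pf = np.array([p_fisher[g] for g in obs.index])
    q = multipletests(pf, method="fdr_bh")[1]

    out = pd.DataFrame({
        "obs_synonymous": obs["synonymous"],
        "obs_missense": obs["missense"],
        "obs_nonsense": obs["nonsense"],
        "exp_synonymous": expected["synonymous"],
        "exp_missense": expected["missense"],
        "exp_nonsense": expected["nonsense"],
        "p_missense": results["missense"],
        "p_nonsense": results["nonsense"],
        "p_fisher": pf,
        "q": q,
    }, index=obs.index)
    out["significant"] = out["q"] < 0.05
    return out


def _estimate_dispersion(obs: np.ndarray, exp: np.ndarray):
    """Class-shared NB dispersion alpha from an offset regression.

    Returns None (Poisson fallback) with < 20 informative genes or when the
    fit finds no overdispersion.
    """
    if len(obs) < 20:
        warnings.warn("fewer than 20 genes: Poisson fallback for dispersion")
        return None
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(obs, np.ones((len(obs), 1)),
                                        offset=np.log(exp))
            fit = model.fit(disp=False, maxiter=200)
        alpha = float(fit.params[-1])
        if not np.isfinite(alpha) or alpha <= 1e-8:
            return None
        return alpha
    except Exception:
        warnings.warn("NB dispersion fit failed: Poisson fallback")
        return None


def annotate_drivers(
    variants: pd.DataFrame,
    genes: dict[str, Gene],
    hotspots: set | None = None,
    oncogenic: set | None = None,
    tissue: str = "intestine",
) -> pd.DataFrame:
    """Rule-based driver calls on impact-annotated coding variants.

    Rules in priority order: truncating (nonsense/frameshift/splice) in a
    recessively acting gene; known activating hotspot in a dominant or
    recessive gene; 'likely oncogenic' database annotation.  Variants
    outside the tissue-appropriate panel (colorectal-90 for intestine,
    pan-cancer-369 otherwise) are dropped; unknown gene roles are skipped
    with a warning.
    """
    hotspots = hotspots or set()
    oncogenic = oncogenic or set()
    panel = "colorectal-90" if tissue == "intestine" else "pan-cancer-369"
    calls = []
    for _, v in variants.iterrows():
        gene = genes.get(v["gene"])
        if gene is None or gene.role not in ("dominant", "recessive", "intermediate"):
            warnings.warn(f"unknown gene or role for {v['gene']}; skipped")
            continue
        if gene.panel != panel:
            continue
        key = (v["gene"], int(v["pos"]), v["alt"])
        rule = None
        if v["impact"] in ("nonsense", "frameshift", "splice") and \
                gene.role in ("recessive", "intermediate"):
            rule = "truncating-in-recessive"
        elif key in hotspots and v["impact"] != "synonymous":
            rule = "hotspot"
        elif key in oncogenic and v["impact"] != "synonymous":
            rule = "likely-oncogenic-annotation"
        if rule:
            calls.append(dict(sample=v.get("sample", ""), gene=v["gene"],
                              pos=int(v["pos"]), alt=v["alt"], rule=rule))
    return pd.DataFrame(calls, columns=["sample", "gene", "pos", "alt", "rule"])


def driver_burden_test(k_case: int, n_case: int, k_ctrl: int, n_ctrl: int) -> dict:
    """Continuity-corrected Pearson chi-squared on the 2x2 driver table."""
    if min(k_case, n_case - k_case, k_ctrl, n_ctrl - k_ctrl) < 0:
        raise ValueError("invalid counts")
    table = np.array([[k_case, n_case - k_case], [k_ctrl, n_ctrl - k_ctrl]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero-margin table")
    stat, p, dof, _ = chi2_contingency(table, correction=True)
    return {"statistic": float(stat), "p_value": float(p), "dof": int(dof)}
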