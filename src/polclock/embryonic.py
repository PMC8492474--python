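"""Early-embryonic mutation calling from bulk blood.

Blood is highly polyclonal, so only mutations from the first few cell
divisions reach appreciable VAF: SBS are retained at VAF >= 0.15 and indels
at VAF >= 0.10 (the laxer indel calling warrants the lower bound).  The
polymerase contribution is quantified by constrained signature fitting
(SBS1/SBS5 clock vs SBS10a/SBS10b/SBS28) for POLE carriers, and by counting
1-bp T insertions at T homopolymers (the ID1 peak) for POLD1 carriers.  The
maternal/paternal inheritance effect is tested with a two-sided Wilcoxon
rank-sum test on the polymerase-attributed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import refsigs
from .reference import ReferenceModel
from .signatures import SignatureModel, fit_exposures

SBS_VAF_MIN = 0.15
ID_VAF_MIN = 0.10
EMBRYONIC_FIT_SIGNATURES = ["SBS1", "SBS5", "SBS10a", "SBS10b", "SBS28"]
POLYMERASE_SIGNATURES = ["SBS10a", "SBS10b", "SBS28"]


@dataclass
class EmbryonicCallSet:
    variants: pd.DataFrame          # retained records with VAF and shared flag
    n_input: int
    shared_fraction_sbs: float | None = None
    shared_fraction_id: float | None = None
    exposures: pd.Series | None = None
    exposure_reliable: bool = True
    t_insertion_count: int | None = None


def call_embryonic(
    blood: pd.DataFrame,
    cross_tissue: pd.DataFrame | None = None,
    sbs_vaf_min: float = SBS_VAF_MIN,
    id_vaf_min: float = ID_VAF_MIN,
) -> EmbryonicCallSet:
    """Threshold blood variants into the embryonic set (inclusive bounds).

    ``blood`` needs NV/NR (or a VAF column); ``cross_tissue`` is a table of
    variants seen in another tissue of the same individual, used to mark
    pre-gastrulation sharing (matched on chrom/pos/alt).
    """
    df = blood.copy()
    if "VAF" not in df.columns:
        df["VAF"] = df["NV"] / df["NR"]
    sbs = df["vclass"] == "SBS"
    keep = (sbs & (df["VAF"] >= sbs_vaf_min)) | (~sbs & (df["VAF"] >= id_vaf_min))
    out = df[keep].copy()
    out["retained"] = True
    shared_sbs = shared_id = None
    if cross_tissue is not None:
        key = ["chrom", "pos", "alt"]
        other = set(map(tuple, cross_tissue[key].itertuples(index=False)))
        out["shared"] = [tuple(r) in other for r in out[key].itertuples(index=False)]
        sbs_out = out[out["vclass"] == "SBS"]
        id_out = out[out["vclass"] == "ID"]
        shared_sbs = float(sbs_out["shared"].mean()) if len(sbs_out) else None
        shared_id = float(id_out["shared"].mean()) if len(id_out) else None
    return EmbryonicCallSet(variants=out, n_input=len(df),
                            shared_fraction_sbs=shared_sbs,
                            shared_fraction_id=shared_id)


def shared_fraction(n_shared: int, n_total: int) -> float:
    """Fraction of embryonic calls confirmed in a second tissue (percent)."""
    if n_total <= 0:
        raise ValueError("no calls")
    return 100.0 * n_shared / n_total


def fit_embryonic_signatures(
    callset: EmbryonicCallSet,
    catalog: np.ndarray,
    sigs: SignatureModel | None = None,
    min_sbs: int = 10,
) -> EmbryonicCallSet:
    """Fit the five-signature embryonic model to a 96-channel catalog.

    Reports polymerase-attributed (SBS10a+SBS10b+SBS28) and clock
    (SBS1+SBS5) counts; flagged unreliable below ``min_sbs`` substitutions.
    """
    if sigs is None:
        prof = refsigs.synthetic_sbs_signatures()[EMBRYONIC_FIT_SIGNATURES]
        sigs = SignatureModel(prof, {n: "reference" for n in prof.columns})
    cat = pd.DataFrame([catalog], index=["embryonic"],
                       columns=sigs.profiles.index)
    exp = fit_exposures(cat, sigs, allowed=EMBRYONIC_FIT_SIGNATURES)
    s = exp.loc["embryonic", EMBRYONIC_FIT_SIGNATURES]
    s["polymerase"] = float(sum(s[x] for x in POLYMERASE_SIGNATURES))
    s["clock"] = float(s["SBS1"] + s["SBS5"])
    callset.exposures = s
    callset.exposure_reliable = catalog.sum() >= min_sbs
    return callset


def count_t_insertions(callset: EmbryonicCallSet,
                       ref: ReferenceModel) -> EmbryonicCallSet:
    """Count retained 1-bp T insertions landing in a run of reference T.

    An insertion record has alt = ref + inserted base; the insertion site is
    inside a T homopolymer when the reference base after the anchor (or the
    anchor itself) is T.
    """
    n = 0
    for _, v in callset.variants.iterrows():
        if v.vclass != "ID" or len(v.alt) != len(v.ref) + 1:
            continue
        if not v.alt.startswith(v.ref):
            continue
        ins = v.alt[len(v.ref):]
        if ins != "T":
            continue
        chrom, pos = v.chrom, int(v.pos)
        seq = ref.chromosomes.get(chrom, "")
        after = seq[pos + len(v.ref): pos + len(v.ref) + 1] if seq else ""
        anchor = v.ref[-1]
        if anchor == "T" or after == "T":
            n += 1
    callset.t_insertion_count = n
    return callset


def test_inheritance_effect(group_maternal, group_paternal) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on polymerase-
    attributed mutation counts, exact for small samples."""
    a = np.asarray(group_maternal, dtype=float)
    b = np.asarray(group_paternal, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (len(a) + len(b) <= 12 and
                         len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) \
        else "auto"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_maternal": len(a), "n_paternal": len(b)}
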