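"""Statistical separation of somatic mutations from germline and artifacts.

The filter chain mirrors low-input LCM crypt sequencing practice:

1. QC thresholds on the calls themselves (median alignment score of mutant
   reads >= 140, no clipped-read excess, panel-of-normals SNP flag; indels
   need quality >= 300 and depth >= 15).
2. An exact binomial test on read counts aggregated over all crypts of a
   patient (~340x): a germline heterozygous variant has true VAF 0.5 at that
   depth, so the lower-tail test rejects for genuinely somatic variants that
   are present in only a subset of crypts.
3. A beta-binomial overdispersion filter on per-sample counts: germline
   variants have consistent VAFs across crypts (rho small), genuine somatic
   mutations are overdispersed (present in some crypts, absent in others);
   rho > 0.1 flags a genuine somatic variant.
4. ARCH deep-sequencing filters for blood (strand support, VAF window,
   consequence class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import betabinom, binom

QC_FIELDS_SBS = ("asmd", "clip_med", "pon")
QC_FIELDS_ID = ("indel_qual", "site_depth")


@dataclass
class BetaBinomialResult:
    variant: object
    rho: float
    loglik: float
    classification: str  # "genuine" | "rejected"


class SchemaError(KeyError):
    pass


def qc_filter(variants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-call QC thresholds.

    Returns (retained, report); the report carries exactly one primary
    reason per dropped record, assigned in fixed order (alignment score,
    clipping, panel-of-normals for SBS; quality, depth for indels).
    """
    if variants.empty:
        return variants.copy(), pd.DataFrame(columns=["index", "stage", "reason"])
    for f in QC_FIELDS_SBS + QC_FIELDS_ID:
        if f not in variants.columns:
            raise SchemaError(f"missing QC field {f!r}")

    reasons = pd.Series("", index=variants.index, dtype=object)
    sbs = variants["vclass"] == "SBS"
    ind = ~sbs
    checks = [
        (sbs & (variants["asmd"] < 140), "alignment_score"),
        (sbs & (variants["clip_med"] > 0), "clipped_reads"),
        (sbs & variants["pon"].astype(bool), "panel_of_normals"),
        (ind & (variants["indel_qual"] < 300), "indel_quality"),
        (ind & (variants["site_depth"] < 15), "indel_depth"),
    ]
    for mask, reason in checks:
        hit = mask & (reasons == "")
        reasons[hit] = reason
    dropped = reasons != ""
    report = pd.DataFrame({
        "index": variants.index[dropped],
        "stage": "qc",
        "reason": reasons[dropped].to_numpy(),
    })
    return variants[~dropped].copy(), report


def aggregate_counts(variants: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-variant NV/NR summed over all samples of the patient."""
    nv = variants[[f"NV_{s}" for s in samples]].sum(axis=1)
    nr = variants[[f"NR_{s}" for s in samples]].sum(axis=1)
    return pd.DataFrame({"NV": nv, "NR": nr})


def binomial_germline_test(
    agg: pd.DataFrame,
    alpha: float = 1e-5,
    mid_p: bool = False,
) -> pd.DataFrame:
    """One-sided exact binomial test of NV ~ Binomial(NR, 0.5).

    The lower-tail p-value P(X <= NV) is small when the aggregate VAF is far
    below the heterozygous germline expectation of 0.5 — the pattern of a
    somatic mutation confined to a few crypts.  Variants with p < alpha
    (default 1e-5, a Bonferroni-style threshold) are labelled
    ``somatic-candidate``; the rest ``germline``.  Records with NR = 0 are
    skipped with label ``undefined``.

    ``mid_p`` subtracts half the point mass, P(X <= NV) - pmf(NV)/2: the
    exact-tail p-value of a discrete statistic is super-uniform
    (conservative) under the null, while the mid-p version is calibrated
    (approximately Uniform(0,1)); classification defaults to the exact tail.
    """
    nv = agg["NV"].to_numpy()
    nr = agg["NR"].to_numpy()
    p = np.ones(len(agg))
    ok = nr > 0
    p[ok] = binom.cdf(nv[ok], nr[ok], 0.5)
    if mid_p:
        p[ok] -= 0.5 * binom.pmf(nv[ok], nr[ok], 0.5)
    label = np.where(~ok, "undefined",
                     np.where(p < alpha, "somatic-candidate", "germline"))
    return pd.DataFrame({"p": p, "label": label}, index=agg.index)


def _betabinom_nll(log10_rho: float, nv: np.ndarray, nr: np.ndarray, mu: float) -> float:
    rho = 10.0 ** log10_rho
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return -betabinom.logpmf(nv, nr, a, b).sum()


def beta_binomial_rho(nv: np.ndarray, nr: np.ndarray,
                      bounds: tuple[float, float] = (-6.0, -0.05),
                      grid: int = 25) -> tuple[float, float]:
    """Maximum-likelihood overdispersion rho with the beta-binomial mean
    fixed to the pooled VAF; grid scan on log10(rho) refined by bounded
    golden-section search.  Returns (rho, loglik)."""
    nv = np.asarray(nv)
    nr = np.asarray(nr)
    keep = nr > 0
    nv, nr = nv[keep], nr[keep]
    if len(nr) < 2:
        raise ValueError("need >= 2 samples with coverage")
    mu = nv.sum() / nr.sum()
    if mu <= 0 or mu >= 1:
        # no heterogeneity possible; rho pinned to the lower bound
        return 10.0 ** bounds[0], 0.0
    xs = np.linspace(bounds[0], bounds[1], grid)
    nlls = [_betabinom_nll(x, nv, nr, mu) for x in xs]
    i = int(np.argmin(nlls))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, grid - 1)]
    res = minimize_scalar(_betabinom_nll, bounds=(lo, hi), args=(nv, nr, mu),
                          method="bounded", options={"xatol": 1e-6})
    return float(10.0 ** res.x), float(-res.fun)


def beta_binomial_filter(
    variants: pd.DataFrame,
    samples: list[str],
    rho_threshold: float = 0.1,
) -> list[BetaBinomialResult]:
    """Classify each variant by its cross-crypt overdispersion."""
    out = []
    nv_cols = [f"NV_{s}" for s in samples]
    nr_cols = [f"NR_{s}" for s in samples]
    for idx, row in variants.iterrows():
        rho, ll = beta_binomial_rho(row[nv_cols].to_numpy(dtype=float),
                                    row[nr_cols].to_numpy(dtype=float))
        cls = "genuine" if rho > rho_threshold else "rejected"
        out.append(BetaBinomialResult(idx, rho, ll, cls))
    return out


def filter_chain(
    variants: pd.DataFrame,
    samples: list[str],
    alpha: float = 1e-5,
    rho_threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QC -> exact binomial germline test -> beta-binomial rho filter.

    Returns (retained somatic variants, per-record filter report).
    """
    kept, report = qc_filter(variants)
    if kept.empty:
        return kept, report
    agg = aggregate_counts(kept, samples)
    bin_res = binomial_germline_test(agg, alpha=alpha)
    germ = bin_res["label"] == "germline"
    rep2 = pd.DataFrame({"index": kept.index[germ], "stage": "binomial",
                         "reason": "germline_vaf"})
    kept = kept[bin_res["label"] == "somatic-candidate"]
    bb = beta_binomial_filter(kept, samples, rho_threshold=rho_threshold)
    rejected = [r.variant for r in bb if r.classification == "rejected"]
    rep3 = pd.DataFrame({"index": rejected, "stage": "beta_binomial",
                         "reason": "low_overdispersion"})
    kept = kept.drop(index=rejected)
    report = pd.concat([report, rep2, rep3], ignore_index=True)
    return kept, report


def arch_filter(
    deep_variants: pd.DataFrame,
    vaf_bounds: tuple[float, float] = (0.005, 0.42),
    reporting_vaf: float = 0.02,
) -> pd.DataFrame:
    """Deep targeted-sequencing (ARCH) candidate filter.

    Retains protein-altering variants with >= 2 supporting reads on each
    strand and VAF inside [0.005, 0.42] (above: germline; below: probable
    false positive), and flags whether each candidate clears the standard
    2% VAF reporting threshold.
    """
    df = deep_variants.copy()
    vaf = df["NV"] / df["NR"]
    keep = (
        (df["fwd"] >= 2)
        & (df["rev"] >= 2)
        & (vaf >= vaf_bounds[0])
        & (vaf <= vaf_bounds[1])
        & df["consequence"].isin(["missense", "nonsynonymous", "stop-gain"])
    )
    out = df[keep].copy()
    out["VAF"] = vaf[keep]
    out["above_reporting_threshold"] = out["VAF"] > reporting_vaf
    return out
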