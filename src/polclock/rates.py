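"""Mutation-rate estimation and mutational age.

Per-crypt burdens accumulate roughly linearly with age, with shared
within-patient deviations, so the per-genotype rate is the fixed age slope of
a linear mixed model (age fixed effect, patient random intercept, REML); the
95% CI is the Wald interval on the slope.  Mutational age scales
chronological age by the ratio of the carrier rate to the wild-type rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import wilcoxon


@dataclass
class RateFit:
    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    intercept: float
    n_records: int
    n_patients: int
    method: str
    random_effects: dict | None = None
    marginal_r2: float | None = None


def fit_rate_lme(
    records: pd.DataFrame,
    response: str = "burden",
    random_slope: bool = False,
) -> RateFit:
    """Fixed-effect accumulation rate (response per year) by REML.

    ``records`` needs columns ``age``, ``patient`` and the response.  With a
    single patient the model degenerates and the fit falls back to OLS with
    a warning.  A free intercept is fitted (burden at age 0 reflects
    embryonic/developmental mutations).
    """
    df = records.dropna(subset=["age", "patient", response]).copy()
    if len(df) < 3:
        raise ValueError("need at least 3 records")
    if df["age"].nunique() < 2:
        raise ValueError("all ages equal: slope unidentifiable")
    n_patients = df["patient"].nunique()

    if n_patients < 2:
        warnings.warn("single patient: falling back to ordinary least squares")
        X = sm.add_constant(df["age"])
        fit = sm.OLS(df[response], X).fit()
        ci = fit.conf_int().loc["age"]
        return RateFit(float(fit.params["age"]), float(ci[0]), float(ci[1]),
                       float(fit.pvalues["age"]), float(fit.params["const"]),
                       len(df), 1, "ols")

    re_formula = "~age" if random_slope else "~1"
    # standardise the response for numerical stability (burdens reach 1e4
    # while variance parameters are optimised on unit scale), then map the
    # slope back
    s_y = float(df[response].std()) or 1.0
    work = df.copy()
    work["_y"] = work[response] / s_y
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("_y ~ age", work, groups=work["patient"],
                            re_formula=re_formula)
        # optimisers can diverge when the between-patient variance hits the
        # boundary (llf becomes inf with a spurious slope); keep the best
        # finite-likelihood candidate
        best_llf = -np.inf
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            llf = float(cand.llf)
            if np.isfinite(llf) and np.isfinite(cand.bse["age"]) and llf > best_llf:
                fit, best_llf = cand, llf
    if fit is None:
        raise RuntimeError("mixed-model fit failed for all optimisers")
    slope = float(fit.params["age"]) * s_y
    se = float(fit.bse["age"]) * s_y
    # t-quantile with df = patients - 2: the slope's information is
    # between-patient, so the normal interval undercovers at cohort sizes
    # of a handful of carriers
    from scipy.stats import t as t_dist

    z = float(t_dist.ppf(0.975, max(n_patients - 2, 1)))
    var_fixed = np.var(fit.predict(work))
    var_re = float(np.trace(np.atleast_2d(fit.cov_re)))
    resid_var = float(fit.scale)
    r2m = var_fixed / (var_fixed + var_re + resid_var)
    return RateFit(
        slope=slope,
        ci_low=slope - z * se,
        ci_high=slope + z * se,
        p_value=float(fit.pvalues["age"]),
        intercept=float(fit.params["Intercept"]) * s_y,
        n_records=len(df),
        n_patients=n_patients,
        method="lmm-reml",
        random_effects=_safe_random_effects(fit),
        marginal_r2=float(r2m),
    )


def _safe_random_effects(fit):
    # singular RE covariance (no detectable between-patient variance) makes
    # BLUPs unavailable; the fixed effects remain valid
    try:
        return {k: v.to_dict() for k, v in fit.random_effects.items()}
    except (ValueError, np.linalg.LinAlgError):
        return None


def mutational_age(rate_case: float, rate_wildtype: float, chrono_age: float) -> float:
    """Chronological age scaled by the observed/wild-type rate ratio."""
    if rate_wildtype <= 0 or chrono_age <= 0 or rate_case < 0:
        raise ValueError("rates and age must be positive")
    return chrono_age * rate_case / rate_wildtype


def coding_vs_genome(paired_fractions: pd.DataFrame) -> dict:
    """Compare polymerase-signature mutation fractions genome-wide vs coding.

    ``paired_fractions`` has columns ``genome`` and ``exome`` (one row per
    unit).  Returns the per-unit fractions, their means and a two-sided
    Wilcoxon signed-rank p-value (exact for small n); with fewer than 3
    pairs the test is skipped.
    """
    g = paired_fractions["genome"].to_numpy(dtype=float)
    e = paired_fractions["exome"].to_numpy(dtype=float)
    out = {
        "n_pairs": len(g),
        "mean_genome": float(np.mean(g)) if len(g) else np.nan,
        "mean_exome": float(np.mean(e)) if len(e) else np.nan,
        "p_value": None,
    }
    if len(g) >= 3:
        diffs = g - e
        if np.allclose(diffs, 0):
            out["p_value"] = 1.0
        else:
            mode = "exact" if len(g) <= 25 and not np.any(diffs == 0) else "auto"
            stat, p = wilcoxon(g, e, alternative="two-sided", mode=mode)
            out["p_value"] = float(p)
            out["statistic"] = float(stat)
    return out
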