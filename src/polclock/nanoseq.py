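"""Duplex-sequencing trinucleotide burden correction.

Restriction-digest duplex libraries interrogate the genome with uneven
trinucleotide composition, and SNP-site masking further distorts it.  Since
substitution rates depend strongly on trinucleotide context, raw burdens are
biased.  The correction projects the observed counts back onto genomic
composition:

    f_i      = t_i / sum_i t_i        (frequency, genome and experiment)
    r_i      = f_i^genome / f_i^experiment
    s'_ij    = s_ij * r_i             (corrected substitution counts)
    beta'    = sum_ij s'_ij / sum_i t_i

The burden denominator uses the experimentally interrogated bases t^e: the
numerator's counts arise from those bases and r_i reprojects only the
composition, so scaling both by the same library size leaves beta'
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import TRINUC_32


@dataclass
class DuplexCounts:
    t_genome: np.ndarray                       # 32-vector
    t_exp: np.ndarray                          # 32-vector
    s: np.ndarray                              # 32 x 6 substitution counts
    f_genome: np.ndarray | None = None
    f_exp: np.ndarray | None = None
    r: np.ndarray | None = None
    s_corrected: np.ndarray | None = None
    burden: float | None = None
    raw_burden: float | None = None


def trinuc_frequencies(t: np.ndarray) -> np.ndarray:
    """f_i = t_i / sum(t)."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("negative trinucleotide counts")
    total = t.sum()
    if total <= 0:
        raise ValueError("all-zero trinucleotide counts")
    return t / total


def correction_ratios(f_genome: np.ndarray, f_exp: np.ndarray,
                      s: np.ndarray | None = None) -> np.ndarray:
    """r_i = f_i^genome / f_i^experiment.

    Contexts never interrogated (f_exp = 0) get r = 0 with a warning when
    they also carry no substitution counts; interrogated counts at an
    uninterrogated context are contradictory and raise.
    """
    import warnings

    f_genome = np.asarray(f_genome, dtype=float)
    f_exp = np.asarray(f_exp, dtype=float)
    r = np.zeros_like(f_genome)
    ok = f_exp > 0
    r[ok] = f_genome[ok] / f_exp[ok]
    if (~ok).any():
        if s is not None and np.asarray(s)[~ok].sum() > 0:
            bad = [TRINUC_32[i] for i in np.nonzero(~ok)[0]]
            raise ValueError(f"substitution counts in uninterrogated contexts: {bad}")
        warnings.warn("contexts with zero experimental frequency get r=0")
    return r


def correct_burden(d: DuplexCounts) -> DuplexCounts:
    """Fill a DuplexCounts with frequencies, ratios, corrected spectrum and
    the corrected per-base burden beta'."""
    d.f_genome = trinuc_frequencies(d.t_genome)
    d.f_exp = trinuc_frequencies(d.t_exp)
    d.r = correction_ratios(d.f_genome, d.f_exp, d.s)
    d.s_corrected = d.s * d.r[:, None]
    denom = d.t_exp.sum()
    d.burden = float(d.s_corrected.sum() / denom)
    d.raw_burden = float(d.s.sum() / denom)
    return d
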