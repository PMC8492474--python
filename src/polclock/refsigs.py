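"""Synthetic stand-in reference signatures.

These are NOT the COSMIC probability vectors: they are synthetic profiles
constructed in-package that reproduce the qualitative channel concentrations
by which each process is recognised — SBS1 as C>T at NpCpG (5-methylcytosine
deamination), SBS5 as a flat clock-like profile, SBS10a/b as the Pol epsilon
proofreading-deficiency peaks (C>A at TpCpT, C>T at TpCpG/TpCpT), SBS10c/d as
the Pol delta counterparts (C>A at ACC/CCA/CCT/TCA/TCT and TCA/TCT
respectively), SBS28 as T>G at TpTpT, and ID1 as 1-bp T insertions at long T
homopolymers.  They serve as planted ground truth for extraction/refitting
recovery experiments; nothing in the package depends on the exact COSMIC
vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reference import CHANNELS_96, CHANNEL_INDEX

# 24-channel reduced indel classification: 1-bp insertions/deletions split by
# base (T vs other) and homopolymer run length (1,2,3,4,>=5), plus aggregates
# for >=2-bp events and unclassifiable records.
ID_CHANNELS = tuple(
    f"{kind}_{base}_hp{run}"
    for kind in ("ins", "del")
    for base in ("T", "other")
    for run in ("1", "2", "3", "4", "5+")
) + ("ins_multi", "del_multi", "ins_other", "del_other")
ID_CHANNEL_INDEX = {c: i for i, c in enumerate(ID_CHANNELS)}


def _profile(peaks: dict[str, float], floor: float = 0.05) -> np.ndarray:
    """Probability vector with ``peaks`` mass on named channels and a
    uniform floor spread over the remaining channels."""
    v = np.zeros(96)
    for ch, w in peaks.items():
        v[CHANNEL_INDEX[ch]] = w
    rest = [i for i in range(96) if v[i] == 0]
    v[rest] = floor * sum(peaks.values()) / (1 - floor) / len(rest) if peaks else 1 / 96
    return v / v.sum()


def _spread(sub: str, weight_by_flank: dict[tuple[str, str], float]) -> dict[str, float]:
    return {f"{f5}[{sub}]{f3}": w for (f5, f3), w in weight_by_flank.items()}


def synthetic_sbs_signatures() -> pd.DataFrame:
    """96 x signatures DataFrame of the synthetic stand-in profiles."""
    sigs = {}
    # SBS1: C>T at NpCpG
    sigs["SBS1"] = _profile(
        {f"{f5}[C>T]G": 0.22 for f5 in "ACGT"}, floor=0.12
    )
    # SBS5: flat clock-like, mild enrichment of T>C
    v = np.full(96, 1.0)
    for f5 in "ACGT":
        for f3 in "ACGT":
            v[CHANNEL_INDEX[f"{f5}[T>C]{f3}"]] = 2.0
    sigs["SBS5"] = v / v.sum()
    # SBS10a: C>A at TpCpT (dominant) and TpCpA
    sigs["SBS10a"] = _profile({"T[C>A]T": 0.55, "T[C>A]A": 0.15}, floor=0.08)
    # SBS10b: C>T at TpCpG and TpCpT
    sigs["SBS10b"] = _profile({"T[C>T]G": 0.40, "T[C>T]T": 0.30}, floor=0.08)
    # SBS10c: C>A at ACC, CCA, CCT, TCA, TCT
    sigs["SBS10c"] = _profile(
        {
            "A[C>A]C": 0.14,
            "C[C>A]A": 0.14,
            "C[C>A]T": 0.14,
            "T[C>A]A": 0.17,
            "T[C>A]T": 0.17,
        },
        floor=0.10,
    )
    # SBS10d: C>A at TCA and TCT only
    sigs["SBS10d"] = _profile({"T[C>A]A": 0.40, "T[C>A]T": 0.45}, floor=0.05)
    # SBS28: T>G at TpTpT
    sigs["SBS28"] = _profile({"T[T>G]T": 0.55, "C[T>G]T": 0.12}, floor=0.10)
    df = pd.DataFrame(sigs, index=list(CHANNELS_96))
    return df


def synthetic_id_signatures() -> pd.DataFrame:
    """24-channel indel stand-ins: ID1-like (T insertions at T homopolymers)
    and a flat background."""
    id1 = np.zeros(len(ID_CHANNELS))
    id1[ID_CHANNEL_INDEX["ins_T_hp5+"]] = 0.55
    id1[ID_CHANNEL_INDEX["ins_T_hp4"]] = 0.25
    id1[ID_CHANNEL_INDEX["ins_T_hp3"]] = 0.12
    id1[ID_CHANNEL_INDEX["ins_T_hp2"]] = 0.05
    id1[ID_CHANNEL_INDEX["ins_T_hp1"]] = 0.03
    flat = np.full(len(ID_CHANNELS), 1.0 / len(ID_CHANNELS))
    return pd.DataFrame({"ID1": id1 / id1.sum(), "ID_flat": flat}, index=list(ID_CHANNELS))
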