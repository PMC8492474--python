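"""Germline/artifact separation: QC thresholds, exact binomial, beta-binomial
overdispersion and ARCH deep-sequencing filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import betabinom

from polclock import filtering, simulate as sim
from polclock.filtering import (
    BetaBinomialResult,
    SchemaError,
    arch_filter,
    beta_binomial_rho,
    binomial_germline_test,
    qc_filter,
)


def _vrow(vclass="SBS", asmd=160, clip=0.0, pon=False, qual=400.0, depth=30,
          **extra):
    row = dict(chrom="c", pos=1, ref="A", alt="T", vclass=vclass, asmd=asmd,
               clip_med=clip, pon=pon, indel_qual=qual, site_depth=depth,
               NV_a=10, NR_a=30, NV_b=0, NR_b=30)
    row.update(extra)
    return row


class TestQcFilter:
    @pytest.mark.parametrize("kwargs,kept,reason", [
        (dict(asmd=139), False, "alignment_score"),
        (dict(asmd=140), True, None),
        (dict(clip=1.0), False, "clipped_reads"),
        (dict(pon=True), False, "panel_of_normals"),
        (dict(vclass="ID", qual=300.0, depth=15), True, None),
        (dict(vclass="ID", qual=299.0), False, "indel_quality"),
        (dict(vclass="ID", depth=14), False, "indel_depth"),
    ])
    def test_thresholds(self, kwargs, kept, reason):
        df = pd.DataFrame([_vrow(**kwargs)])
        out, rep = qc_filter(df)
        assert (len(out) == 1) == kept
        if not kept:
            assert rep["reason"].iloc[0] == reason

    def test_empty_table(self):
        out, rep = qc_filter(pd.DataFrame())
        assert out.empty and rep.empty

    def test_missing_fields_schema_error(self):
        with pytest.raises(SchemaError):
            qc_filter(pd.DataFrame([{"vclass": "SBS", "asmd": 150}]))

    def test_one_primary_reason_per_dropped_record(self):
        df = pd.DataFrame([_vrow(asmd=100, clip=1.0, pon=True)])
        out, rep = qc_filter(df)
        assert len(rep) == 1 and rep["reason"].iloc[0] == "alignment_score"


def binom_tail_oracle(nv, nr):
    """Direct lower-tail summation of the binomial pmf at p = 0.5."""
    from math import comb

    return sum(comb(nr, k) for k in range(nv + 1)) * 0.5**nr


class TestBinomialGermlineTest:
    def test_matches_tail_summation_oracle(self):
        cases = [(170, 340), (34, 340), (0, 12), (7, 15), (150, 340)]
        agg = pd.DataFrame({"NV": [c[0] for c in cases],
                            "NR": [c[1] for c in cases]})
        res = binomial_germline_test(agg)
        for (nv, nr), p in zip(cases, res["p"]):
            assert p == pytest.approx(binom_tail_oracle(nv, nr), rel=1e-9)

    def test_germline_depth_labels(self):
        agg = pd.DataFrame({"NV": [170, 0, 34], "NR": [340, 340, 340]})
        res = binomial_germline_test(agg)
        assert res["label"].tolist() == ["germline", "somatic-candidate",
                                         "somatic-candidate"]
        assert res["p"].iloc[0] > 0.4
        assert res["p"].iloc[1] == pytest.approx(0.5**340)
        assert res["p"].iloc[2] < 1e-20

    def test_zero_depth_undefined(self):
        res = binomial_germline_test(pd.DataFrame({"NV": [0], "NR": [0]}))
        assert res["label"].iloc[0] == "undefined"

    def test_midp_uniform_under_germline_null(self, rng):
        # p-values Uniform(0,1) at the aggregate ~340x germline regime
        from scipy.stats import kstest

        nr = rng.poisson(340, 5000)
        nv = rng.binomial(nr, 0.5)
        res = binomial_germline_test(pd.DataFrame({"NV": nv, "NR": nr}),
                                     mid_p=True)
        assert kstest(res["p"], "uniform").pvalue > 0.01


def dense_grid_rho_oracle(nv, nr):
    """Independent dense-grid ML search for the fixed-mean beta-binomial."""
    nv, nr = np.asarray(nv), np.asarray(nr)
    mu = nv.sum() / nr.sum()
    best, best_ll = None, -np.inf
    for lr in np.linspace(-6, -0.05, 4000):
        rho = 10.0**lr
        a = mu * (1 - rho) / rho
        b = (1 - mu) * (1 - rho) / rho
        ll = betabinom.logpmf(nv, nr, a, b).sum()
        if ll > best_ll:
            best, best_ll = rho, ll
    return best


class TestBetaBinomial:
    @pytest.mark.parametrize("nv,nr,genuine", [
        ((10, 0, 0, 15), (30, 30, 28, 31), True),
        ((14, 16, 15, 13), (30, 31, 29, 30), False),
    ])
    def test_matches_dense_grid_oracle(self, nv, nr, genuine):
        rho, _ = beta_binomial_rho(np.array(nv), np.array(nr))
        oracle = dense_grid_rho_oracle(nv, nr)
        assert rho == pytest.approx(oracle, rel=0.05, abs=1e-5)
        assert (rho > 0.1) == genuine

    def test_identical_counts_pin_rho_at_lower_bound(self):
        rho, _ = beta_binomial_rho(np.array([15, 15, 15, 15]),
                                   np.array([30, 30, 30, 30]))
        assert rho < 1e-3

    def test_all_zero_nv_rejected(self):
        rho, _ = beta_binomial_rho(np.zeros(4, int), np.full(4, 30))
        assert rho == pytest.approx(1e-6)

    def test_rho_monotone_in_cross_sample_variance(self):
        # family with pooled VAF fixed at 0.25, increasing spread
        nr = np.full(4, 40)
        rhos = []
        for spread in (0, 4, 8, 10):
            nv = np.array([10 - spread, 10 + spread, 10 - spread, 10 + spread])
            rhos.append(beta_binomial_rho(nv, nr)[0])
        assert all(a <= b + 1e-9 for a, b in zip(rhos, rhos[1:]))

    def test_requires_two_covered_samples(self):
        with pytest.raises(ValueError):
            beta_binomial_rho(np.array([3]), np.array([30]))


class TestArchFilter:
    def _df(self, vaf, fwd=3, rev=3, csq="missense"):
        nr = 10_000
        return pd.DataFrame([dict(NV=int(vaf * nr), NR=nr, fwd=fwd, rev=rev,
                                  consequence=csq)])

    def test_germline_vaf_removed(self):
        assert arch_filter(self._df(0.43)).empty

    def test_low_vaf_false_positive_removed(self):
        assert arch_filter(self._df(0.004)).empty

    def test_low_but_valid_vaf_flagged_below_reporting(self):
        out = arch_filter(self._df(0.01, fwd=2, rev=2))
        assert len(out) == 1
        assert not out["above_reporting_threshold"].iloc[0]

    def test_strand_support_required(self):
        assert arch_filter(self._df(0.05, fwd=1, rev=5)).empty

    def test_synonymous_removed(self):
        assert arch_filter(self._df(0.05, csq="synonymous")).empty


def test_filter_chain_recovers_somatic_and_blocks_germline(ref_genes):
    cfg = sim.CohortConfig(
        patients=[sim.PatientConfig("P", 50.0, "POLE_L424V", n_crypts=10)],
        sbs_rate={**sim.SBS_RATE, "POLE_L424V": 30.0},
        id_rate={**sim.ID_RATE, "POLE_L424V": 4.0},
        germline_het=400, germline_hom=100, seed=2)
    truth = sim.simulate_cohort(ref_genes, cfg)
    vt = sim.simulate_reads(truth, "P", 30, seed=3, ref=ref_genes)
    kept, rep = filtering.filter_chain(vt, truth.samples["P"])
    som = vt[(vt["truth"] == "somatic") & (vt["vclass"] == "SBS")]
    kept_som = kept[(kept["truth"] == "somatic") & (kept["vclass"] == "SBS")]
    assert len(kept_som) / len(som) >= 0.99
    germ = vt[vt["truth"] == "germline"]
    leaked = kept[kept["truth"] == "germline"]
    assert len(leaked) / len(germ) <= 0.001
    # exactly one primary reason per dropped record
    assert rep["index"].is_unique


def test_beta_binomial_separates_germline_from_mosaic(rng):
    # paper-like depths: 10 crypts at ~30x
    correct = 0
    n = 200
    for i in range(n):
        nr = rng.poisson(30, 10).clip(min=1)
        if i % 2 == 0:
            nv = rng.binomial(nr, 0.5)
            want = "rejected"
        else:
            present = rng.permutation([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
            nv = rng.binomial(nr, 0.5 * present)
            want = "genuine"
        rho, _ = beta_binomial_rho(nv, nr)
        got = "genuine" if rho > 0.1 else "rejected"
        correct += got == want
    assert correct / n >= 0.99
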