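"""Catalogs, de novo extraction, constrained refitting and strand bias."""

import numpy as np
import pandas as pd
import pytest

from polclock import refsigs, signatures as sig
from polclock.reference import CHANNELS_96, build_reference
from polclock.signatures import SignatureModel, cosine


def _multinomial_catalog(profile: np.ndarray, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, profile / profile.sum()).astype(float)


class TestCatalogs:
    def test_channel_assignment_and_collapse(self, ref_small):
        seq = ref_small.chromosomes["chr1"]
        # find an ACG site (C centre) and a CGT site (G centre)
        pos_c = seq.find("ACG") + 1
        pos_g = seq.find("CGT") + 1
        muts = pd.DataFrame([
            dict(chrom="chr1", pos=pos_c, ref="C", alt="T"),
            dict(chrom="chr1", pos=pos_g, ref="G", alt="A"),
        ])
        cat = sig.sbs_catalog(muts, ref_small)
        assert cat[CHANNELS_96.index("A[C>T]G")] == 2
        assert cat.sum() == 2

    def test_reference_mismatch_excluded_with_warning(self, ref_small):
        seq = ref_small.chromosomes["chr1"]
        pos = seq.find("ACA") + 1
        muts = pd.DataFrame([dict(chrom="chr1", pos=pos, ref="G", alt="T")])
        with pytest.warns(UserWarning):
            cat = sig.sbs_catalog(muts, ref_small)
        assert cat.sum() == 0

    def test_single_signature_catalog_cosine(self, sbs_sigs):
        v = sbs_sigs["SBS10b"].to_numpy()
        cat = _multinomial_catalog(v, 1000, seed=1)
        assert cosine(cat, v) >= 0.95


class TestPrepareUnits:
    def _cats(self, totals):
        rng = np.random.default_rng(0)
        rows = {f"u{i}": rng.multinomial(t, np.full(96, 1 / 96)).astype(float)
                for i, t in enumerate(totals)}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(CHANNELS_96))

    def test_exclusion_and_subsampling_boundaries(self):
        cats = self._cats([99, 100, 2500, 2501])
        out = sig.prepare_units(cats, seed=1)
        assert "u0" not in out.index                  # 99 -> excluded
        assert out.loc["u1"].sum() == 100             # boundary retained
        assert out.loc["u2"].sum() == 2500            # unchanged
        assert out.loc["u3"].sum() == 2500            # downsampled exactly

    def test_subsampling_is_without_replacement(self):
        cats = self._cats([3000])
        out = sig.prepare_units(cats, seed=2)
        assert (out.to_numpy() <= cats.to_numpy()).all()

    def test_seeded_and_deterministic(self):
        cats = self._cats([5000])
        a = sig.prepare_units(cats, seed=3)
        b = sig.prepare_units(cats, seed=3)
        pd.testing.assert_frame_equal(a, b)


def _planted_units(sbs_sigs, names, n_units=30, muts=2000, seed=0):
    rng = np.random.default_rng(seed)
    profiles = sbs_sigs[names].to_numpy().T
    rows = []
    mixes = []
    for _ in range(n_units):
        mix = rng.dirichlet(np.ones(len(names)))
        p = mix @ profiles
        rows.append(rng.multinomial(muts, p).astype(float))
        mixes.append(mix)
    cats = pd.DataFrame(rows, index=[f"u{i}" for i in range(n_units)],
                        columns=list(CHANNELS_96))
    return cats, np.array(mixes)


class TestExtractDenovo:
    def test_three_planted_signatures_recovered(self, sbs_sigs):
        names = ["SBS1", "SBS10a", "SBS10c"]
        cats, _ = _planted_units(sbs_sigs, names, seed=1)
        model = sig.extract_denovo(cats, k_range=range(2, 5), n_restarts=6,
                                   seed=2)
        assert model.profiles.shape[1] == 3
        hits = set()
        for name in names:
            cs = [cosine(model.profiles[c].to_numpy(),
                         sbs_sigs[name].to_numpy())
                  for c in model.profiles.columns]
            best = int(np.argmax(cs))
            assert max(cs) >= 0.95
            hits.add(best)
        assert len(hits) == 3  # each planted signature matched by a distinct one

    def test_single_signature_selects_k1(self, sbs_sigs):
        rng = np.random.default_rng(3)
        v = sbs_sigs["SBS10b"].to_numpy()
        cats = pd.DataFrame(
            [rng.multinomial(2000, v).astype(float) for _ in range(10)],
            index=[f"u{i}" for i in range(10)], columns=list(CHANNELS_96))
        model = sig.extract_denovo(cats, k_range=range(1, 4), n_restarts=5,
                                   seed=4)
        assert model.profiles.shape[1] == 1
        assert cosine(model.profiles.iloc[:, 0].to_numpy(), v) >= 0.99

    def test_unit_order_invariance(self, sbs_sigs):
        cats, _ = _planted_units(sbs_sigs, ["SBS1", "SBS10a"], n_units=10,
                                 seed=5)
        m1 = sig.extract_denovo(cats, k_range=[2], n_restarts=4, seed=6)
        m2 = sig.extract_denovo(cats.iloc[::-1], k_range=[2], n_restarts=4,
                                seed=6)
        sims = np.array([[cosine(m1.profiles[a].to_numpy(),
                                 m2.profiles[b].to_numpy())
                          for b in m2.profiles.columns]
                         for a in m1.profiles.columns])
        assert (sims.max(axis=1) > 0.98).all()

    def test_k_range_exceeding_units_errors(self, sbs_sigs):
        cats, _ = _planted_units(sbs_sigs, ["SBS1"], n_units=3, seed=7)
        with pytest.raises(ValueError):
            sig.extract_denovo(cats, k_range=[5], seed=1)


class TestFitExposures:
    def _model(self, sbs_sigs, names=("SBS1", "SBS5", "SBS10a", "SBS10b", "SBS28")):
        prof = sbs_sigs[list(names)]
        return SignatureModel(prof, {n: "reference" for n in names})

    def test_exact_single_signature_catalog(self, sbs_sigs):
        model = self._model(sbs_sigs, ("SBS1", "SBS5"))
        cat = pd.DataFrame([1000 * sbs_sigs["SBS1"].to_numpy()],
                           index=["u"], columns=list(CHANNELS_96))
        exp = sig.fit_exposures(cat, model, allowed=["SBS1", "SBS5"])
        assert exp.loc["u", "SBS1"] == pytest.approx(1000, rel=0.01)
        assert exp.loc["u", "SBS5"] == pytest.approx(0, abs=10)
        assert exp.loc["u", "recon_cosine"] >= 0.99

    def test_zero_catalog_zero_exposures(self, sbs_sigs):
        model = self._model(sbs_sigs)
        cat = pd.DataFrame([np.zeros(96)], index=["u"],
                           columns=list(CHANNELS_96))
        exp = sig.fit_exposures(cat, model)
        assert (exp[model.names()].to_numpy() == 0).all()

    def test_pole_mixture_fractions_recovered(self, sbs_sigs):
        weights = {"SBS10a": 0.45, "SBS10b": 0.35, "SBS28": 0.05,
                   "SBS1": 0.10, "SBS5": 0.05}
        mix = sum(w * sbs_sigs[n].to_numpy() for n, w in weights.items())
        cat = pd.DataFrame([_multinomial_catalog(mix, 3000, seed=8)],
                           index=["u"], columns=list(CHANNELS_96))
        model = self._model(sbs_sigs)
        exp = sig.fit_exposures(cat, model)
        total = exp.loc["u", model.names()].sum()
        for n, w in weights.items():
            assert exp.loc["u", n] / total == pytest.approx(w, abs=0.05)

    def test_disallowed_signatures_exactly_zero(self, sbs_sigs):
        model = self._model(sbs_sigs)
        cat = pd.DataFrame([_multinomial_catalog(
            sbs_sigs["SBS10a"].to_numpy(), 500, seed=9)],
            index=["u"], columns=list(CHANNELS_96))
        exp = sig.fit_exposures(cat, model, allowed=["SBS10a", "SBS5"])
        assert exp.loc["u", "SBS10b"] == 0.0
        assert exp.loc["u", "SBS28"] == 0.0

    def test_empty_allowed_set_errors(self, sbs_sigs):
        model = self._model(sbs_sigs)
        cat = pd.DataFrame([np.ones(96)], index=["u"],
                           columns=list(CHANNELS_96))
        with pytest.raises(ValueError):
            sig.fit_exposures(cat, model, allowed=[])


class TestStrandBias:
    def _ref(self):
        # alternate leading/lagging every 5 kb on a 50 kb chromosome
        return build_reference(11, {"chr1": 50_000}, n_genes=0,
                               replication_segment=5_000)

    def _mutations(self, ref, rng, n=4000, leading_bias=1.0):
        """C>A mutations at C sites, placed with a leading-template bias."""
        rows = []
        seq = ref.chromosomes["chr1"]
        c_pos = [i for i in range(1, len(seq) - 1) if seq[i] == "C"]
        while len(rows) < n:
            pos = c_pos[int(rng.integers(len(c_pos)))]
            strand = ref.replication_strand("chr1", pos)
            accept = 1.0 if strand == "leading" else 1.0 / leading_bias
            if rng.random() < accept:
                rows.append(dict(chrom="chr1", pos=pos, ref="C", alt="A",
                                 vclass="SBS"))
        return pd.DataFrame(rows)

    def test_uniform_null_no_bias(self, rng):
        ref = self._ref()
        muts = self._mutations(ref, rng, n=5000)
        tab = sig.replication_strand_bias(muts, ref)
        informative = tab[(tab["leading"] + tab["lagging"]) >= 20]
        assert np.median(np.abs(informative["log2_ratio"])) < 0.15
        from statsmodels.stats.multitest import multipletests

        rej = multipletests(tab["p"].to_numpy(), alpha=0.05,
                            method="fdr_bh")[0]
        assert rej.sum() == 0

    def test_planted_bias_recovered(self, rng):
        ref = self._ref()
        muts = self._mutations(ref, rng, n=6000, leading_bias=3.0)
        tab = sig.replication_strand_bias(muts, ref)
        informative = tab[(tab["leading"] + tab["lagging"]) >= 50]
        pooled = np.log2(informative["leading"].sum()
                         / informative["lagging"].sum())
        assert pooled == pytest.approx(np.log2(3.0), abs=0.3)

    def test_inverted_annotation_negates_ratios(self, rng):
        ref = self._ref()
        muts = self._mutations(ref, rng, n=2000, leading_bias=2.0)
        tab1 = sig.replication_strand_bias(muts, ref)
        ref.replication = [(c, s, e, "lagging" if l == "leading" else "leading")
                           for c, s, e, l in ref.replication]
        tab2 = sig.replication_strand_bias(muts, ref)
        assert np.allclose(tab1["log2_ratio"], -tab2["log2_ratio"])

    def test_no_annotated_mutations_empty_table(self, rng):
        ref = self._ref()
        ref.replication = []
        muts = self._mutations(self._ref(), rng, n=10)
        tab = sig.replication_strand_bias(muts, ref)
        assert tab.empty
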