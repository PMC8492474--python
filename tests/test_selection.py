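"""Context-corrected dN/dS, driver annotation, driver-burden comparison."""

import numpy as np
import pandas as pd
import pytest

from polclock import refsigs, selection as sel
from polclock.reference import Gene, ReferenceModel, trinuc_counts
from polclock.selection import (
    annotate_drivers,
    classify_impact,
    dnds_modified,
    driver_burden_test,
    expected_class_weights,
    simulate_coding_mutations,
)


def _toy_ref(cds_seq: str, flank: str = "AAAA") -> tuple[ReferenceModel, Gene]:
    seq = flank + cds_seq + flank
    gene = Gene("G1", "c", [(len(flank), len(flank) + len(cds_seq))], "+",
                "recessive")
    ref = ReferenceModel(chromosomes={"c": seq}, genes=[gene],
                         trinuc_genome=trinuc_counts(seq))
    return ref, gene


class TestClassifyImpact:
    def test_stop_gain(self):
        ref, gene = _toy_ref("CAAGGG")  # Q G
        pos = gene.cds[0][0]
        assert classify_impact({"pos": pos, "ref": "C", "alt": "T"},
                               gene, ref) == "nonsense"

    def test_synonymous(self):
        ref, gene = _toy_ref("GCTGGG")  # A G ; GCT->GCC still Ala
        pos = gene.cds[0][0] + 2
        assert classify_impact({"pos": pos, "ref": "T", "alt": "C"},
                               gene, ref) == "synonymous"

    def test_missense(self):
        ref, gene = _toy_ref("GCTGGG")  # GCT->GTT Ala->Val
        pos = gene.cds[0][0] + 1
        assert classify_impact({"pos": pos, "ref": "C", "alt": "T"},
                               gene, ref) == "missense"

    def test_frameshift_deletion(self):
        ref, gene = _toy_ref("ATG" + "GCT" * 99)
        pos = gene.cds[0][0] + 30
        v = {"pos": pos, "ref": ref.chromosomes["c"][pos: pos + 2],
             "alt": ref.chromosomes["c"][pos]}
        assert classify_impact(v, gene, ref) == "frameshift"

    def test_reverse_strand_uses_complement(self):
        # CDS on minus strand: genomic TTA at CDS start reads TAA... build
        # a gene whose minus-strand codon CAT (genomic ATG) mutates
        ref, gene = _toy_ref("CATGGG")
        gene.strand = "-"
        # minus-strand CDS = CCCATG ; genomic C>A at last CDS base changes
        # first codon position of minus strand
        pos = gene.cds[0][1] - 1  # genomic 'G'
        cls = classify_impact({"pos": pos, "ref": "G", "alt": "A"}, gene, ref)
        assert cls in {"missense", "nonsense", "synonymous"}

    def test_splice_region_and_outside(self):
        ref, gene = _toy_ref("ATGGCT")
        s, e = gene.cds[0]
        assert classify_impact({"pos": e + 1, "ref": "A", "alt": "T"},
                               gene, ref) == "splice"
        with pytest.raises(ValueError):
            classify_impact({"pos": e + 3, "ref": "A", "alt": "T"}, gene, ref)


def brute_force_expected(gene, ref, spectrum):
    """Independent per-site enumeration using Biopython translation."""
    from Bio.Seq import Seq

    from polclock.reference import (CHANNEL_INDEX, TRINUC_INDEX,
                                    collapse_context, sbs_channel)

    w = {"synonymous": 0.0, "missense": 0.0, "nonsense": 0.0}
    seq = ref.chromosomes[gene.chrom]
    s, e = gene.cds[0]
    cds = seq[s:e]
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    prot = str(Seq(cds).translate())
    for pos in range(s, e):
        tri = seq[pos - 1: pos + 2]
        ctx = ref.trinuc_genome[TRINUC_INDEX[collapse_context(tri)]]
        for alt in "ACGT":
            if alt == seq[pos]:
                continue
            p = spectrum[CHANNEL_INDEX[sbs_channel(tri, alt)]]
            if p == 0:
                continue
            mutated = seq[:pos] + alt + seq[pos + 1:]
            cds2 = mutated[s:e]
            if gene.strand == "-":
                cds2 = str(Seq(cds2).reverse_complement())
            prot2 = str(Seq(cds2).translate())
            if prot2 == prot:
                cls = "synonymous"
            elif any(b == "*" and a != "*" for a, b in zip(prot, prot2)):
                cls = "nonsense"
            else:
                cls = "missense"  # includes stop-loss
            w[cls] += p / ctx
    return w


class TestExpectedCounts:
    def test_matches_brute_force_enumeration_exactly(self, ref_genes):
        spectrum = np.full(96, 1 / 96)
        genes = ref_genes.genes[:3]
        got = expected_class_weights(genes, ref_genes, spectrum)
        for g in genes:
            oracle = brute_force_expected(g, ref_genes, spectrum)
            for cls in ("synonymous", "missense", "nonsense"):
                assert got.loc[g.name, cls] == pytest.approx(
                    oracle[cls], rel=1e-12)

    def test_tct_concentrated_spectrum_raises_nonsense_fraction(self):
        # TCA-rich toy gene: C>A at TCA creates TAA stops on the reverse
        # reading (TCA -> TAA at first codon position via complement) and
        # TCA->TAA directly when the C is codon position 2 of *CA
        cds = "TCATCATCATCATCATCATCATCATCATCA"
        ref, gene = _toy_ref(cds)
        uni = np.full(96, 1 / 96)
        from polclock.reference import CHANNEL_INDEX

        conc = np.zeros(96)
        conc[CHANNEL_INDEX["T[C>A]T"]] = 0.5
        conc[CHANNEL_INDEX["T[C>A]A"]] = 0.5
        w_uni = expected_class_weights([gene], ref, uni)
        w_conc = expected_class_weights([gene], ref, conc)

        def nonsense_frac(w):
            tot = w.loc["G1"].sum()
            return w.loc["G1", "nonsense"] / tot

        assert nonsense_frac(w_conc) > nonsense_frac(w_uni)

    def test_empty_gene_list(self, ref_genes):
        out = expected_class_weights([], ref_genes, np.full(96, 1 / 96))
        assert out.empty


@pytest.fixture(scope="module")
def setup(ref_genes):
    sigs = refsigs.synthetic_sbs_signatures()
    spectrum = (0.5 * sigs["SBS10a"] + 0.3 * sigs["SBS10b"]
                + 0.2 * sigs["SBS5"]).to_numpy()
    spectrum /= spectrum.sum()
    table = sel.enumerate_coding_substitutions(ref_genes.genes, ref_genes,
                                               spectrum)
    weights = expected_class_weights(ref_genes.genes, ref_genes, spectrum)
    return spectrum, table, weights


class TestDndsModified:

    def test_neutral_simulation_no_significant_genes(self, ref_genes, setup):
        spectrum, table, weights = setup
        muts = simulate_coding_mutations(ref_genes.genes, ref_genes, spectrum,
                                         2000, 40, seed=11, table=table)
        res = dnds_modified(muts, ref_genes.genes, ref_genes, spectrum,
                            weights=weights)
        assert res["significant"].sum() == 0

    def test_planted_driver_detected(self, ref_genes, setup):
        spectrum, table, weights = setup
        target = ref_genes.genes[5].name
        muts = simulate_coding_mutations(ref_genes.genes, ref_genes, spectrum,
                                         2500, 50, seed=12, table=table,
                                         driver_gene=target, driver_excess=10)
        res = dnds_modified(muts, ref_genes.genes, ref_genes, spectrum,
                            weights=weights)
        assert res.loc[target, "q"] < 0.05

    def test_observed_equals_expected_nothing_significant(self, ref_genes,
                                                          setup):
        spectrum, table, weights = setup
        # manufacture observations exactly proportional to expectation
        t = 500 / weights["synonymous"].sum()
        rows = []
        for g in ref_genes.genes:
            for cls in ("synonymous", "missense", "nonsense"):
                n = int(round(weights.loc[g.name, cls] * t))
                rows.extend(dict(sample=f"S{i % 10}", gene=g.name,
                                 chrom="chr1", pos=i, alt="T", impact=cls)
                            for i in range(n))
        res = dnds_modified(pd.DataFrame(rows), ref_genes.genes, ref_genes,
                            spectrum, weights=weights)
        assert res["significant"].sum() == 0
        assert (res[["p_missense", "p_nonsense"]].min(axis=1) >= 0.2).all()

    def test_context_correction_beats_naive_uniform_expectation(
            self, ref_genes, setup):
        """Under a polymerase spectrum, a uniform-rate expectation produces
        spurious selection hits the context correction avoids."""
        spectrum, table, weights = setup
        naive_weights = expected_class_weights(ref_genes.genes, ref_genes,
                                               np.full(96, 1 / 96))
        corrected_hits = naive_hits = 0
        for seed in range(5):
            muts = simulate_coding_mutations(ref_genes.genes, ref_genes,
                                             spectrum, 2500, 40,
                                             seed=100 + seed, table=table)
            res_c = dnds_modified(muts, ref_genes.genes, ref_genes, spectrum,
                                  weights=weights)
            res_n = dnds_modified(muts, ref_genes.genes, ref_genes, spectrum,
                                  weights=naive_weights, family="poisson")
            corrected_hits += int(res_c["significant"].sum())
            naive_hits += int(res_n["significant"].sum())
        assert naive_hits >= max(3 * corrected_hits, 1)

    def test_sample_caps_applied(self):
        rows = [dict(sample="hyper", gene=f"g{i % 3}", chrom="c", pos=i,
                     alt="T", impact="missense") for i in range(6000)]
        rows += [dict(sample="ok", gene="g0", chrom="c", pos=i, alt="T",
                      impact="missense") for i in range(30)]
        capped = sel.apply_sample_caps(pd.DataFrame(rows))
        assert "hyper" not in capped["sample"].values
        assert len(capped[capped["sample"] == "ok"]) == 20


class TestBenjaminiHochberg:
    def test_matches_textbook_step_up(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                      0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341,
                      0.384, 0.569, 0.594, 0.696, 0.762, 0.94, 0.942, 0.975,
                      0.986])
        q = multipletests(p, method="fdr_bh")[1]
        m = len(p)
        # textbook step-up: q_i = min_{j>=i} p_j * m / j on sorted p
        oracle = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(q, oracle)
        assert (q >= p - 1e-12).all()
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()


class TestAnnotateDrivers:
    def _genes(self):
        g_rec = Gene("TP53L", "c", [(0, 300)], "+", "recessive",
                     panel="colorectal-90")
        g_dom = Gene("KRASL", "c", [(400, 700)], "+", "dominant",
                     panel="colorectal-90")
        g_out = Gene("OTHER", "c", [(800, 1100)], "+", "recessive",
                     panel="pan-cancer-369")
        return {g.name: g for g in [g_rec, g_dom, g_out]}

    def test_truncating_in_recessive(self):
        calls = annotate_drivers(
            pd.DataFrame([dict(sample="s", gene="TP53L", pos=10, alt="T",
                               impact="nonsense")]), self._genes())
        assert calls["rule"].tolist() == ["truncating-in-recessive"]

    def test_hotspot_in_dominant(self):
        calls = annotate_drivers(
            pd.DataFrame([dict(sample="s", gene="KRASL", pos=412, alt="A",
                               impact="missense")]),
            self._genes(), hotspots={("KRASL", 412, "A")})
        assert calls["rule"].tolist() == ["hotspot"]

    def test_synonymous_never_called(self):
        calls = annotate_drivers(
            pd.DataFrame([dict(sample="s", gene="TP53L", pos=10, alt="T",
                               impact="synonymous")]),
            self._genes(), hotspots={("TP53L", 10, "T")})
        assert calls.empty

    def test_panel_filtering_by_tissue(self):
        v = pd.DataFrame([dict(sample="s", gene="OTHER", pos=810, alt="T",
                               impact="nonsense")])
        assert annotate_drivers(v, self._genes(), tissue="intestine").empty
        assert len(annotate_drivers(v, self._genes(), tissue="blood")) == 1


class TestDriverBurdenTest:
    def test_printed_comparison_reproduced(self):
        res = driver_burden_test(20, 109, 26, 445)
        assert f"{res['p_value']:.1g}" == "5e-05"

    def test_identical_proportions(self):
        res = driver_burden_test(10, 100, 10, 100)
        assert res["statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_statistic_matches_chi2_tail_oracle(self):
        from scipy.stats import chi2

        res = driver_burden_test(50, 500, 50, 500)
        assert res["p_value"] == pytest.approx(chi2.sf(res["statistic"], 1))
        small = driver_burden_test(5, 50, 5, 50)
        assert small["statistic"] == 0.0

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            driver_burden_test(0, 10, 0, 10)
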