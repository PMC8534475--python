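import numpy as np
import pandas as pd
import pytest

from stabilimeta import compare, quant
from stabilimeta.compare import (
    gene_fc_and_deviation, method_means, method_regression,
    normalized_heatmap_values, panel_report, taxon_wide_fc,
)

META = pd.DataFrame(
    {"method": ["in_situ", "in_situ", "onboard", "onboard"],
     "specimen": [1, 2, 3, 4]},
    index=pd.Index(["i1", "i2", "o1", "o2"], name="sample_id"))


def matrix(rows, index):
    return pd.DataFrame(rows, index=index, columns=META.index, dtype=float)


class TestMethodMeans:
    def test_arithmetic_means(self):
        mat = matrix([[100, 300, 50, 150]], ["g1"])
        means = method_means(mat, META)
        assert means.loc["g1", "in_situ"] == 200.0
        assert means.loc["g1", "onboard"] == 100.0

    def test_sample_permutation_invariance(self):
        mat = matrix([[100, 300, 50, 150]], ["g1"])
        shuffled = mat[["o2", "i1", "o1", "i2"]]
        assert method_means(shuffled, META).equals(method_means(mat, META))

    def test_missing_method_rejected(self):
        mat = matrix([[1, 1, 1, 1]], ["g1"])
        meta = META.copy()
        meta["method"] = "onboard"
        with pytest.raises(ValueError, match="in_situ"):
            method_means(mat, meta)


class TestTaxonWideFc:
    def test_ratio_of_taxon_totals(self):
        mat = matrix([[300, 300, 150, 150], [100, 100, 50, 50]], ["g1", "g2"])
        fc = taxon_wide_fc(method_means(mat, META), {"g1": "T", "g2": "T"})
        assert fc["T"] == pytest.approx(2.0)

    def test_orientation_inverts(self):
        mat = matrix([[300, 300, 150, 150]], ["g1"])
        means = method_means(mat, META)
        fc = taxon_wide_fc(means, {"g1": "T"})
        swapped = means.rename(columns={"in_situ": "onboard", "onboard": "in_situ"})
        fc_rev = taxon_wide_fc(swapped, {"g1": "T"})
        assert fc["T"] * fc_rev["T"] == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        mat = matrix([[1, 1, 0, 0]], ["g1"])
        with pytest.raises(ValueError, match="T"):
            taxon_wide_fc(method_means(mat, META), {"g1": "T"})


class TestDeviation:
    def test_gene_matching_taxon_trend_has_zero_deviation(self):
        mat = matrix([[300, 300, 150, 150], [30, 30, 15, 15]], ["g1", "g2"])
        means = method_means(mat, META)
        ann = {"g1": "T", "g2": "T"}
        fc = taxon_wide_fc(means, ann)
        report = gene_fc_and_deviation(means, fc, ann, pseudo=1e-9)
        np.testing.assert_allclose(report["deviation_log2"], 0.0, atol=1e-6)
        assert not report["flag"].any()

    def test_gene_against_trend_is_flagged(self):
        # taxon flat overall, one gene 8x up onboard
        mat = matrix([[100, 100, 800, 800]] + [[100, 100, 100, 100]] * 20,
                     [f"g{i}" for i in range(21)])
        means = method_means(mat, META)
        ann = {f"g{i}": "T" for i in range(21)}
        fc = taxon_wide_fc(means, ann)
        report = gene_fc_and_deviation(means, fc, ann, threshold=2.0)
        assert report.loc["g0", "flag"]
        assert report["flag"].sum() == 1

    def test_deviation_identity(self):
        rng = np.random.default_rng(0)
        mat = matrix(rng.uniform(1, 1000, size=(10, 4)), [f"g{i}" for i in range(10)])
        means = method_means(mat, META)
        ann = {f"g{i}": "T" for i in range(10)}
        fc = taxon_wide_fc(means, ann)
        r = gene_fc_and_deviation(means, fc, ann, pseudo=0.01)
        np.testing.assert_allclose(
            r["deviation_log2"],
            np.log2(r["fc_insitu_over_onboard"]) - np.log2(r["taxon_fc"]))

    def test_method_wide_scaling_cancels_in_deviation(self):
        # global scale factors per condition (e.g. TPM renormalization's
        # expected effect) shift every gene FC equally and cancel exactly
        rng = np.random.default_rng(1)
        mat = matrix(rng.uniform(10, 1000, size=(12, 4)), [f"g{i}" for i in range(12)])
        ann = {f"g{i}": "T" for i in range(12)}
        scaled = mat * pd.Series([2.0, 2.0, 0.5, 0.5], index=META.index)
        m1, m2 = method_means(mat, META), method_means(scaled, META)
        r1 = gene_fc_and_deviation(m1, taxon_wide_fc(m1, ann), ann, pseudo=1e-12)
        r2 = gene_fc_and_deviation(m2, taxon_wide_fc(m2, ann), ann, pseudo=1e-12)
        np.testing.assert_allclose(r1["deviation_log2"], r2["deviation_log2"],
                                   atol=1e-9)


class TestHeatmap:
    def test_constant_vector_maps_to_zeros(self):
        mat = pd.DataFrame({"s1": [5.0, 5.0, 5.0]}, index=list("abc"))
        out = normalized_heatmap_values(mat)
        assert (out["s1"] == 0.0).all()

    def test_powers_of_ten_closed_form(self):
        mat = pd.DataFrame({"s1": [1.0, 10.0, 100.0]}, index=list("abc"))
        out = normalized_heatmap_values(mat, pseudo=0.0)
        np.testing.assert_allclose(out["s1"], [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])

    def test_output_standardized_per_column(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.uniform(1, 5000, size=(8, 5)),
                           columns=[f"s{i}" for i in range(5)])
        out = normalized_heatmap_values(mat)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=0), 1.0, rtol=1e-12)

    def test_per_taxon_mode(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.uniform(1, 5000, size=(6, 4)))
        out = normalized_heatmap_values(mat, mode="per_taxon")
        assert abs(float(out.to_numpy().mean())) < 1e-12
        assert float(out.to_numpy().std()) == pytest.approx(1.0)


class TestRegression:
    def test_exact_proportional_points(self):
        means = pd.DataFrame({"in_situ": [1.0, 2.0], "onboard": [2.0, 4.0]})
        assert method_regression(means) == pytest.approx(2.0)

    def test_identity_line(self):
        means = pd.DataFrame({"in_situ": [1.0, 5.0, 9.0], "onboard": [1.0, 5.0, 9.0]})
        assert method_regression(means) == pytest.approx(1.0)

    def test_free_intercept_mode(self):
        means = pd.DataFrame({"in_situ": [0.0, 1.0, 2.0], "onboard": [1.0, 2.0, 3.0]})
        slope, intercept = method_regression(means, through_origin=False)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        means = pd.DataFrame({"in_situ": [0.0, 0.0], "onboard": [1.0, 2.0]})
        with pytest.raises(ValueError):
            method_regression(means)


class TestPanelReport:
    def block(self, rows, kos):
        return pd.DataFrame(rows, index=kos, columns=META.index, dtype=float)

    def test_expressed_requires_floor_in_all_samples(self):
        blocks = {"T": self.block([[60, 70, 60, 70], [60, 40, 60, 60]],
                                  ["K03553", "K04043"])}
        panel = {"recA": "K03553", "dnaK": "K04043"}
        out = panel_report(blocks, panel, META, floor=50.0).set_index("gene")
        assert bool(out.loc["recA", "expressed"])
        assert not bool(out.loc["dnaK", "expressed"])

    def test_absent_ko_reports_zero(self):
        blocks = {"T": self.block([[60, 70, 60, 70]], ["K03553"])}
        out = panel_report(blocks, {"pmoA": "K10944"}, META).set_index("gene")
        assert out.loc["pmoA", "in_situ_mean"] == 0.0
        assert not bool(out.loc["pmoA", "expressed"])

    def test_invalid_ko_id_rejected(self):
        with pytest.raises(ValueError, match="bogus"):
            panel_report({}, {"bogus": "KO-X"}, META)

    def test_full_stress_panel_runs(self):
        rng = np.random.default_rng(4)
        kos = list(quant.STRESS_PANEL.values())
        blocks = {"T": self.block(rng.uniform(10, 5000, (9, 4)), kos)}
        out = panel_report(blocks, quant.STRESS_PANEL, META)
        assert len(out) == 9
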