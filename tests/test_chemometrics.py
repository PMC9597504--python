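import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from rosaeval import chemometrics as cm
from rosaeval.errors import RangeError, ValidationError


def separable_data(seed=0, n=20, p_noise=50, shift=5.0):
    """Two Gaussian clusters separated by `shift` sd on one variable."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p_noise + 1))
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    x[labels == "b", 0] += shift
    return x, labels


class TestUVScale:
    def test_simple_column(self):
        s = cm.uv_scale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(s.data[:, 0], [-1, 0, 1])

    def test_constant_column_flagged_zero(self):
        s = cm.uv_scale(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        np.testing.assert_allclose(s.data[:, 0], 0.0)
        assert s.constant.tolist() == [True, False]

    def test_output_columns_standardized(self):
        rng = np.random.default_rng(1)
        s = cm.uv_scale(rng.normal(2.0, 3.0, size=(30, 5)))
        np.testing.assert_allclose(s.data.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(s.data.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_needs_two_samples(self):
        with pytest.raises(ValidationError):
            cm.uv_scale(np.ones((1, 3)))


class TestPCA:
    def test_collinear_data_is_rank_one(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        res = cm.pca(cm.uv_scale(x))
        assert res.all_contribution[0] == pytest.approx(100.0)

    def test_contribution_rates_sum_to_100(self):
        rng = np.random.default_rng(2)
        res = cm.pca(cm.uv_scale(rng.normal(size=(12, 7))))
        assert res.all_contribution.sum() == pytest.approx(100.0, abs=1e-6)

    def test_rotation_invariant_rates(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 6))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        centered = x - x.mean(axis=0)
        a = cm.pca(cm.ScaledMatrix(centered, np.zeros(6), np.ones(6), np.zeros(6, bool)))
        b = cm.pca(cm.ScaledMatrix(centered @ q, np.zeros(6), np.ones(6), np.zeros(6, bool)))
        np.testing.assert_allclose(a.all_contribution, b.all_contribution, atol=1e-8)

    def test_pooled_qc_sample_projects_to_origin(self):
        """The pooled-QC construction (mean of all samples) sits at the
        origin of a centered PCA score space."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 5))
        s = cm.uv_scale(x)
        res = cm.pca(s)
        qc = s.data.mean(axis=0)  # the pooled sample, in scaled coordinates
        np.testing.assert_allclose((qc - s.data.mean(axis=0)) @ res.loadings, 0.0, atol=1e-10)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(5)
        s = cm.uv_scale(rng.normal(size=(9, 4)))
        res = cm.pca(s)
        np.testing.assert_allclose(res.scores @ res.loadings.T, s.data, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValidationError):
            cm.pca(cm.uv_scale(np.random.default_rng(0).normal(size=(4, 6))), 5)

    def test_combined_contribution(self):
        assert cm.combined_contribution([30.0, 20.0, 10.0]) == pytest.approx(50.0)


class TestOPLSDA:
    def test_reduces_to_pls1_without_orthogonal_components(self):
        """With n_orth = 0 the predictive score equals the first PLS1
        component (collinear to 1e-8 against scikit-learn)."""
        x, labels = separable_data(seed=6)
        s = cm.uv_scale(x)
        model = cm.fit_oplsda(s, labels, n_orth=0)
        y = np.where(labels == "b", 1.0, -1.0)
        pls = PLSRegression(n_components=1, scale=False).fit(s.data, y - y.mean())
        t_ref = pls.x_scores_[:, 0]
        cos = abs(t_ref @ model.t) / (np.linalg.norm(t_ref) * np.linalg.norm(model.t))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_scores_orthogonal_to_predictive(self):
        x, labels = separable_data(seed=7)
        model = cm.fit_oplsda(cm.uv_scale(x), labels, n_orth=2)
        for t_o in model.t_orth:
            assert abs(model.t @ t_o) < 1e-8 * np.linalg.norm(model.t) * np.linalg.norm(t_o)

    def test_separable_classes_perfectly_classified(self):
        x, labels = separable_data(seed=8)
        model = cm.fit_oplsda(cm.uv_scale(x), labels, n_orth=1)
        pred = np.where(model.t > 0, model.classes[1], model.classes[0])
        assert (pred == labels).mean() == 1.0

    def test_single_class_rejected(self):
        x, _ = separable_data(seed=9)
        with pytest.raises(ValidationError):
            cm.fit_oplsda(cm.uv_scale(x), np.array(["a"] * len(x)))

    def test_excessive_orthogonal_components_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(4, 3))
        labels = np.array(["a", "a", "b", "b"])
        with pytest.raises(RangeError):
            cm.fit_oplsda(cm.uv_scale(x), labels, n_orth=3)


class TestVIP:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n_orth", [0, 1, 2])
    def test_normalization_sum_of_squares_equals_p(self, seed, n_orth):
        """sum VIP^2 = p (mean squared VIP is 1) for any fitted model."""
        rng = np.random.default_rng(seed)
        n, p = 14, 9
        x = rng.normal(size=(n, p))
        labels = rng.permutation(["a"] * (n // 2) + ["b"] * (n // 2))
        model = cm.fit_oplsda(cm.uv_scale(x), labels, n_orth=n_orth)
        for mode in ("predictive", "total"):
            v = cm.vip(model, mode=mode)
            assert (v**2).sum() == pytest.approx(p, rel=1e-9)

    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(8, 1))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        model = cm.fit_oplsda(cm.uv_scale(x), labels, n_orth=0)
        assert cm.vip(model)[0] == pytest.approx(1.0)

    def test_informative_variable_has_max_vip_above_one(self):
        x, labels = separable_data(seed=12)
        model = cm.fit_oplsda(cm.uv_scale(x), labels, n_orth=1)
        v = cm.vip(model)
        assert np.argmax(v) == 0
        assert v[0] > 1


class TestSPlot:
    def test_variable_identical_to_score_has_corr_one(self):
        x, labels = separable_data(seed=13)
        s = cm.uv_scale(x)
        model = cm.fit_oplsda(s, labels, n_orth=0)
        x2 = np.column_stack([s.data, model.t])
        model2 = cm.fit_oplsda(
            cm.ScaledMatrix(x2, np.zeros(x2.shape[1]), np.ones(x2.shape[1]), np.zeros(x2.shape[1], bool)),
            labels,
            n_orth=0,
        )
        splot = cm.s_plot(model2)
        # the appended variable is collinear with the old t; its pcorr is ~1
        assert abs(splot["pcorr1"].iloc[-1]) > 0.999

    def test_pcorr_within_unit_interval_and_sign_matches_cov(self):
        x, labels = separable_data(seed=14)
        model = cm.fit_oplsda(cm.uv_scale(x), labels, n_orth=1)
        splot = cm.s_plot(model)
        assert splot["pcorr1"].between(-1, 1).all()
        nz = (splot["p1"] != 0) & (splot["pcorr1"] != 0)
        assert (np.sign(splot.loc[nz, "p1"]) == np.sign(splot.loc[nz, "pcorr1"])).all()

    def test_zero_variance_variable_flagged(self):
        x, labels = separable_data(seed=15)
        x[:, 3] = 2.0
        s = cm.uv_scale(x)
        model = cm.fit_oplsda(s, labels, n_orth=0)
        splot = cm.s_plot(model)
        assert splot.loc[3, "degenerate"]
        assert splot.loc[3, "pcorr1"] == 0.0


class TestFoldChange:
    def test_simple_ratio(self):
        later = pd.DataFrame({"x": [4.0, 4.0]})
        earlier = pd.DataFrame({"x": [2.0, 2.0]})
        fc = cm.fold_change_table(later, earlier)
        assert fc.loc[0, "FC"] == pytest.approx(2.0)
        assert fc.loc[0, "log2FC"] == pytest.approx(1.0)

    def test_swapping_groups_inverts(self):
        rng = np.random.default_rng(16)
        a = pd.DataFrame(rng.uniform(1, 5, size=(3, 4)), columns=list("wxyz"))
        b = pd.DataFrame(rng.uniform(1, 5, size=(3, 4)), columns=list("wxyz"))
        fc_ab = cm.fold_change_table(a, b)["FC"].to_numpy()
        fc_ba = cm.fold_change_table(b, a)["FC"].to_numpy()
        np.testing.assert_allclose(fc_ab, 1.0 / fc_ba)

    def test_zero_mean_replaced_by_pseudo_value(self):
        later = pd.DataFrame({"x": [6.0, 6.0], "y": [8.0, 8.0]})
        earlier = pd.DataFrame({"x": [0.0, 0.0], "y": [4.0, 4.0]})
        fc = cm.fold_change_table(later, earlier).set_index("compound")
        # smallest positive mean is 4 -> pseudo-value 2 -> FC = 6/2
        assert fc.loc["x", "FC"] == pytest.approx(3.0)
        assert np.isfinite(fc.loc["x", "log2FC"])

    def test_both_means_zero_flagged_undefined(self):
        later = pd.DataFrame({"x": [0.0, 0.0], "y": [2.0, 2.0]})
        earlier = pd.DataFrame({"x": [0.0, 0.0], "y": [1.0, 1.0]})
        fc = cm.fold_change_table(later, earlier).set_index("compound")
        assert bool(fc.loc["x", "undefined"])
        assert np.isnan(fc.loc["x", "FC"])


class TestScreen:
    @pytest.mark.parametrize("vip_v,fc_v,status", [
        (1.2, 2.0, "up"),
        (0.9, 10.0, "not_significant"),
        (1.5, 0.5, "down"),
        (1.5, 1.2, "not_significant"),
        (1.0, 3.0, "not_significant"),  # VIP strictly > 1 required
    ])
    def test_threshold_rules(self, vip_v, fc_v, status):
        out = cm.screen_differential([vip_v], pd.DataFrame({"compound": ["c"], "FC": [fc_v]}))
        assert out.loc[0, "status"] == status

    def test_undefined_fc_excluded(self):
        out = cm.screen_differential([2.0], pd.DataFrame({"compound": ["c"], "FC": [np.nan]}))
        assert out.loc[0, "status"] == "excluded"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cm.screen_differential([1.0, 2.0], pd.DataFrame({"compound": ["c"], "FC": [1.0]}))


class TestStagePipeline:
    def test_nine_comparisons_on_default_survey(self, small_voc_sim):
        screen = cm.consecutive_stage_screen(small_voc_sim.records)
        assert screen["comparison"].nunique() == 9
        assert set(screen.columns) >= {"comparison", "compound", "VIP", "FC", "log2FC", "status"}

    def test_comparison_names_use_vial_codes(self, small_voc_sim):
        screen = cm.consecutive_stage_screen(small_voc_sim.records)
        assert "BZ1_vs_BZ3" in set(screen["comparison"])
        assert "HX5_vs_HX7" in set(screen["comparison"])

    def test_union_counts_each_compound_once(self, small_voc_sim):
        screen = cm.consecutive_stage_screen(small_voc_sim.records)
        union = cm.differential_union(screen)
        assert len(union) == len(set(union))
        assert set(union) <= set(small_voc_sim.records["compound"])
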