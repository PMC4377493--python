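import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connfeed.network import (Z_CAP, DifferenceMatrix, bootstrap_pair_test,
                              colored_cells, difference_matrices,
                              group_mean_difference, negativity_tests,
                              preprocess_rest_run, psd_check,
                              regress_confounds, roi_matrix_from_series,
                              score_group_comparison)
from connfeed.roi import RoiRegistry, RoiSpec, partition_network_pairs
from connfeed.synthetic import default_covariance_spec, simulate_rest_run


def tiny_registry(networks):
    rois = tuple(RoiSpec(name=f"r{i}", network=net, center=(float(3 * i), 0, 0),
                         radius=1.0)
                 for i, net in enumerate(networks))
    return RoiRegistry(rois=rois)


def diff_from_values(names, values, group=""):
    """DifferenceMatrix with given upper-triangle cells (row-major order)."""
    n = len(names)
    mat = np.zeros((n, n))
    it = iter(values)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = next(it)
    return DifferenceMatrix(dz=pd.DataFrame(mat, index=names, columns=names),
                            group=group)


class TestConfoundRegression:
    def test_residuals_orthogonal_to_every_confound(self, rng):
        data = rng.standard_normal((120, 5))
        conf = rng.standard_normal((120, 9))
        resid = regress_confounds(data, conf)
        for k in range(9):
            for c in range(5):
                r = np.corrcoef(resid[:, c], conf[:, k])[0, 1]
                assert abs(r) < 1e-10

    def test_signal_equal_to_confound_vanishes(self, rng):
        conf = rng.standard_normal((80, 3))
        data = conf[:, [1]] * 2.5 + 1.0
        resid = regress_confounds(data, conf)
        assert np.abs(resid).max() < 1e-10

    def test_rank_deficient_confounds_same_residuals(self, rng):
        data = rng.standard_normal((60, 4))
        conf = rng.standard_normal((60, 3))
        dup = np.column_stack([conf, conf[:, 0]])  # duplicated regressor
        np.testing.assert_allclose(regress_confounds(data, conf),
                                   regress_confounds(data, dup), atol=1e-10)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="confound rows"):
            regress_confounds(rng.standard_normal((50, 2)),
                              rng.standard_normal((49, 3)))

    def test_voxel_preprocessing_discards_and_orthogonalises(self):
        reg_spec = default_covariance_spec()
        from connfeed.roi import synthetic_registry
        registry = synthetic_registry()
        run, _, confounds = simulate_rest_run(reg_spec, n_volumes=40, seed=0,
                                              registry=registry)
        cleaned = preprocess_rest_run(run, confounds, smoothing_fwhm=0.0)
        assert cleaned.n_volumes == 38
        conf = confounds.to_numpy()[2:]
        flat = cleaned.data.reshape(-1, 38)
        sample = flat[::997]
        for k in range(conf.shape[1]):
            dots = sample @ (conf[:, k] - conf[:, k].mean())
            assert np.abs(dots).max() < 1e-8


class TestRoiMatrix:
    def test_fisher_z_closed_form(self):
        q = np.linalg.qr(np.random.default_rng(0).standard_normal((60, 2))
                         - 0.0)[0]  # orthonormal columns
        q -= q.mean(axis=0)
        q, _ = np.linalg.qr(q)
        r = 0.5
        series = pd.DataFrame({"a": q[:, 0],
                               "b": r * q[:, 0] + np.sqrt(1 - r**2) * q[:, 1]})
        mat = roi_matrix_from_series(series)
        assert mat.z.loc["a", "b"] == pytest.approx(0.54931, abs=1e-4)
        assert mat.z.loc["b", "a"] == mat.z.loc["a", "b"]
        assert mat.z.loc["a", "a"] == 0.0

    def test_identical_series_capped_with_warning(self, rng):
        x = rng.standard_normal(50)
        series = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(50)})
        with pytest.warns(RuntimeWarning, match="capped"):
            mat = roi_matrix_from_series(series)
        assert mat.z.loc["a", "b"] == pytest.approx(Z_CAP)

    def test_zero_variance_roi_rejected(self, rng):
        series = pd.DataFrame({"a": np.ones(30), "b": rng.standard_normal(30)})
        with pytest.raises(ValueError, match="zero-variance"):
            roi_matrix_from_series(series)

    def test_permutation_invariance(self, rng):
        series = pd.DataFrame(rng.standard_normal((80, 4)),
                              columns=["a", "b", "c", "d"])
        mat = roi_matrix_from_series(series)
        perm = ["c", "a", "d", "b"]
        mat_p = roi_matrix_from_series(series[perm])
        np.testing.assert_allclose(mat_p.z.to_numpy(),
                                   mat.z.loc[perm, perm].to_numpy(), atol=1e-12)


class TestDifferences:
    def _matrices(self, rng):
        series = {s: pd.DataFrame(rng.standard_normal((40, 3)),
                                  columns=["x", "y", "z"])
                  for s in ("pre", "post")}
        return {s: roi_matrix_from_series(v, session=s)
                for s, v in series.items()}

    def test_identical_sessions_zero(self, rng):
        mats = self._matrices(rng)
        mats["post"] = mats["pre"]
        diff = difference_matrices(mats, "post-pre")
        assert np.abs(diff.dz.to_numpy()).max() == 0.0

    def test_swapped_contrast_negates(self, rng):
        mats = self._matrices(rng)
        d1 = difference_matrices(mats, "post-pre")
        d2 = difference_matrices(mats, "pre-post")
        np.testing.assert_allclose(d1.dz.to_numpy(), -d2.dz.to_numpy(), atol=1e-14)

    def test_hand_computed_three_roi_case(self, rng):
        mats = self._matrices(rng)
        diff = difference_matrices(mats, "post-pre")
        for a in "xyz":
            for b in "xyz":
                expected = mats["post"].z.loc[a, b] - mats["pre"].z.loc[a, b]
                assert diff.dz.loc[a, b] == pytest.approx(expected, abs=1e-14)

    def test_group_mean(self, rng):
        mats = self._matrices(rng)
        d = difference_matrices(mats, "post-pre")
        mean = group_mean_difference([d, d, d])
        np.testing.assert_allclose(mean.dz.to_numpy(), d.dz.to_numpy(), atol=1e-14)


class TestColoredCells:
    def test_threshold_is_pooled_mean_plus_sd(self):
        reg = tiny_registry(["MVN", "DMN"])
        partition = partition_network_pairs(reg)
        diffs = {"g1": diff_from_values(reg.names, [-0.11], group="g1"),
                 "g2": diff_from_values(reg.names, [0.07], group="g2")}
        res = colored_cells(diffs, partition)
        assert res.pooled_mean == pytest.approx(-0.02)
        assert res.pooled_sd == pytest.approx(0.09)
        assert res.threshold == pytest.approx(0.07)
        # strict inequality: the 0.07 cell is not colored
        assert res.counts.to_numpy().sum() == 0

    def test_all_equal_cells_no_coloring(self):
        reg = tiny_registry(["MVN", "MVN", "MVN"])
        partition = partition_network_pairs(reg)
        diffs = {"g": diff_from_values(reg.names, [0.3, 0.3, 0.3])}
        res = colored_cells(diffs, partition)
        assert res.pooled_sd == 0.0
        assert res.counts.to_numpy().sum() == 0

    def test_hand_two_group_three_roi_example(self):
        reg = tiny_registry(["MVN", "MVN", "DMN"])
        partition = partition_network_pairs(reg)
        # cells in row-major upper-triangle order: (r0,r1), (r0,r2), (r1,r2)
        diffs = {"g1": diff_from_values(reg.names, [0.0, 0.5, 0.5], group="g1"),
                 "g2": diff_from_values(reg.names, [0.0, 0.0, 0.0], group="g2")}
        pooled = np.array([0.0, 0.5, 0.5, 0.0, 0.0, 0.0])
        threshold = pooled.mean() + pooled.std()
        res = colored_cells(diffs, partition)
        assert res.threshold == pytest.approx(threshold)
        assert res.count("g1", "MVN-DMN") == 2
        assert res.count("g1", "MVN-MVN") == 0
        assert res.count("g2", "MVN-DMN") == 0


class TestBootstrap:
    def _registry16(self):
        return tiny_registry(["MVN"] * 8 + ["DMN"] * 4 + ["control"] * 4)

    def test_no_colored_cells_nowhere_significant(self, rng):
        reg = self._registry16()
        partition = partition_network_pairs(reg)
        diffs = {g: diff_from_values(reg.names, rng.normal(0, 1e-6, 120), group=g)
                 for g in ("a", "b", "c")}
        res = bootstrap_pair_test(diffs, partition, n_boot=500, seed=0)
        assert not res.table["significant"].any()

    def test_constructed_type_significant_matches_binomial_oracle(self):
        reg = self._registry16()
        partition = partition_network_pairs(reg)
        names = reg.names
        mvn = names[:8]
        dmn = names[8:12]
        mat = np.zeros((16, 16))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if (a in mvn and b in dmn) or (a in dmn and b in mvn):
                    mat[i, j] = 1.0
        nf = DifferenceMatrix(dz=pd.DataFrame(mat, index=names, columns=names),
                              group="nf")
        zero = diff_from_values(names, np.zeros(120))
        diffs = {"nf": nf, "sham": zero, "imagery": zero}
        res = bootstrap_pair_test(diffs, partition, n_boot=3000, seed=1)
        table = res.table.set_index(["group", "pair_type"])
        assert table.loc[("nf", "MVN-DMN"), "significant"]
        others = table.drop(index=("nf", "MVN-DMN"))
        assert not others["significant"].any()
        # independent oracle: resampled counts are Binomial(m, pooled fraction)
        frac = 32 / 360
        expected_upper = stats.binom.ppf(1 - 0.05 / 18, 32, frac)
        assert abs(table.loc[("nf", "MVN-DMN"), "ci_upper"] - expected_upper) <= 3

    def test_same_seed_identical(self, rng):
        reg = self._registry16()
        partition = partition_network_pairs(reg)
        diffs = {g: diff_from_values(reg.names, rng.normal(0, 0.1, 120), group=g)
                 for g in ("a", "b", "c")}
        r1 = bootstrap_pair_test(diffs, partition, n_boot=500, seed=11)
        r2 = bootstrap_pair_test(diffs, partition, n_boot=500, seed=11)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_n_boot_too_small_for_percentile(self, rng):
        reg = self._registry16()
        partition = partition_network_pairs(reg)
        diffs = {g: diff_from_values(reg.names, rng.normal(0, 0.1, 120), group=g)
                 for g in ("a", "b", "c")}
        with pytest.raises(ValueError, match="percentile"):
            bootstrap_pair_test(diffs, partition, n_boot=150, alpha=0.01, seed=0)


class TestGroupStats:
    def test_negativity_matches_textbook_formula(self):
        values = np.array([-0.4, -0.1, -0.3, -0.25, -0.5, 0.05])
        res = negativity_tests({"set": values}, alternative="two-sided")
        t_oracle = values.mean() / (values.std(ddof=1) / np.sqrt(len(values)))
        assert res["t"][0] == pytest.approx(t_oracle, abs=1e-12)

    def test_strongly_negative_sample_flagged(self, rng):
        values = -1.0 + rng.normal(0, 0.01, 12)
        res = negativity_tests({"a": values, "b": values, "c": values})
        assert res["significant"].all()

    def test_symmetric_sample_not_flagged(self, rng):
        values = np.r_[np.linspace(-0.3, 0.3, 12)]
        res = negativity_tests({"a": values})
        assert not res["significant"].any()

    def test_bonferroni_caps_at_one(self, rng):
        values = rng.normal(0.0, 0.2, 10)
        res = negativity_tests({c: values for c in "abc"})
        assert (res["p_bonferroni"] <= 1.0).all()

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            negativity_tests({"a": np.full(5, -0.5)})

    def test_anova_identical_groups(self, rng):
        g = rng.standard_normal(6)
        res = score_group_comparison({"a": g, "b": g.copy(), "c": g.copy()})
        assert res.f_stat == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_anova_matches_hand_computed_f(self):
        groups = {"a": np.array([1.0, 2.0, 3.0, 4.0]),
                  "b": np.array([2.0, 3.0, 4.0, 5.0]),
                  "c": np.array([8.0, 9.0, 10.0, 11.0])}
        res = score_group_comparison(groups)
        data = np.concatenate(list(groups.values()))
        grand = data.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / 9)
        assert res.f_stat == pytest.approx(f_oracle, abs=1e-10)

    def test_shifted_group_detected_posthoc(self, rng):
        groups = {"treat": rng.normal(5.0, 1.0, 8),
                  "c1": rng.normal(0.0, 1.0, 8),
                  "c2": rng.normal(0.0, 1.0, 8)}
        res = score_group_comparison(groups, reference="treat")
        assert (res.posthoc["p_bonferroni"] < 0.01).all()
        assert res.p_value < 0.01


class TestPsd:
    def test_sinusoid_peak_recovered(self):
        tr = 2.0
        t = np.arange(512) * tr
        x = np.sin(2 * np.pi * 0.03 * t)
        freqs, _, peak = psd_check(x, tr)
        resolution = freqs[1] - freqs[0]
        assert abs(peak - 0.03) <= resolution
        assert freqs[-1] == pytest.approx(0.25)  # Nyquist at TR 2 s

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            psd_check(np.zeros(8), 2.0)
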