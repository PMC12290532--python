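import numpy as np
import pytest

from prepdecode import fusion
from prepdecode.eeg import CELL_ORDER, EEGEffectSpec, generate_eeg
from prepdecode.fusion import (average_rdms, build_rdm, commonality,
                               commonality_series, eeg_rdm_series, fusion_r2,
                               ldc_distance, lower_triangle, model_rdms,
                               permutation_cluster_test, smooth_moving_average)


def identity_covariance_residuals(p: int) -> np.ndarray:
    """Residual rows whose sample covariance is exactly the identity."""
    scale = np.sqrt((2 * p - 1) / 2.0)
    return np.vstack([np.eye(p), -np.eye(p)]) * scale


class TestLDC:
    def test_identical_patterns_give_zero(self):
        rng = np.random.default_rng(0)
        pat = rng.standard_normal((2, 5))
        res = (rng.standard_normal((30, 5)), rng.standard_normal((30, 5)))
        assert ldc_distance(pat, pat, res) == pytest.approx(0.0)

    def test_unit_difference_identity_covariance_closed_form(self):
        p = 6
        e = np.zeros(p)
        e[0] = 1.0
        a = np.vstack([e, e])
        b = np.zeros((2, p))
        res = (identity_covariance_residuals(p),) * 2
        assert ldc_distance(a, b, res, shrinkage=0.1) == pytest.approx(1.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 2, 4))
        res = (rng.standard_normal((20, 4)), rng.standard_normal((20, 4)))
        assert ldc_distance(a, b, res) == pytest.approx(ldc_distance(b, a, res))

    def test_unbiased_under_null(self):
        """Cross-validated distances average 0 without a true difference,
        and individual values go negative."""
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(1500):
            a = rng.standard_normal((2, 3))
            b = rng.standard_normal((2, 3))
            res = (identity_covariance_residuals(3),) * 2
            vals.append(ldc_distance(a, b, res, shrinkage=0.0))
        vals = np.array(vals)
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(vals.size)
        assert (vals < 0).any()

    def test_bad_fold_count_rejected(self):
        with pytest.raises(ValueError):
            ldc_distance(np.zeros((3, 4)), np.zeros((3, 4)),
                         (np.eye(4), np.eye(4)))


class TestRDM:
    def _patterns(self, rng, spread=1.0):
        base = rng.standard_normal((8, 1, 6)) * spread
        return np.repeat(base, 2, axis=1) + 0.1 * rng.standard_normal((8, 2, 6))

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        rdm = build_rdm(self._patterns(rng),
                        (identity_covariance_residuals(6),) * 2)
        np.testing.assert_allclose(rdm, rdm.T)
        np.testing.assert_allclose(np.diag(rdm), 0)
        assert lower_triangle(rdm).size == 28

    def test_single_pattern_gives_near_zero_rdm(self):
        rng = np.random.default_rng(4)
        one = rng.standard_normal(6)
        patterns = np.tile(one, (8, 2, 1))
        rdm = build_rdm(patterns, (identity_covariance_residuals(6),) * 2)
        np.testing.assert_allclose(rdm, 0, atol=1e-10)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        patterns = self._patterns(rng)
        res = (identity_covariance_residuals(6),) * 2
        rdm = build_rdm(patterns, res)
        perm = rng.permutation(8)
        rdm_p = build_rdm(patterns[perm], res)
        np.testing.assert_allclose(rdm_p, rdm[perm][:, perm], atol=1e-10)


class TestModelRDMs:
    def test_lower_triangle_sums(self):
        models = model_rdms()
        assert lower_triangle(models["condition"]).sum() == 16
        assert lower_triangle(models["category"]).sum() == 16
        assert lower_triangle(models["cue"]).sum() == 24

    def test_cue_model_shares_shapes_across_conditions(self):
        cue = model_rdms()["cue"]
        zeros = [(i, j) for i in range(8) for j in range(i)
                 if cue[i, j] == 0]
        assert len(zeros) == 4
        for i, j in zeros:
            assert CELL_ORDER[i][1:] == CELL_ORDER[j][1:]  # same physical shape

    def test_binary_and_symmetric(self):
        for m in model_rdms().values():
            assert set(np.unique(m)) <= {0.0, 1.0}
            np.testing.assert_array_equal(m, m.T)


class TestFusionR2:
    def test_identity_and_sign_flip(self):
        v = np.random.default_rng(6).standard_normal(28)
        assert fusion_r2(v, v) == pytest.approx(1.0)
        assert fusion_r2(v, -v) == pytest.approx(1.0)

    def test_orthogonalized_vector_gives_zero(self):
        rng = np.random.default_rng(7)
        v = rng.standard_normal(28)
        w = rng.standard_normal(28)
        vc = v - v.mean()
        w = w - w.mean()
        w = w - (w @ vc) / (vc @ vc) * vc  # Gram-Schmidt against centered v
        assert fusion_r2(v, w) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(fusion_r2(np.ones(28), np.arange(28.0)))


def oracle_commonality(eeg, fmri, models: dict, interest: str) -> float:
    """Independent route: commonality as a difference of squared semipartial
    correlations computed from full-model R-squared differences."""
    def r2_of(y, cols):
        X = np.column_stack([np.ones(y.size)] + cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(resid ** 2) / tss

    others = [v for m, v in models.items() if m != interest]
    every = list(models.values())
    sr2_without = r2_of(eeg, [fmri] + others) - (r2_of(eeg, others) if others else 0.0)
    sr2_with = r2_of(eeg, [fmri] + every) - r2_of(eeg, every)
    return sr2_without - sr2_with


class TestCommonality:
    @pytest.mark.parametrize("n_models", [2, 3])
    def test_matches_brute_force_oracle(self, n_models):
        """Mandatory dual-route check: semipartial-residual implementation
        vs all-subsets-regression oracle on 100 random instances."""
        rng = np.random.default_rng(8)
        names = ["condition", "category", "cue"][:n_models]
        for _ in range(100):
            eeg = rng.standard_normal(28)
            fmri = rng.standard_normal(28)
            models = {m: rng.standard_normal(28) for m in names}
            ours = commonality(eeg, fmri, models, names[0])
            ref = oracle_commonality(eeg, fmri, models, names[0])
            assert ours == pytest.approx(ref, abs=1e-10, rel=1e-10)

    def test_recovers_generating_model(self):
        rng = np.random.default_rng(9)
        mv = {m: lower_triangle(v) for m, v in model_rdms().items()}
        c_a = np.array([commonality(
            mv["category"] + 0.3 * rng.standard_normal(28),
            mv["category"] + 0.3 * rng.standard_normal(28),
            mv, "category") for _ in range(50)])
        c_b = np.array([commonality(
            mv["category"] + 0.3 * rng.standard_normal(28),
            mv["category"] + 0.3 * rng.standard_normal(28),
            mv, "cue") for _ in range(50)])
        assert c_a.mean() > 0.2
        assert abs(c_b.mean()) < 0.05

    def test_unrelated_eeg_gives_near_zero(self):
        rng = np.random.default_rng(10)
        mv = {m: lower_triangle(v) for m, v in model_rdms().items()}
        vals = [commonality(rng.standard_normal(28),
                            mv["category"] + 0.1 * rng.standard_normal(28),
                            mv, "category") for _ in range(200)]
        assert abs(np.mean(vals)) < 0.05

    def test_collinear_models_rejected(self):
        v = np.arange(28.0)
        with pytest.raises(ValueError, match="collinear"):
            commonality(v, v, {"a": v, "b": 2 * v}, "a")

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError):
            commonality(np.ones(28), np.ones(28),
                        {"a": np.arange(28.0)}, "zzz")


class TestSmoothing:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_moving_average(np.full(20, 3.0)), 3.0)

    def test_unit_impulse_spreads_to_fifths(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = smooth_moving_average(x)
        np.testing.assert_allclose(out[3:8], 0.2)
        np.testing.assert_allclose(out[[0, 1, 2, 8, 9, 10]], 0)

    def test_linear_ramp_interior_unchanged(self):
        x = np.arange(30.0)
        out = smooth_moving_average(x)
        np.testing.assert_allclose(out[2:-2], x[2:-2])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_moving_average(np.ones(5), window=4)


class TestEEGRDMs:
    def test_ramping_category_signal_grows_over_interval(self):
        """With a planted ramp, face-vs-name LDC is larger at 1500 ms than at
        300 ms; without it the distances hover near zero."""
        models = model_rdms()
        cat_pairs = lower_triangle(models["category"]).astype(bool)
        spec = EEGEffectSpec(trials_per_cell=32)
        diffs, null_means = [], []
        for seed in range(8):
            rdms = eeg_rdm_series(generate_eeg(spec, seed=seed))
            epochs = generate_eeg(spec, seed=seed)
            t_early = int(np.argmin(np.abs(epochs.times_ms - 300)))
            t_late = int(np.argmin(np.abs(epochs.times_ms - 1500)))
            early = lower_triangle(rdms[t_early])[cat_pairs].mean()
            late = lower_triangle(rdms[t_late])[cat_pairs].mean()
            diffs.append(late - early)
            null = eeg_rdm_series(generate_eeg(
                EEGEffectSpec(trials_per_cell=32, ramp_amplitude=0.0,
                              condition_amplitude=0.0, shape_amplitude=0.0),
                seed=seed))
            null_means.append(lower_triangle(null[t_late]).mean())
        assert np.mean(diffs) > 0
        assert min(diffs) > 0
        assert abs(np.mean(null_means)) < 0.5

    def test_identical_cell_patterns_give_zero_expected_distance(self):
        # shape patterns off: cells differing only in shape index share a
        # generative pattern, so their expected LDC is 0
        spec = EEGEffectSpec(trials_per_cell=24, shape_amplitude=0.0)
        vals = []
        for seed in range(10):
            rdms = eeg_rdm_series(generate_eeg(spec, seed=seed))
            vals.append(np.mean([rdms[-1, 0, 1], rdms[-1, 2, 3],
                                 rdms[-1, 4, 5], rdms[-1, 6, 7]]))
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 0.05

    def test_too_few_epochs_rejected(self):
        eeg_obj = generate_eeg(EEGEffectSpec(trials_per_cell=1), seed=0)
        with pytest.raises(ValueError):
            eeg_rdm_series(eeg_obj)


@pytest.fixture(scope="module")
def group_rdms():
    return average_rdms([
        eeg_rdm_series(generate_eeg(EEGEffectSpec(trials_per_cell=24),
                                    seed=300 + i))
        for i in range(6)
    ])


class TestPermutationClusterTest:
    def _two_models(self):
        models = model_rdms()
        return {m: models[m] for m in ("category", "cue")}

    def test_planted_ramp_yields_significant_late_window(self, group_rdms):
        models = model_rdms()
        fm = (100 * models["category"] + 20 * models["cue"]
              + np.random.default_rng(0).normal(0, 1, (8, 8)))
        fm = (fm + fm.T) / 2
        np.fill_diagonal(fm, 0)
        win = permutation_cluster_test(group_rdms, fm, self._two_models(),
                                       "category", n_perm=1500, seed=1)
        sig = win.windows[win.windows.significant]
        assert len(sig) >= 1
        # the window sits late in the interval and reaches target onset
        assert (sig.start + sig.length).max() >= 60
        assert sig.start.min() > 10

    def test_alpha_one_flags_everything(self, group_rdms):
        fm = model_rdms()["category"].astype(float)
        win = permutation_cluster_test(group_rdms, fm, self._two_models(),
                                       "category", n_perm=500, alpha=1.0,
                                       seed=2)
        assert win.significant_mask().all()

    def test_short_series_and_low_nperm_rejected(self):
        fm = model_rdms()["category"].astype(float)
        with pytest.raises(ValueError):
            permutation_cluster_test(np.zeros((2, 8, 8)), fm,
                                     self._two_models(), "category")
        with pytest.raises(ValueError):
            permutation_cluster_test(np.zeros((10, 8, 8)), fm,
                                     self._two_models(), "category",
                                     n_perm=100)

    def test_commonality_series_matches_pointwise_commonality(self, group_rdms):
        mv = {m: lower_triangle(v) for m, v in self._two_models().items()}
        fm = model_rdms()["category"] * 5.0
        series = commonality_series(group_rdms, fm, self._two_models(),
                                    "category")
        direct = [commonality(lower_triangle(group_rdms[t]),
                              lower_triangle(fm), mv, "category")
                  for t in range(0, group_rdms.shape[0], 10)]
        np.testing.assert_allclose(series[::10], direct, atol=1e-10)
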