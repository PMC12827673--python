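import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amanet import (
    AugConfig,
    RawTrialSet,
    amplitude_scale,
    augment,
    csp_apply,
    csp_fit,
    sliding_window,
)
from amanet.augment import SpatialFilterBank, n_windows, sample_betas
from amanet.exceptions import (
    ConfigurationError,
    DimensionError,
    InsufficientDataError,
    SegmentationError,
    SpecError,
)


class TestSlidingWindow:
    def test_paper_case_five_windows(self):
        trial = np.arange(3 * 1000, dtype=float).reshape(3, 1000)
        wins = sliding_window(trial, 500, 125)
        assert len(wins) == 5
        np.testing.assert_array_equal(wins[0], trial[:, :500])
        np.testing.assert_array_equal(wins[-1], trial[:, 500:1000])

    def test_identity_case(self):
        trial = np.random.default_rng(0).standard_normal((4, 500))
        wins = sliding_window(trial, 500, 125)
        assert len(wins) == 1
        np.testing.assert_array_equal(wins[0], trial)

    def test_enumerated_starts(self):
        trial = np.arange(2 * 12, dtype=float).reshape(2, 12)
        wins = sliding_window(trial, 4, 3)
        assert len(wins) == 3
        for w, start in zip(wins, (0, 3, 6)):
            np.testing.assert_array_equal(w, trial[:, start : start + 4])

    def test_window_too_long_raises_with_lengths(self):
        with pytest.raises(SegmentationError, match="600.*500|500.*600"):
            sliding_window(np.zeros((2, 500)), 600, 100)

    @given(
        t=st.integers(10, 400),
        w=st.integers(1, 400),
        s=st.integers(1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_count_matches_closed_form(self, t, w, s):
        if w > t or s > w:
            return
        wins = sliding_window(np.zeros((1, t)), w, s)
        # independent count: enumerate admissible start indices
        expected = len([i for i in range(0, t, s) if i + w <= t and i % s == 0])
        assert len(wins) == (t - w) // s + 1 == expected


def _windows_from_cov(cov, n, t, rng):
    chol = np.linalg.cholesky(cov)
    return np.einsum("ij,njt->nit", chol, rng.standard_normal((n, cov.shape[0], t)))


class TestCspFit:
    def test_analytic_two_channel_example(self, rng):
        # per-class covariances diag(4,1) and diag(1,4): generalized
        # eigenvalues 0.8 / 0.2 with coordinate-axis filters
        e0 = _windows_from_cov(np.diag([4.0, 1.0]), 60, 400, rng)
        e1 = _windows_from_cov(np.diag([1.0, 4.0]), 60, 400, rng)
        epochs = np.concatenate([e0, e1])
        labels = np.array([0] * 60 + [1] * 60)
        bank = csp_fit(epochs, labels, n_components=2)
        assert bank.filters.shape == (2, 2)
        np.testing.assert_allclose(bank.eigenvalues, [0.8, 0.2], atol=0.03)
        for row in bank.filters:
            unit = row / np.linalg.norm(row)
            assert max(abs(unit[0]), abs(unit[1])) > 0.99
        assert list(bank.class_of_filter) == [0, 1]

    def test_same_distribution_gives_half_eigenvalues(self, rng):
        e = rng.standard_normal((100, 3, 300))
        labels = np.array([0, 1] * 50)
        bank = csp_fit(e, labels, n_components=2)
        np.testing.assert_allclose(bank.eigenvalues, 0.5, atol=0.05)

    def test_four_class_six_pairs_gives_twelve_rows(self, rng):
        epochs = rng.standard_normal((80, 16, 100))
        labels = np.repeat(np.arange(4), 20)
        bank = csp_fit(epochs, labels, n_components=12)
        assert bank.filters.shape == (12, 16)
        assert list(np.bincount(bank.class_of_filter)) == [3, 3, 3, 3]

    def test_brute_force_oracle_equivalence(self, rng):
        # dense grid over unit vectors in 2-d: maximize var-ratio
        e0 = _windows_from_cov(np.array([[2.0, 0.8], [0.8, 1.0]]), 80, 300, rng)
        e1 = _windows_from_cov(np.array([[1.0, -0.3], [-0.3, 1.5]]), 80, 300, rng)
        epochs = np.concatenate([e0, e1])
        labels = np.array([0] * 80 + [1] * 80)
        bank = csp_fit(epochs, labels, n_components=2)

        def mean_cov(es):
            covs = es @ es.transpose(0, 2, 1)
            tr = np.trace(covs, axis1=1, axis2=2)
            return (covs / tr[:, None, None]).mean(axis=0)

        s0, s1 = mean_cov(e0), mean_cov(e1)
        thetas = np.linspace(0, np.pi, 20001)
        vs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        ratios = np.einsum("ni,ij,nj->n", vs, s0, vs) / np.einsum(
            "ni,ij,nj->n", vs, s0 + s1, vs
        )
        best = vs[np.argmax(ratios)]
        top = bank.filters[0] / np.linalg.norm(bank.filters[0])
        assert abs(float(top @ best)) >= 0.999

    def test_joint_diagonalization_identity(self, rng):
        e0 = _windows_from_cov(np.array([[3.0, 1.0], [1.0, 2.0]]), 50, 200, rng)
        e1 = _windows_from_cov(np.array([[1.0, 0.2], [0.2, 1.0]]), 50, 200, rng)
        epochs = np.concatenate([e0, e1])
        labels = np.array([0] * 50 + [1] * 50)
        bank = csp_fit(epochs, labels, n_components=2)

        def mean_cov(es):
            covs = es @ es.transpose(0, 2, 1)
            tr = np.trace(covs, axis1=1, axis2=2)
            return (covs / tr[:, None, None]).mean(axis=0)

        composite = mean_cov(e0) + mean_cov(e1)
        gram = bank.filters @ composite @ bank.filters.T
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-6)

    def test_eigenvalue_pairs_sum_to_one(self, rng):
        e0 = _windows_from_cov(np.array([[2.5, 0.4], [0.4, 0.8]]), 50, 200, rng)
        e1 = _windows_from_cov(np.array([[0.9, -0.2], [-0.2, 1.7]]), 50, 200, rng)
        epochs = np.concatenate([e0, e1])
        labels = np.array([0] * 50 + [1] * 50)
        bank = csp_fit(epochs, labels, n_components=2)

        def mean_cov(es):
            covs = es @ es.transpose(0, 2, 1)
            tr = np.trace(covs, axis1=1, axis2=2)
            return (covs / tr[:, None, None]).mean(axis=0)

        s0, s1 = mean_cov(e0), mean_cov(e1)
        for w in bank.filters:
            lam0 = (w @ s0 @ w) / (w @ (s0 + s1) @ w)
            lam1 = (w @ s1 @ w) / (w @ (s0 + s1) @ w)
            assert lam0 + lam1 == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention(self, rng):
        e0 = _windows_from_cov(np.diag([4.0, 1.0]), 30, 100, rng)
        e1 = _windows_from_cov(np.diag([1.0, 4.0]), 30, 100, rng)
        bank = csp_fit(
            np.concatenate([e0, e1]), np.array([0] * 30 + [1] * 30), n_components=2
        )
        for row in bank.filters:
            assert row[np.argmax(np.abs(row))] > 0

    def test_insufficient_class_windows_raises(self, rng):
        epochs = rng.standard_normal((3, 2, 50))
        labels = np.array([0, 0, 1])
        with pytest.raises(InsufficientDataError):
            csp_fit(epochs, labels, n_components=2)

    def test_too_many_components_raises(self, rng):
        epochs = rng.standard_normal((20, 2, 50))
        labels = np.array([0, 1] * 10)
        with pytest.raises(ConfigurationError):
            csp_fit(epochs, labels, n_components=4)


class TestCspApply:
    def test_identity_bank(self, rng):
        bank = SpatialFilterBank(
            filters=np.eye(3),
            eigenvalues=np.full(3, 0.5),
            class_of_filter=np.zeros(3),
            n_source_channels=3,
        )
        x = rng.standard_normal((3, 40))
        np.testing.assert_array_equal(csp_apply(bank, x), x)

    def test_zero_window_gives_zero(self, rng):
        bank = SpatialFilterBank(
            filters=rng.standard_normal((2, 3)),
            eigenvalues=np.full(2, 0.5),
            class_of_filter=np.zeros(2),
            n_source_channels=3,
        )
        assert np.all(csp_apply(bank, np.zeros((3, 10))) == 0)

    def test_variance_ratio_after_projection(self, rng):
        e0 = _windows_from_cov(np.diag([4.0, 1.0]), 100, 500, rng)
        e1 = _windows_from_cov(np.diag([1.0, 4.0]), 100, 500, rng)
        epochs = np.concatenate([e0, e1])
        labels = np.array([0] * 100 + [1] * 100)
        bank = csp_fit(epochs, labels, n_components=2)
        proj = csp_apply(bank, e1)
        var = proj.var(axis=(0, 2))
        # component attributed to class 1 carries ~4x the variance on class-1 data
        assert var[1] / var[0] == pytest.approx(4.0, rel=0.25)

    def test_channel_mismatch_raises(self, rng):
        bank = SpatialFilterBank(
            filters=np.eye(3),
            eigenvalues=np.full(3, 0.5),
            class_of_filter=np.zeros(3),
            n_source_channels=3,
        )
        with pytest.raises(DimensionError):
            csp_apply(bank, rng.standard_normal((4, 10)))


class TestAmplitudeScale:
    def test_identity(self, rng):
        x = rng.standard_normal((2, 30))
        np.testing.assert_array_equal(amplitude_scale(x, 1.0), x)

    def test_sinusoid_peak(self):
        t = np.linspace(0, 1, 500)
        x = np.sin(2 * np.pi * 5 * t)[None, :]
        y = amplitude_scale(x, 0.9)
        assert np.max(np.abs(y)) == pytest.approx(0.9, abs=1e-3)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(SpecError):
            amplitude_scale(np.ones((1, 5)), 0.0)

    def test_sampled_betas_within_band(self):
        cfg = AugConfig()
        betas = sample_betas(cfg, 10_000, np.random.default_rng(0))
        assert betas.min() >= 0.9 and betas.max() <= 1.1

    def test_truncated_normal_betas_within_band(self):
        cfg = AugConfig(beta_distribution="truncated-normal")
        betas = sample_betas(cfg, 10_000, np.random.default_rng(0))
        assert betas.min() >= 0.9 and betas.max() <= 1.1
        assert abs(betas.mean() - 1.0) < 0.005


class TestAugment:
    def _split(self, trials, n_test=4):
        train = RawTrialSet(trials.data[n_test:], trials.labels[n_test:], trials.sfreq)
        test = RawTrialSet(trials.data[:n_test], trials.labels[:n_test], trials.sfreq)
        return train, test

    def test_window_counts(self, easy_small_trials):
        train, test = self._split(easy_small_trials)
        cfg = AugConfig(n_pairs=1, seed=0)
        tr, te, bank = augment(train, test, cfg)
        assert tr.n_windows == train.n_trials * 5
        assert te.n_windows == test.n_trials * 5
        assert bank is not None

    def test_test_windows_unscaled(self, easy_small_trials):
        train, test = self._split(easy_small_trials)
        cfg = AugConfig(n_pairs=1, seed=0)
        _, te, bank = augment(train, test, cfg)
        # recompute the raw CSP projection of the first test window
        expected = bank.filters @ test.data[0, :, :500]
        np.testing.assert_allclose(te.data[0], expected, rtol=1e-12)

    def test_binary_n_pairs_one_gives_two_channels(self, easy_small_trials):
        train, test = self._split(easy_small_trials)
        tr, te, _ = augment(train, test, AugConfig(n_pairs=1, seed=0))
        assert tr.data.shape[1] == 2
        assert te.data.shape[1] == 2

    def test_deterministic_rerun(self, easy_small_trials):
        train, test = self._split(easy_small_trials)
        cfg = AugConfig(n_pairs=1, seed=11)
        tr1, te1, _ = augment(train, test, cfg)
        tr2, te2, _ = augment(train, test, cfg)
        np.testing.assert_array_equal(tr1.data, tr2.data)
        np.testing.assert_array_equal(te1.data, te2.data)

    def test_labels_follow_source_trial(self, easy_small_trials):
        train, test = self._split(easy_small_trials)
        tr, _, _ = augment(train, test, AugConfig(n_pairs=1, seed=0))
        for tid in np.unique(tr.source_trial):
            mask = tr.source_trial == tid
            assert len(set(tr.labels[mask])) == 1
            assert tr.labels[mask][0] == train.labels[tid]

    def test_missing_test_class_warns(self, easy_small_trials):
        trials = easy_small_trials
        train_mask = trials.labels == 0
        train = RawTrialSet(trials.data[train_mask][:6].repeat(2, axis=0),
                            np.array([0, 1] * 6), trials.sfreq)
        test = RawTrialSet(trials.data[:2], trials.labels[:2] * 0 + 1, trials.sfreq)
        test = RawTrialSet(test.data, np.array([1, 1]), trials.sfreq)
        train2 = RawTrialSet(train.data, np.array([0] * 12), trials.sfreq)
        with pytest.warns(UserWarning, match="absent"):
            augment(train2, test, AugConfig(n_pairs=1, use_csp=False, seed=0))

    def test_shape_mismatch_raises(self, easy_small_trials):
        train, test = self._split(easy_small_trials)
        short = RawTrialSet(test.data[:, :, :900], test.labels, test.sfreq)
        with pytest.raises(DimensionError):
            augment(train, short, AugConfig(n_pairs=1, seed=0))

    def test_scale_train_only_false_scales_test(self, easy_small_trials):
        train, test = self._split(easy_small_trials)
        cfg = AugConfig(n_pairs=1, seed=0, scale_train_only=False)
        _, te_scaled, bank = augment(train, test, cfg)
        expected = bank.filters @ test.data[0, :, :500]
        assert not np.allclose(te_scaled.data[0], expected)


class TestAugConfigValidation:
    def test_bad_stride(self):
        with pytest.raises(ConfigurationError):
            AugConfig(window_size=100, stride=200)

    def test_bounds_must_bracket_one(self):
        with pytest.raises(ConfigurationError):
            AugConfig(beta_low=1.05, beta_high=1.2)

    def test_n_components(self):
        assert AugConfig(n_pairs=6).n_components == 12
        assert AugConfig(n_pairs=1).n_components == 2
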