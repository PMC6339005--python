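"""HDCA contracts: FLD closed form, projection linearity, logistic fusion,
training determinism, the single-window reduction oracle, scale invariance
and localisation of injected effects."""

import numpy as np
import pytest
from sklearn.covariance import LedoitWolf

from rsvpauth import hdca
from rsvpauth.hdca import (
    WindowingScheme,
    classify,
    fit_temporal,
    fld_weights,
    score,
    spatial_project,
    train,
    window_features,
)
from rsvpauth.preprocess import EpochSet
from rsvpauth.simulate import CHANNELS_16


def fld_oracle(X, labels):
    """Closed form (S_w + λ·target)⁻¹(μ₁ − μ₀) via sklearn's Ledoit-Wolf."""
    centered = X.copy()
    centered[labels == 0] -= X[labels == 0].mean(axis=0)
    centered[labels == 1] -= X[labels == 1].mean(axis=0)
    cov = LedoitWolf(assume_centered=True).fit(centered).covariance_
    w = np.linalg.solve(cov, X[labels == 1].mean(axis=0) - X[labels == 0].mean(axis=0))
    return w / np.linalg.norm(w)


class TestWindowing:
    def test_paper_tiling_600_samples(self):
        w = WindowingScheme.tile(600, 600.0, 100.0)
        assert w.n_windows == 10
        assert w.bounds[0] == (0, 60) and w.bounds[-1] == (540, 600)

    def test_windows_tile_without_overlap(self):
        w = WindowingScheme.tile(600, 600.0, 100.0)
        covered = [i for a, b in w.bounds for i in range(a, b)]
        assert covered == list(range(600))

    def test_window_larger_than_epoch_raises(self):
        with pytest.raises(ValueError):
            WindowingScheme.tile(30, 600.0, 100.0)


class TestFLDWeights:
    def test_identity_covariance_recovers_mean_difference(self, rng):
        # Whiten so the sample within-class covariance is exactly identity;
        # with no shrinkage distortion (target = I), w ∝ μ₁−μ₀ = e₁.
        n, c = 60, 2
        Z = rng.standard_normal((n, c))
        labels = np.repeat([0, 1], n // 2)
        for cls in (0, 1):
            Z[labels == cls] -= Z[labels == cls].mean(axis=0)
        cov = Z.T @ Z / n
        L = np.linalg.cholesky(np.linalg.inv(cov))
        X = Z @ L.T
        X[labels == 1] += np.array([1.0, 0.0])
        w = fld_weights(X, labels)
        np.testing.assert_allclose(np.abs(w), [1.0, 0.0], atol=1e-9)

    def test_matches_closed_form_direction(self, rng):
        for _ in range(10):
            labels = np.repeat([0, 1], 30)
            X = rng.standard_normal((60, 6)) @ rng.standard_normal((6, 6))
            X[labels == 1] += rng.standard_normal(6)
            w = fld_weights(X, labels)
            assert abs(w @ fld_oracle(X, labels)) >= 0.999

    def test_sign_convention_self_projects_higher(self, rng):
        labels = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 4))
        X[labels == 1] -= 2.0  # effect pointing "down"
        w = fld_weights(X, labels)
        assert (X[labels == 1] @ w).mean() >= (X[labels == 0] @ w).mean()

    def test_duplicate_channel_solvable_via_shrinkage(self, rng):
        labels = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 3))
        X[labels == 1, 0] += 1.0
        X = np.column_stack([X, X[:, 0]])  # exact duplicate column
        w = fld_weights(X, labels)
        assert np.isfinite(w).all() and abs(np.linalg.norm(w) - 1) < 1e-9

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            fld_weights(X, np.ones(10, int))

    def test_all_zero_data_rejected(self):
        labels = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="zero"):
            fld_weights(np.zeros((10, 3)), labels)


class TestSpatialProject:
    def setup_method(self):
        self.windows = WindowingScheme.tile(60, 600.0, 100.0)

    def test_single_channel_unit_weight_returns_window_mean(self, rng):
        data = rng.standard_normal((5, 1, 60))
        feats = window_features(data, self.windows)
        y = spatial_project(feats, np.ones((1, 1)), self.windows)
        np.testing.assert_allclose(y[:, 0], data.mean(axis=(1, 2)))

    def test_zero_weights_give_zero(self, rng):
        feats = rng.standard_normal((4, 1, 3))
        y = spatial_project(feats, np.zeros((1, 3)), self.windows)
        np.testing.assert_array_equal(y, 0.0)

    def test_homogeneity(self, rng):
        feats = rng.standard_normal((4, 1, 3))
        W = rng.standard_normal((1, 3))
        np.testing.assert_allclose(spatial_project(feats, 2 * W, self.windows),
                                   2 * spatial_project(feats, W, self.windows))

    def test_channel_mismatch_raises(self, rng):
        feats = rng.standard_normal((4, 1, 3))
        with pytest.raises(ValueError, match="channel"):
            spatial_project(feats, np.ones((1, 5)), self.windows)


class TestTemporalFusion:
    def test_separable_scores_reach_perfect_training_accuracy(self):
        y = np.linspace(-3, 3, 40).reshape(-1, 1)
        labels = (y[:, 0] > 0).astype(int)
        v, b = fit_temporal(y, labels)
        pred = (y @ v + b) > 0
        assert (pred == labels).all()

    def test_permuted_labels_near_chance(self, rng):
        y = rng.standard_normal((200, 5))
        labels = rng.permutation(np.repeat([0, 1], 100))
        accs = []
        for test in np.array_split(rng.permutation(200), 5):
            mask = np.ones(200, bool)
            mask[test] = False
            v, b = fit_temporal(y[mask], labels[mask])
            accs.append((((y[test] @ v + b) > 0) == labels[test]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.12  # 95% binomial band for n=200

    def test_duplicated_column_splits_weight_not_probabilities(self, rng):
        y = rng.standard_normal((80, 1))
        labels = (y[:, 0] + 0.3 * rng.standard_normal(80) > 0).astype(int)
        v1, b1 = fit_temporal(y, labels)
        v2, b2 = fit_temporal(np.hstack([y, y]), labels)
        # L2-regularised fit splits coefficient mass equally across the copies
        np.testing.assert_allclose(v2[0], v2[1], atol=1e-4)
        p1 = 1 / (1 + np.exp(-(y @ v1 + b1)))
        p2 = 1 / (1 + np.exp(-(np.hstack([y, y]) @ v2 + b2)))
        # probabilities shift slightly (the duplicate halves the L2 penalty),
        # but the ranking and the 0.5-threshold decisions are unchanged
        np.testing.assert_array_equal(np.argsort(p1), np.argsort(p2))
        np.testing.assert_array_equal(p1 >= 0.5, p2 >= 0.5)


class TestTrainScoreClassify:
    def test_training_is_deterministic(self, quiet_epochs):
        m1 = train(quiet_epochs)
        m2 = train(quiet_epochs)
        np.testing.assert_array_equal(m1.spatial_weights, m2.spatial_weights)
        np.testing.assert_array_equal(m1.temporal_weights, m2.temporal_weights)
        assert m1.intercept == m2.intercept

    def test_high_snr_heldout_accuracy_above_90(self, quiet_config):
        from rsvpauth import experiments
        train_ep = experiments.session_epochs(quiet_config, include=("user", "blind"))
        test_ep = experiments.session_epochs(quiet_config.replace(seed=quiet_config.seed + 1),
                                             include=("user", "blind"))
        model = train(train_ep)
        dec = classify(test_ep, model)
        assert ((dec == (test_ep.labels == 1)).mean()) > 0.9

    def test_scores_lie_in_unit_interval(self, quiet_epochs):
        model = train(quiet_epochs)
        s = score(quiet_epochs, model)
        assert np.all((s >= 0) & (s <= 1))

    def test_scale_invariance_of_decisions(self, quiet_epochs):
        import dataclasses
        model_a = train(quiet_epochs)
        scaled = dataclasses.replace(quiet_epochs, data=quiet_epochs.data * 7.5)
        model_b = train(scaled)
        np.testing.assert_array_equal(classify(quiet_epochs, model_a),
                                      classify(scaled, model_b))

    def test_single_window_reduces_to_plain_fld_ranking(self, quiet_epochs):
        whole = WindowingScheme.tile(quiet_epochs.n_times, quiet_epochs.fs,
                                     window_ms=1000.0)
        model = train(quiet_epochs, windows=whole)
        s = score(quiet_epochs, model)
        means = quiet_epochs.data.mean(axis=2)  # whole-epoch channel means
        w = fld_weights(means, quiet_epochs.labels)
        proj = means @ w
        # logistic calibration is monotone, so rankings must agree exactly
        np.testing.assert_array_equal(np.argsort(s), np.argsort(proj))

    def test_login_aggregation_uses_mean_score(self, quiet_epochs):
        model = train(quiet_epochs)
        s = score(quiet_epochs, model)
        got = classify(quiet_epochs, model, trials_per_login=2)
        n = (s.size // 2) * 2
        expected = s[:n].reshape(-1, 2).mean(axis=1) >= model.threshold
        np.testing.assert_array_equal(got, expected)

    def test_threshold_zero_accepts_everything(self, quiet_epochs):
        model = train(quiet_epochs, threshold=0.0)
        assert classify(quiet_epochs, model).all()

    def test_mask_restricts_model_channels(self, quiet_epochs):
        mask = np.zeros(quiet_epochs.n_channels, bool)
        mask[[CHANNELS_16.index(c) for c in ("P3", "Pz", "P4")]] = True
        model = train(quiet_epochs, channel_mask=mask)
        assert model.spatial_weights.shape[1] == 3


@pytest.fixture(scope="module")
def localised_model():
    from rsvpauth import experiments

    epochs = experiments.recovery_dataset(seed=123)
    return train(epochs)


class TestEffectLocalisation:
    """Injected parietal 300–500 ms effect must surface in the weights."""

    def test_temporal_weights_peak_in_injected_windows(self, localised_model):
        peak = int(np.argmax(np.abs(localised_model.temporal_weights)))
        assert peak in (3, 4)  # 300–400 and 400–500 ms windows

    def test_spatial_mass_concentrates_on_injected_channels(self, localised_model):
        idx = [CHANNELS_16.index(c) for c in ("P3", "Pz", "P4")]
        W = localised_model.spatial_weights[3:5]  # injected windows
        mass = (W[:, idx] ** 2).sum() / (W ** 2).sum()
        assert mass >= 0.5
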