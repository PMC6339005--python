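"""Hierarchical discriminant component analysis (HDCA) for ERP epochs.

HDCA is a two-level linear classifier for single-trial ERP detection.  The
epoch is tiled into consecutive time windows (default 100 ms).  Level one
learns, per window n, a Fisher-linear-discriminant spatial weight vector
w_n over channels, compressing the multichannel signal into one window score

    y_n = Σ_i w_{n,i} x̄_{i,n},

where x̄_{i,n} is channel i's mean over window n.  Level two fuses the
window scores with logistic-regression weights v_k into a single interest
score per trial,

    Y_S = σ(Σ_k v_k y_k + b),

calibrated so self-face (target) trials score higher than non-self trials.
A trial is accepted when Y_S reaches the decision threshold (default 0.5);
a login attempt spanning several trials is decided by the mean score.

The spatial step uses shrinkage-regularised FLD, w ∝ (S_w + λI)⁻¹(μ₁ − μ₀),
with the shrinkage intensity λ chosen by the Ledoit–Wolf formula, so
rank-deficient window covariances (duplicate or silent channels) stay
solvable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.linear_model import LogisticRegression

from .preprocess import EpochSet

#: L2 regularisation strength (sklearn ``C``) of the temporal logistic fit.
LOGREG_C = 1.0


@dataclass(frozen=True)
class WindowingScheme:
    """Non-overlapping tiling of the epoch into equal time windows."""

    window_ms: float
    bounds: tuple[tuple[int, int], ...]  # half-open sample ranges

    @property
    def n_windows(self) -> int:
        return len(self.bounds)

    @classmethod
    def tile(cls, n_samples: int, fs: float, window_ms: float = 100.0) -> "WindowingScheme":
        """Tile ``n_samples`` at ``fs`` into floor-many ``window_ms`` windows."""
        per = int(round(window_ms * fs / 1000.0))
        if per < 1 or per > n_samples:
            raise ValueError("window does not fit the epoch")
        n_win = n_samples // per
        bounds = tuple((k * per, (k + 1) * per) for k in range(n_win))
        return cls(window_ms=window_ms, bounds=bounds)


@dataclass
class HDCAModel:
    """Trained two-level model.

    ``spatial_weights`` is n_windows × n_selected_channels (w_{n,i});
    ``temporal_weights``/``intercept`` are the logistic fusion (v_k, b);
    ``channel_mask`` records which montage channels the model consumes.
    """

    spatial_weights: np.ndarray
    temporal_weights: np.ndarray
    intercept: float
    threshold: float
    windows: WindowingScheme
    channel_mask: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.spatial_weights = np.asarray(self.spatial_weights, float)
        self.temporal_weights = np.asarray(self.temporal_weights, float)
        self.channel_mask = np.asarray(self.channel_mask, bool)
        if self.spatial_weights.shape[0] != self.windows.n_windows:
            raise ValueError("one spatial weight row per window required")
        if self.temporal_weights.shape[0] != self.windows.n_windows:
            raise ValueError("one temporal weight per window required")
        if self.spatial_weights.shape[1] != int(self.channel_mask.sum()):
            raise ValueError("spatial weight columns must match selected channels")


def window_features(data: np.ndarray, windows: WindowingScheme) -> np.ndarray:
    """Per-window per-channel means: trials × n_windows × channels."""
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("data must be trials × channels × time")
    feats = np.empty((data.shape[0], windows.n_windows, data.shape[1]))
    for k, (a, b) in enumerate(windows.bounds):
        feats[:, k, :] = data[:, :, a:b].mean(axis=2)
    return feats


def fld_weights(X: np.ndarray, labels: np.ndarray,
                shrinkage: float | None = None) -> np.ndarray:
    """Shrinkage-FLD spatial weights for one window.

    Solves (S_w + shrinkage-target)⁻¹ (μ₁ − μ₀) with the convex shrinkage
    S = (1−λ) S_w + λ (tr S_w / C) I, λ from the Ledoit–Wolf estimator unless
    given.  The result has unit L2 norm and is signed so the self class
    projects higher than the non-self class.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels, int)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if min(np.sum(labels == c) for c in classes) < 2:
        raise ValueError("need at least 2 trials per class")
    mu0 = X[labels == 0].mean(axis=0)
    mu1 = X[labels == 1].mean(axis=0)
    centered = X.copy()
    centered[labels == 0] -= mu0
    centered[labels == 1] -= mu1
    n, c = X.shape
    S = centered.T @ centered / n  # pooled within-class covariance (MLE)
    if shrinkage is None:
        shrinkage = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
    target = np.trace(S) / c
    if target == 0:
        raise ValueError("all-zero data: no within-class variance")
    S_shrunk = (1.0 - shrinkage) * S + shrinkage * target * np.eye(c)
    w = np.linalg.solve(S_shrunk, mu1 - mu0)
    norm = np.linalg.norm(w)
    if norm == 0:
        # equal class means: any unit direction is as (un)informative
        w = np.zeros(c)
        w[0] = 1.0
        return w
    w /= norm
    if (X[labels == 1] @ w).mean() < (X[labels == 0] @ w).mean():
        w = -w
    return w


def spatial_project(epochs: EpochSet | np.ndarray, spatial_weights: np.ndarray,
                    windows: WindowingScheme) -> np.ndarray:
    """Window scores y: trials × n_windows, y[:, n] = feats[:, n, :] @ w_n."""
    if isinstance(epochs, EpochSet):
        feats = window_features(epochs.data, windows)
    else:
        feats = np.asarray(epochs, float)
    W = np.asarray(spatial_weights, float)
    if feats.shape[2] != W.shape[1]:
        raise ValueError(f"channel count mismatch: data has {feats.shape[2]}, "
                         f"weights expect {W.shape[1]}")
    return np.einsum("tnc,nc->tn", feats, W)


def fit_temporal(y: np.ndarray, labels: np.ndarray,
                 C: float = LOGREG_C) -> tuple[np.ndarray, float]:
    """Logistic-regression fusion weights (v_k, intercept) on window scores."""
    y = np.asarray(y, float)
    labels = np.asarray(labels, int)
    if np.unique(labels).size != 2:
        raise ValueError("exactly two classes required")
    lr = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    lr.fit(y, labels)
    return lr.coef_[0].copy(), float(lr.intercept_[0])


def fit_features(feats: np.ndarray, labels: np.ndarray,
                 C: float = LOGREG_C) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit both HDCA levels on precomputed window features.

    Low-level entry point used by cross-validation and the GA fitness loop,
    where features are computed once and channel subsets are sliced out.
    Returns ``(spatial_weights, temporal_weights, intercept)``.
    """
    n_win = feats.shape[1]
    W = np.stack([fld_weights(feats[:, n, :], labels) for n in range(n_win)])
    y = np.einsum("tnc,nc->tn", feats, W)
    v, b = fit_temporal(y, labels, C)
    return W, v, b


def score_features(feats: np.ndarray, W: np.ndarray, v: np.ndarray,
                   b: float) -> np.ndarray:
    """Interest scores Y_S in [0, 1] from precomputed window features."""
    y = np.einsum("tnc,nc->tn", np.asarray(feats, float), W)
    return expit(y @ v + b)


def train(epochs: EpochSet, labels: np.ndarray | None = None,
          windows: WindowingScheme | None = None,
          channel_mask: np.ndarray | None = None,
          threshold: float = 0.5, C: float = LOGREG_C) -> HDCAModel:
    """Train HDCA on classification-ready epochs (crop to 0..1000 ms first).

    ``channel_mask`` (boolean over the montage) restricts the model to a
    channel subset, as selected by the genetic algorithm; default all
    channels.
    """
    if labels is None:
        labels = epochs.labels
    if channel_mask is None:
        channel_mask = np.ones(epochs.n_channels, dtype=bool)
    channel_mask = np.asarray(channel_mask, bool)
    if channel_mask.size != epochs.n_channels or not channel_mask.any():
        raise ValueError("channel_mask must cover the montage and select >= 1 channel")
    if windows is None:
        windows = WindowingScheme.tile(epochs.n_times, epochs.fs)
    feats = window_features(epochs.data[:, channel_mask, :], windows)
    W, v, b = fit_features(feats, labels, C)
    return HDCAModel(spatial_weights=W, temporal_weights=v, intercept=b,
                     threshold=threshold, windows=windows,
                     channel_mask=channel_mask,
                     channel_names=epochs.channel_names)


def score(epochs: EpochSet, model: HDCAModel) -> np.ndarray:
    """Per-trial interest score Y_S ∈ [0, 1]."""
    if epochs.n_channels != model.channel_mask.size:
        raise ValueError("epochs do not match the model's montage")
    feats = window_features(epochs.data[:, model.channel_mask, :], model.windows)
    return score_features(feats, model.spatial_weights,
                          model.temporal_weights, model.intercept)


def classify(epochs: EpochSet, model: HDCAModel,
             trials_per_login: int | None = None) -> np.ndarray:
    """Accept/reject decisions: Y_S ≥ threshold.

    With ``trials_per_login`` set, consecutive trials are grouped into login
    attempts decided by the mean score against the threshold (this is also
    the tie rule when per-trial decisions disagree); returns one decision
    per attempt, trailing incomplete groups dropped.
    """
    s = score(epochs, model)
    if trials_per_login is None:
        return s >= model.threshold
    if trials_per_login < 1:
        raise ValueError("trials_per_login must be >= 1")
    n_full = s.size // trials_per_login
    grouped = s[: n_full * trials_per_login].reshape(n_full, trials_per_login)
    return grouped.mean(axis=1) >= model.threshold
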