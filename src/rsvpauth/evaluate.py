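"""Authentication-performance evaluation: ACC / FAR / FRR, cross-validation,
and the cross-session permanence test.

Biometric error rates, in percent:

    ACC = 100 · correct / total test samples
    FAR = 100 · falsely accepted / imposter test samples
    FRR = 100 · falsely rejected / user test samples

Performance within one session is measured by stratified 5-fold
cross-validation, pooling held-out decisions over folds; permanence (model
stability over time) is measured by applying the session-1 model to
session-2 epochs without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import hdca
from .preprocess import EpochSet


@dataclass(frozen=True)
class AuthProtocol:
    """Study-design constants of the authentication protocol.

    15 account holders, each attacked by two imposters (one blind, one who
    knows the user), give 45 subject-level datasets; a login attempt uses 2
    consecutive RSVP trials.
    """

    n_users: int = 15
    imposters_per_user: int = 2
    trials_per_login: int = 2

    @property
    def n_imposters(self) -> int:
        return self.n_users * self.imposters_per_user

    @property
    def n_datasets(self) -> int:
        return self.n_users + self.n_imposters

    def login_seconds(self, trial_duration_ms: float = 3000.0) -> float:
        return self.trials_per_login * trial_duration_ms / 1000.0


@dataclass
class AuthMetrics:
    """Confusion counts with ACC/FAR/FRR views (percentages)."""

    n_user_test: int
    n_imposter_test: int
    false_accepts: int
    false_rejects: int

    def __post_init__(self) -> None:
        if self.false_accepts > self.n_imposter_test or self.false_rejects > self.n_user_test:
            raise ValueError("error counts exceed test-set sizes")

    @property
    def n_test(self) -> int:
        return self.n_user_test + self.n_imposter_test

    @property
    def acc(self) -> float:
        return 100.0 * (1.0 - (self.false_accepts + self.false_rejects) / self.n_test)

    @property
    def far(self) -> float:
        """Percent of imposter attempts accepted; NaN if none were tested."""
        if self.n_imposter_test == 0:
            return float("nan")
        return 100.0 * self.false_accepts / self.n_imposter_test

    @property
    def frr(self) -> float:
        """Percent of genuine attempts rejected; NaN if none were tested."""
        if self.n_user_test == 0:
            return float("nan")
        return 100.0 * self.false_rejects / self.n_user_test

    def as_dict(self, ndigits: int = 2) -> dict:
        return {
            "n_user_test": self.n_user_test,
            "n_imposter_test": self.n_imposter_test,
            "false_accepts": self.false_accepts,
            "false_rejects": self.false_rejects,
            "acc": round(self.acc, ndigits),
            "far": round(self.far, ndigits) if self.n_imposter_test else float("nan"),
            "frr": round(self.frr, ndigits) if self.n_user_test else float("nan"),
        }


def compute_metrics(decisions: np.ndarray, labels: np.ndarray,
                    strict: bool = True) -> AuthMetrics:
    """Confusion counts from accept decisions vs true labels (1 = user).

    With ``strict`` (default), both classes must be present so FAR and FRR
    are both defined; permanence tests on user-only data pass ``strict=False``
    and read NaN for the undefined rate.
    """
    decisions = np.asarray(decisions, bool)
    labels = np.asarray(labels, int)
    if decisions.shape != labels.shape:
        raise ValueError("decisions and labels must align")
    if decisions.size == 0:
        raise ValueError("empty test set")
    n_user = int((labels == 1).sum())
    n_imp = int((labels == 0).sum())
    if strict and (n_user == 0 or n_imp == 0):
        raise ValueError("both classes must be present (use strict=False to allow one)")
    fa = int((decisions & (labels == 0)).sum())
    fr = int((~decisions & (labels == 1)).sum())
    return AuthMetrics(n_user_test=n_user, n_imposter_test=n_imp,
                       false_accepts=fa, false_rejects=fr)


def make_folds(labels: np.ndarray, n_folds: int = 5,
               seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled, seed-reproducible (train, test) index pairs."""
    labels = np.asarray(labels, int)
    for cls in np.unique(labels):
        if (labels == cls).sum() < n_folds:
            raise ValueError(f"class {cls} has fewer trials than folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(labels.size), labels)]


def cv_accuracy(feats: np.ndarray, labels: np.ndarray,
                folds: list[tuple[np.ndarray, np.ndarray]],
                mask: np.ndarray | None = None,
                threshold: float = 0.5) -> float:
    """Pooled cross-validated accuracy on precomputed window features.

    ``mask`` selects a channel subset (last feature axis).  This is the GA
    fitness kernel: with the fold assignment frozen, accuracy is a
    deterministic function of the mask.
    """
    labels = np.asarray(labels, int)
    if mask is not None:
        feats = feats[:, :, np.asarray(mask, bool)]
    correct = 0
    for tr, te in folds:
        W, v, b = hdca.fit_features(feats[tr], labels[tr])
        dec = hdca.score_features(feats[te], W, v, b) >= threshold
        correct += int((dec == (labels[te] == 1)).sum())
    return correct / labels.size


def crossval(epochs: EpochSet, labels: np.ndarray | None = None,
             folds: int = 5, seed: int = 0,
             channel_mask: np.ndarray | None = None,
             windows: hdca.WindowingScheme | None = None,
             return_fold_details: bool = False):
    """Stratified k-fold cross-validation of HDCA (or GA-HDCA via a mask).

    Per fold, HDCA is trained on the training trials only and applied to the
    held-out trials; decisions are pooled over folds into one
    :class:`AuthMetrics`, so every trial is tested exactly once.
    """
    if labels is None:
        labels = epochs.labels
    labels = np.asarray(labels, int)
    if windows is None:
        windows = hdca.WindowingScheme.tile(epochs.n_times, epochs.fs)
    data = epochs.data
    if channel_mask is not None:
        data = data[:, np.asarray(channel_mask, bool), :]
    feats = hdca.window_features(data, windows)

    fold_idx = make_folds(labels, folds, seed)
    decisions = np.zeros(labels.size, dtype=bool)
    fold_acc = []
    for tr, te in fold_idx:
        W, v, b = hdca.fit_features(feats[tr], labels[tr])
        dec = hdca.score_features(feats[te], W, v, b) >= 0.5
        decisions[te] = dec
        fold_acc.append(float((dec == (labels[te] == 1)).mean()))
    metrics = compute_metrics(decisions, labels)
    if return_fold_details:
        return metrics, fold_acc
    return metrics


def permanence_test(model: hdca.HDCAModel, epochs: EpochSet) -> AuthMetrics:
    """Apply a previously trained model to later-session epochs, no refit.

    Measures biometric permanence: how well the enrolment-session model
    survives day-scale nonstationarity of the ERP response.
    """
    if epochs.n_channels != model.channel_mask.size:
        raise ValueError("session-2 epochs do not match the model's montage")
    decisions = hdca.classify(epochs, model)
    return compute_metrics(decisions, epochs.labels, strict=False)
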