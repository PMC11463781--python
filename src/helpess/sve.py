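"""Splitting Voting Ensemble (SVE) for strongly imbalanced binary problems.

The majority-class training rows are partitioned into n near-equal slices
(n chosen so that each slice is roughly the size of the minority class);
one base learner is trained per slice joined with the complete minority
class, and the ensemble's probability for a row is the plain arithmetic
mean of the n members' class-1 probabilities. Every training row is used
exactly once on the majority side — no subsampling discards data and no
oversampling duplicates or synthesises rows.

The base learner is a pluggable scikit-learn-style classifier; the default
is a LightGBM gradient-boosted tree ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone

logger = logging.getLogger("helpess")


def default_base_learner(seed: int = 0, **params):
    """LightGBM classifier with deterministic, single-threaded settings."""
    from lightgbm import LGBMClassifier

    defaults = dict(random_state=seed, n_jobs=1, verbose=-1)
    defaults.update(params)
    return LGBMClassifier(**defaults)


@dataclass
class SVEConfig:
    """Configuration of the ensemble: base learner, slice count, decision rule."""

    base_learner: object | None = None  # cloneable classifier with predict_proba
    n_override: int | None = None
    seed: int = 0
    decision_threshold: float = 0.5
    base_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_override is not None and self.n_override < 1:
            raise ValueError("n_override must be >= 1")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must lie in (0, 1)")

    def make_base(self):
        if self.base_learner is not None:
            return clone(self.base_learner)
        return default_base_learner(self.seed, **self.base_params)


def choose_n(n_majority: int, n_minority: int) -> int:
    """Number of ensemble members: max(1, floor(majority / minority)).

    This makes every slice approximately the size of the minority class,
    so each member trains on a balanced subset.
    """
    if n_minority < 1:
        raise ValueError("minority class is empty")
    return max(1, n_majority // n_minority)


class SVEClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style estimator wrapping the splitting-voting scheme.

    Parameters mirror :class:`SVEConfig`; after :meth:`fit` the trained
    members, the slice assignment of every majority row and the class
    roles are exposed as attributes.
    """

    def __init__(self, base_learner=None, n_override=None, seed=0,
                 decision_threshold=0.5, base_params=None):
        self.base_learner = base_learner
        self.n_override = n_override
        self.seed = seed
        self.decision_threshold = decision_threshold
        self.base_params = base_params

    def _config(self) -> SVEConfig:
        return SVEConfig(
            base_learner=self.base_learner,
            n_override=self.n_override,
            seed=self.seed,
            decision_threshold=self.decision_threshold,
            base_params=self.base_params or {},
        )

    def fit(self, X, y):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SVE requires exactly two classes in y")
        minority, majority = classes[np.argsort(counts)]
        self.classes_ = np.sort(classes)
        self.minority_, self.majority_ = minority, majority

        maj_idx = np.flatnonzero(y == majority)
        min_idx = np.flatnonzero(y == minority)
        n = cfg.n_override or choose_n(len(maj_idx), len(min_idx))
        rng = np.random.default_rng(cfg.seed)
        shuffled = rng.permutation(maj_idx)
        # round-robin deal keeps slice sizes within one of each other
        self.slice_assignment_ = {int(row): int(i % n) for i, row in enumerate(shuffled)}
        self.members_ = []
        for i in range(n):
            rows = np.sort(np.concatenate([shuffled[i::n], min_idx]))
            member = cfg.make_base()
            try:
                member.fit(X[rows], y[rows])
            except Exception as exc:  # pragma: no cover - propagated with context
                raise RuntimeError(f"base learner failed on member {i}: {exc}") from exc
            self.members_.append(member)
        self.n_members_ = n
        return self

    def _positive_proba(self, member, X) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            # members are fitted and queried on bare arrays; silence the
            # sklearn feature-name bookkeeping warning that lightgbm triggers
            warnings.filterwarnings("ignore", message=".*valid feature names.*")
            proba = member.predict_proba(X)
        col = list(member.classes_).index(self.classes_[1])
        return proba[:, col]

    def predict_proba(self, X):
        """Class probabilities: the exact mean over members, per row."""
        X = self._check_columns(X)
        pos = np.mean([self._positive_proba(m, X) for m in self.members_], axis=0)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X, threshold: float | None = None):
        """Hard labels: positive class iff probability >= threshold (default 0.5)."""
        t = self.decision_threshold if threshold is None else threshold
        pos = self.predict_proba(X)[:, 1]
        return np.where(pos >= t, self.classes_[1], self.classes_[0])

    def _check_columns(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        n_fit = getattr(self.members_[0], "n_features_in_", X.shape[1])
        if X.shape[1] != n_fit:
            raise ValueError(f"expected {n_fit} features, got {X.shape[1]}")
        return X
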