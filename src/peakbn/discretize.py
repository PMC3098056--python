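"""Sklearn-style transformer for per-feature max-MI three-bin discretization."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .info import apply_boundaries, discretize_max_mi

__all__ = ["MaxMIDiscretizer", "DiscretizedTable"]


class MaxMIDiscretizer(TransformerMixin, BaseEstimator):
    """Discretize each feature into low/medium/high bins maximizing class MI.

    For every column the two cut points (b_low < b_high) that maximize
    MI(class; binned column) are found by sweeping a candidate grid — all
    midpoints between consecutive distinct values when there are at most
    ``exhaustive_cap`` of them, else midpoints near ``n_quantiles`` evenly
    spaced sample quantiles.  Values strictly below b_low bin low, strictly
    above b_high bin high, everything else (including boundary hits) medium.

    Parameters
    ----------
    exhaustive_cap : int, default 64
        Largest number of distinct-value midpoints for which the grid is
        exhaustive.
    n_quantiles : int, default 64
        Number of quantile-based candidate cuts above the cap.

    Attributes
    ----------
    boundaries_ : ndarray, shape (n_features, 2)
        The fitted (b_low, b_high) per column.
    mi_ : ndarray, shape (n_features,)
        MI(class; binned column) in bits at the chosen boundaries.
    mode_ : list of str
        Grid used per column ("exhaustive"/"quantile") or the degenerate
        fallback ("two-level"/"constant").
    """

    def __init__(self, exhaustive_cap: int = 64, n_quantiles: int = 64):
        self.exhaustive_cap = exhaustive_cap
        self.n_quantiles = n_quantiles

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        nf = X.shape[1]
        self.boundaries_ = np.empty((nf, 2))
        self.mi_ = np.empty(nf)
        self.mode_ = []
        for j in range(nf):
            res = discretize_max_mi(
                X[:, j], y,
                exhaustive_cap=self.exhaustive_cap,
                n_quantiles=self.n_quantiles,
            )
            self.boundaries_[j] = (res.b_low, res.b_high)
            self.mi_[j] = res.mi
            self.mode_.append(res.mode)
        self.n_features_in_ = nf
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "boundaries_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; fitted with {self.n_features_in_}"
            )
        out = np.empty(X.shape, dtype=np.int8)
        for j in range(X.shape[1]):
            out[:, j] = apply_boundaries(X[:, j], *self.boundaries_[j])
        return out


class DiscretizedTable:
    """Binned view of a :class:`~peakbn.data.SampleTable`.

    Bundles the integer bin matrix with the fitted boundaries and the
    per-feature MI with the class, keyed by m/z feature ids.
    """

    def __init__(self, bins, boundaries, per_feature_mi, feature_ids, modes=None):
        self.bins = np.asarray(bins, dtype=np.int8)
        self.boundaries = np.asarray(boundaries, dtype=float)
        self.per_feature_mi = np.asarray(per_feature_mi, dtype=float)
        self.feature_ids = np.asarray(feature_ids)
        self.modes = list(modes) if modes is not None else None
        if not (self.boundaries[:, 0] < self.boundaries[:, 1]).all():
            raise ValueError("every feature needs b_low < b_high")
        if self.bins.shape[1] != self.feature_ids.size:
            raise ValueError("bins / feature_ids shape mismatch")

    @classmethod
    def from_table(cls, table, exhaustive_cap: int = 64, n_quantiles: int = 64):
        disc = MaxMIDiscretizer(exhaustive_cap, n_quantiles).fit(
            table.abundances, table.class_codes
        )
        return cls(
            bins=disc.transform(table.abundances),
            boundaries=disc.boundaries_,
            per_feature_mi=disc.mi_,
            feature_ids=table.feature_ids,
            modes=disc.mode_,
        )

    def mi_by_feature(self) -> dict:
        return dict(zip(self.feature_ids.tolist(), self.per_feature_mi.tolist()))
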