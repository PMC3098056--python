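"""Mutual-information primitives for peak-table feature screening.

Everything here works on discrete (or discretized) data with plain empirical
(maximum-likelihood) probability estimates — no shrinkage and no bias
correction.  MI is reported in bits.  The module provides:

* :func:`mutual_information` and :func:`conditional_mutual_information`;
* :func:`discretize_max_mi`, the three-bin (low/medium/high) discretization
  that chooses the two cut points maximizing MI(class; binned feature);
* :func:`permutation_baseline`, the class-label permutation null used to set
  the significance threshold for feature screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ThresholdSpec",
    "DiscretizationResult",
    "mutual_information",
    "conditional_mutual_information",
    "discretize_max_mi",
    "apply_boundaries",
    "permutation_baseline",
]

#: low / medium / high bin codes
LOW, MEDIUM, HIGH = 0, 1, 2


@dataclass(frozen=True)
class ThresholdSpec:
    """Significance threshold for MI(class; feature) screening.

    ``baseline_mi`` is the largest MI (bits) obtained when class labels are
    randomly permuted and every feature is re-discretized against the permuted
    labels; ``multiplier`` is the empirical safety factor applied on top of
    it (3.2 by default).  ``effective_threshold`` is their exact product.
    """

    baseline_mi: float
    multiplier: float = 3.2

    def __post_init__(self) -> None:
        if self.baseline_mi < 0:
            raise ValueError(f"baseline_mi must be >= 0, got {self.baseline_mi}")
        if self.multiplier <= 0:
            raise ValueError(f"multiplier must be > 0, got {self.multiplier}")

    @property
    def effective_threshold(self) -> float:
        return self.baseline_mi * self.multiplier


def _codes(v: Sequence) -> tuple[np.ndarray, int]:
    """Integer-code an arbitrary discrete vector (alphabet in sorted order)."""
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if arr.size == 0:
        raise ValueError("empty input")
    _, inv = np.unique(arr, return_inverse=True)
    return inv.astype(np.intp), int(inv.max()) + 1


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """MI in bits from contingency counts; last two axes are the table.

    Zero cells contribute 0 (the 0*log(0) := 0 convention).
    """
    n = counts.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n
        pr = p.sum(axis=-1, keepdims=True)
        pc = p.sum(axis=-2, keepdims=True)
        terms = p * np.log2(p / (pr * pc))
    terms = np.where(counts > 0, terms, 0.0)
    mi = terms.sum(axis=(-2, -1))
    # clip tiny negative round-off
    return np.maximum(mi, 0.0)


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Empirical mutual information MI(X;Y) in bits.

    Probabilities are plain cell frequencies of the joint contingency table;
    the result is symmetric in its arguments and bounded by the log2 of the
    smaller alphabet.
    """
    xi, kx = _codes(x)
    yi, ky = _codes(y)
    if xi.shape != yi.shape:
        raise ValueError(f"length mismatch: {xi.size} vs {yi.size}")
    counts = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky)
    return float(_mi_from_counts(counts.astype(float)))


def conditional_mutual_information(c: Sequence, v2: Sequence, v1: Sequence) -> float:
    """Conditional mutual information MI(C; V2 | V1) in bits.

    The sample is partitioned by the value of ``v1`` and the MI between ``c``
    and ``v2`` inside each stratum is averaged with weights P(v1):
    CMI = sum_v P(V1=v) * MI(C; V2 | V1=v).
    """
    ci, _ = _codes(c)
    v2i, _ = _codes(v2)
    v1i, k1 = _codes(v1)
    if not (ci.shape == v2i.shape == v1i.shape):
        raise ValueError("length mismatch among c, v2, v1")
    n = ci.size
    total = 0.0
    for s in range(k1):
        mask = v1i == s
        ns = int(mask.sum())
        if ns < 2:
            # a single-case stratum carries no information
            continue
        total += (ns / n) * mutual_information(ci[mask], v2i[mask])
    return total


@dataclass(frozen=True)
class DiscretizationResult:
    """Outcome of the max-MI three-bin discretization of one feature."""

    b_low: float
    b_high: float
    bins: np.ndarray = field(repr=False)
    mi: float
    #: "exhaustive" | "quantile" | "two-level" | "constant"
    mode: str

    @property
    def degenerate(self) -> bool:
        return self.mode in ("two-level", "constant")


def apply_boundaries(values: np.ndarray, b_low: float, b_high: float) -> np.ndarray:
    """Bin values with frozen boundaries: <b_low -> low, >b_high -> high.

    A value exactly equal to a boundary falls in the medium bin, so the
    extreme bins stay strictly extreme.  Out-of-range values in new data bin
    as usual (they land in low or high); nothing is rejected.
    """
    v = np.asarray(values, dtype=float)
    return np.where(v < b_low, LOW, np.where(v > b_high, HIGH, MEDIUM)).astype(np.int8)


def _cut_positions(
    v_sorted: np.ndarray, exhaustive_cap: int, n_quantiles: int
) -> tuple[np.ndarray, str]:
    """Candidate cut positions (index i = first i sorted cases below the cut).

    Exhaustive grid = every midpoint between consecutive distinct values when
    there are at most ``exhaustive_cap`` of them; otherwise the midpoints
    nearest ``n_quantiles`` evenly spaced sample quantiles.
    """
    n = v_sorted.size
    change = np.flatnonzero(np.diff(v_sorted)) + 1  # positions in [1, n-1]
    if change.size <= exhaustive_cap:
        return change, "exhaustive"
    qs = np.linspace(0.0, 1.0, n_quantiles + 2)[1:-1]
    qv = np.quantile(v_sorted, qs)
    pos = np.unique(np.searchsorted(v_sorted, qv, side="right"))
    pos = pos[(pos >= 1) & (pos <= n - 1)]
    # snap to actual value-change positions so every cut is a real midpoint
    pos = np.unique(change[np.searchsorted(change, pos, side="left").clip(max=change.size - 1)])
    return pos, "quantile"


def discretize_max_mi(
    values: Sequence,
    class_labels: Sequence,
    exhaustive_cap: int = 64,
    n_quantiles: int = 64,
) -> DiscretizationResult:
    """Three-bin discretization of one feature maximizing MI with the class.

    Both cut points are swept over a candidate grid (all pairs b_low < b_high)
    and the pair with the largest MI(class; binned feature) is kept.  The grid
    is every midpoint between consecutive distinct values (exhaustive) when
    the feature has few distinct values, else midpoints near evenly spaced
    sample quantiles (``n_quantiles`` candidates).

    Features with fewer than 3 distinct values fall back to a single cut
    ("two-level") or to a constant medium bin with MI 0 ("constant"); the
    fallback is flagged in ``mode``.
    """
    v = np.asarray(values, dtype=float)
    yi, kc = _codes(class_labels)
    if v.shape != yi.shape:
        raise ValueError(f"length mismatch: {v.size} values vs {yi.size} labels")

    distinct = np.unique(v)
    if distinct.size == 1:
        b_low, b_high = distinct[0] - 0.5, distinct[0] + 0.5
        return DiscretizationResult(
            b_low, b_high, np.full(v.shape, MEDIUM, dtype=np.int8), 0.0, "constant"
        )
    if distinct.size == 2:
        a, b = distinct
        b_low = 0.5 * (a + b)
        bins = apply_boundaries(v, b_low, b)
        mi = mutual_information(bins, yi)
        return DiscretizationResult(b_low, float(b), bins, mi, "two-level")

    n = v.size
    order = np.argsort(v, kind="stable")
    vs = v[order]
    ys = yi[order]
    pos, mode = _cut_positions(vs, exhaustive_cap, n_quantiles)

    onehot = np.zeros((n, kc))
    onehot[np.arange(n), ys] = 1.0
    cum = np.vstack([np.zeros((1, kc)), np.cumsum(onehot, axis=0)])  # (n+1, kc)

    ii, jj = np.triu_indices(pos.size, k=1)
    low = cum[pos[ii]]
    mid = cum[pos[jj]] - low
    high = cum[n] - cum[pos[jj]]
    counts = np.stack([low, mid, high], axis=1)  # (pairs, 3, kc)
    mis = _mi_from_counts(counts)
    best = int(np.argmax(mis))  # ties -> first pair in grid order (deterministic)
    pi, pj = int(pos[ii[best]]), int(pos[jj[best]])
    best_mi = float(mis[best])

    if mode == "quantile":
        # coordinate-wise refinement over ALL distinct-value midpoints, so the
        # coarse grid's winner is polished to a local (in practice global)
        # optimum of the exhaustive objective
        change = np.flatnonzero(np.diff(vs)) + 1
        for _ in range(10):
            moved = False
            for which in (0, 1):
                if which == 0:
                    cand = change[change < pj]
                    c_low = cum[cand]
                    c_mid = cum[pj] - c_low
                    c_high = np.broadcast_to(cum[n] - cum[pj], c_low.shape)
                else:
                    cand = change[change > pi]
                    c_low = np.broadcast_to(cum[pi], (cand.size, kc))
                    c_mid = cum[cand] - cum[pi]
                    c_high = cum[n] - cum[cand]
                if cand.size == 0:
                    continue
                m = _mi_from_counts(np.stack([c_low, c_mid, c_high], axis=1))
                k = int(np.argmax(m))
                if m[k] > best_mi + 1e-15:
                    best_mi = float(m[k])
                    if which == 0:
                        pi = int(cand[k])
                    else:
                        pj = int(cand[k])
                    moved = True
            if not moved:
                break

    def midpoint(p: int) -> float:
        return 0.5 * (vs[p - 1] + vs[p])

    b_low = midpoint(pi)
    b_high = midpoint(pj)
    bins = apply_boundaries(v, b_low, b_high)
    return DiscretizationResult(b_low, b_high, bins, best_mi, mode)


def permutation_baseline(
    table,
    n_perm: int = 100,
    multiplier: float = 3.2,
    seed: int | None = None,
    exhaustive_cap: int = 64,
    n_quantiles: int = 64,
    class_labels: Sequence | None = None,
) -> ThresholdSpec:
    """Largest MI(class; feature) under class-label permutation.

    For each of ``n_perm`` permutations the class labels are shuffled and
    every feature is re-discretized (max-MI, same settings as the real run)
    against the shuffled labels; the maximum MI over all features and all
    permutations becomes ``baseline_mi``.  Re-discretizing per permutation is
    essential: the boundary optimization inflates null MI, and the baseline
    must absorb that inflation.

    ``table`` may be a SampleTable or a 2-D abundance array (cases x
    features); in the latter case ``class_labels`` must be given.  The
    permutations are drawn sequentially from one seeded generator, so the
    baseline is non-decreasing in ``n_perm`` for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if hasattr(table, "abundances"):
        X = np.asarray(table.abundances, dtype=float)
        y = np.asarray(table.class_labels)
    else:
        X = np.asarray(table, dtype=float)
        if class_labels is None:
            raise ValueError("class_labels required when table is a plain array")
        y = np.asarray(class_labels)
    yi, _ = _codes(y)
    rng = np.random.default_rng(seed)
    baseline = 0.0
    for _ in range(n_perm):
        yp = rng.permutation(yi)
        for f in range(X.shape[1]):
            res = discretize_max_mi(
                X[:, f], yp, exhaustive_cap=exhaustive_cap, n_quantiles=n_quantiles
            )
            if res.mi > baseline:
                baseline = res.mi
    return ThresholdSpec(baseline_mi=baseline, multiplier=multiplier)
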