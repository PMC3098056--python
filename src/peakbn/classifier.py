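"""Markov-blanket classifier over the class-rooted network.

Only the first-level features (the Markov blanket of the class node) enter
the classifier: given the network structure, the class posterior factorizes
as P(class | bins) proportional to P(class) * prod_f P(bin_f | class) over
first-level features f, so child features add nothing.  Conditional
probability tables are empirical counts with Laplace smoothing; posteriors
are accumulated in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .discretize import MaxMIDiscretizer
from .info import ThresholdSpec, apply_boundaries, permutation_baseline
from .network import (
    BayesNet,
    link_features,
    orient_and_prune,
    select_first_level,
)

__all__ = [
    "ClassifierParams",
    "BayesNetClassifier",
    "fit_parameters",
    "posterior",
    "classify",
]


@dataclass
class ClassifierParams:
    """Frozen parameters of a fitted Markov-blanket classifier.

    ``cpts`` maps feature id -> (3, n_classes) array with P(bin | class) in
    columns (each column sums to 1, all entries positive after smoothing);
    ``boundaries`` maps feature id -> (b_low, b_high) frozen from training.
    """

    class_labels: list
    class_prior: np.ndarray
    cpts: dict
    boundaries: dict
    decision_threshold: float = 0.5
    positive_class: object = None

    def __post_init__(self) -> None:
        self.class_prior = np.asarray(self.class_prior, dtype=float)
        for f, t in self.cpts.items():
            t = np.asarray(t, dtype=float)
            if t.shape != (3, len(self.class_labels)):
                raise ValueError(f"CPT for {f} has shape {t.shape}")
            if not np.allclose(t.sum(axis=0), 1.0, atol=1e-12):
                raise ValueError(f"CPT columns for {f} must sum to 1")
            if not (t > 0).all():
                raise ValueError(f"CPT for {f} has non-positive entries")
            self.cpts[f] = t
        if self.positive_class is None and len(self.class_labels) == 2:
            self.positive_class = self.class_labels[1]

    @property
    def features(self) -> list:
        return list(self.cpts.keys())

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "class_labels": [str(c) for c in self.class_labels],
            "class_prior": self.class_prior.tolist(),
            "decision_threshold": self.decision_threshold,
            "positive_class": str(self.positive_class),
            "features": [
                {
                    "id": f if isinstance(f, (int, float)) else str(f),
                    "b_low": self.boundaries[f][0],
                    "b_high": self.boundaries[f][1],
                    "cpt": self.cpts[f].tolist(),
                }
                for f in self.features
            ],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassifierParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        cpts = {f["id"]: np.array(f["cpt"]) for f in obj["features"]}
        boundaries = {f["id"]: (f["b_low"], f["b_high"]) for f in obj["features"]}
        return cls(
            class_labels=obj["class_labels"],
            class_prior=np.array(obj["class_prior"]),
            cpts=cpts,
            boundaries=boundaries,
            decision_threshold=obj["decision_threshold"],
            positive_class=obj["positive_class"],
        )


def fit_parameters(
    net: BayesNet,
    bins: np.ndarray,
    feature_ids,
    class_codes: np.ndarray,
    class_labels: list,
    boundaries: np.ndarray,
    pseudocount: float = 1.0,
    decision_threshold: float = 0.5,
) -> ClassifierParams:
    """Estimate prior and first-level CPTs from binned training data.

    Each CPT cell is (count + pseudocount) normalized within its class
    column; the default pseudocount of 1 (Laplace) keeps every entry
    strictly positive even for bins unobserved in a class.
    """
    first = net.first_level
    if not first:
        raise ValueError("network has no first-level feature")
    nc = len(class_labels)
    counts_c = np.bincount(class_codes, minlength=nc).astype(float)
    if (counts_c == 0).any():
        missing = [class_labels[i] for i in np.flatnonzero(counts_c == 0)]
        raise ValueError(f"classes absent from training data: {missing}")
    idx = {f: i for i, f in enumerate(feature_ids)}
    cpts, bnds = {}, {}
    for f in first:
        j = idx[f]
        tab = np.zeros((3, nc))
        np.add.at(tab, (bins[:, j], class_codes), 1.0)
        tab += pseudocount
        cpts[f] = tab / tab.sum(axis=0, keepdims=True)
        bnds[f] = (float(boundaries[j, 0]), float(boundaries[j, 1]))
    return ClassifierParams(
        class_labels=list(class_labels),
        class_prior=counts_c / counts_c.sum(),
        cpts=cpts,
        boundaries=bnds,
        decision_threshold=decision_threshold,
    )


def posterior(params: ClassifierParams, case_bins: dict) -> np.ndarray:
    """Class posterior for one case given its bin values (feature id -> bin).

    Accumulated in log space, so thousands of features cannot underflow.
    """
    logp = np.log(params.class_prior.astype(float))
    for f in params.features:
        b = int(case_bins[f])
        if b not in (0, 1, 2):
            raise ValueError(f"bin value {b} for feature {f} outside {{0,1,2}}")
        logp = logp + np.log(params.cpts[f][b])
    return np.exp(logp - logsumexp(logp))


def _posterior_matrix(params: ClassifierParams, table) -> np.ndarray:
    """Posterior per case for a SampleTable, using the frozen boundaries."""
    fid = list(table.feature_ids)
    idx = {f: i for i, f in enumerate(fid)}
    missing = [f for f in params.features if f not in idx]
    if missing:
        raise ValueError(f"table is missing classifier features: {missing}")
    logp = np.tile(np.log(params.class_prior), (table.n_cases, 1))
    for f in params.features:
        b_low, b_high = params.boundaries[f]
        b = apply_boundaries(table.abundances[:, idx[f]], b_low, b_high)
        logp += np.log(params.cpts[f])[b]
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def classify(params: ClassifierParams, table, roc: bool = True) -> dict:
    """Apply a frozen classifier to a peak table.

    Returns a dict with per-case ``posterior`` rows, deterministic ``calls``
    (binary problems: positive iff P(positive) strictly exceeds the decision
    threshold; a posterior exactly at the threshold is a negative call), and
    — when the table carries labels matching the classifier's — the
    misclassification ``error_rate`` and ROC points.
    """
    post = _posterior_matrix(params, table)
    labels = params.class_labels
    if len(labels) == 2:
        pos = labels.index(params.positive_class)
        neg = 1 - pos
        calls = np.where(post[:, pos] > params.decision_threshold, labels[pos], labels[neg])
    else:
        calls = np.asarray(labels, dtype=object)[np.argmax(post, axis=1)]
    out = {"posterior": post, "calls": calls, "classes": list(labels)}
    if table.class_labels is None:
        return out
    truth = np.asarray(table.class_labels).astype(str)
    if set(np.unique(truth)) <= {str(c) for c in labels}:
        out["error_rate"] = float(np.mean(truth != calls.astype(str)))
        if roc and len(labels) == 2:
            y_bin = (truth == str(params.positive_class)).astype(int)
            fpr, tpr, thresholds = roc_curve(y_bin, post[:, labels.index(params.positive_class)])
            out["roc"] = {"fpr": fpr, "tpr": tpr, "thresholds": thresholds}
    return out


class BayesNetClassifier(ClassifierMixin, BaseEstimator):
    """Feature-screening Bayesian-network classifier for peak tables.

    ``fit`` runs the whole structure-learning pipeline: max-MI three-bin
    discretization, permutation-baseline significance threshold, first-level
    selection, feature-feature linking, conditional-MI orientation/demotion,
    and CPT estimation for the surviving Markov blanket.

    Parameters
    ----------
    n_permutations : int, default 100
        Label permutations for the significance baseline (ignored when
        ``threshold`` is given).
    threshold_multiplier : float, default 3.2
        Multiplier applied to the permutation baseline MI.
    drop_threshold : float, default 0.75
        Minimum fractional conditional-MI drop that demotes a first-level
        feature to a child (serial chain).
    pseudocount : float, default 1.0
        Laplace smoothing added to every CPT cell.
    decision_threshold : float, default 0.5
        Posterior cut for deterministic binary calls (strictly greater ->
        positive class).
    threshold : ThresholdSpec or None
        Precomputed significance threshold; supply it to reuse one baseline
        across many fits (as repeated cross-validation does).
    feature_ids : sequence or None
        Node labels for the network (e.g. m/z values); defaults to column
        indices.
    random_state : int or None
        Seed for the permutation baseline.
    """

    def __init__(
        self,
        n_permutations: int = 100,
        threshold_multiplier: float = 3.2,
        drop_threshold: float = 0.75,
        pseudocount: float = 1.0,
        decision_threshold: float = 0.5,
        exhaustive_cap: int = 64,
        n_quantiles: int = 64,
        threshold: ThresholdSpec | None = None,
        feature_ids=None,
        random_state: int | None = None,
    ):
        self.n_permutations = n_permutations
        self.threshold_multiplier = threshold_multiplier
        self.drop_threshold = drop_threshold
        self.pseudocount = pseudocount
        self.decision_threshold = decision_threshold
        self.exhaustive_cap = exhaustive_cap
        self.n_quantiles = n_quantiles
        self.threshold = threshold
        self.feature_ids = feature_ids
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        fids = (
            list(self.feature_ids)
            if self.feature_ids is not None
            else list(range(X.shape[1]))
        )
        if len(fids) != X.shape[1]:
            raise ValueError("feature_ids length does not match X")

        self.discretizer_ = MaxMIDiscretizer(
            self.exhaustive_cap, self.n_quantiles
        ).fit(X, y_codes)
        bins = self.discretizer_.transform(X)

        self.threshold_ = self.threshold or permutation_baseline(
            X,
            class_labels=y_codes,
            n_perm=self.n_permutations,
            multiplier=self.threshold_multiplier,
            seed=self.random_state,
            exhaustive_cap=self.exhaustive_cap,
            n_quantiles=self.n_quantiles,
        )

        per_mi = dict(zip(fids, self.discretizer_.mi_.tolist()))
        first = select_first_level(per_mi, self.threshold_)
        if not first:
            raise ValueError(
                "no feature exceeded the significance threshold "
                f"({self.threshold_.effective_threshold:.4f} bits)"
            )
        links = link_features(bins, fids, first, self.threshold_, n_classes=self.classes_.size)
        self.network_, self.decisions_ = orient_and_prune(
            bins, fids, y_codes, per_mi, first, links, self.drop_threshold
        )
        self.params_ = fit_parameters(
            self.network_,
            bins,
            fids,
            y_codes,
            list(self.classes_),
            self.discretizer_.boundaries_,
            pseudocount=self.pseudocount,
            decision_threshold=self.decision_threshold,
        )
        self._feature_index = {f: i for i, f in enumerate(fids)}
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        p = self.params_
        logp = np.tile(np.log(p.class_prior), (X.shape[0], 1))
        for f in p.features:
            j = self._feature_index[f]
            b = apply_boundaries(X[:, j], *p.boundaries[f])
            logp += np.log(p.cpts[f])[b]
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        if self.classes_.size == 2:
            pos = list(self.classes_).index(self.params_.positive_class)
            return np.where(
                proba[:, pos] > self.decision_threshold,
                self.classes_[pos],
                self.classes_[1 - pos],
            )
        return self.classes_[np.argmax(proba, axis=1)]
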