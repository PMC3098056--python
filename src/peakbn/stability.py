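"""Repeated stratified k-fold cross-validation with arc-frequency tallies.

Feature-selection stability is the point: the whole structure-learning
pipeline is re-run inside every training fold of every repeat, so the n*k
recorded networks show which arcs survive resampling.  The per-repeat
misclassification rates double as the cross-validated error prediction that
a later lockbox evaluation is judged against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold

from .classifier import BayesNetClassifier
from .data import SampleTable
from .info import ThresholdSpec, permutation_baseline
from .network import CLASS_NODE

logger = logging.getLogger(__name__)

__all__ = ["CVPlan", "StabilityReport", "run_cv", "error_summary", "plot_arc_frequencies"]


@dataclass
class CVPlan:
    """Resampling design: k folds, repeated n times with reshuffled groups."""

    k: int = 10
    n_repeats: int = 100
    stratified: bool = True
    seed: int = 0
    use_groups: bool = False


@dataclass
class StabilityReport:
    """Arc tallies and error rates across all n*k recorded networks."""

    arc_counts: dict
    repeat_error_rates: list
    n_networks: int
    settings: dict = field(default_factory=dict)
    boundaries_log: list | None = None
    fold_classifiers: list | None = None

    def arc_frequency(self, source, target) -> float:
        return self.arc_counts.get((source, target), 0) / self.n_networks

    def class_arc_frequency(self, feature) -> float:
        return self.arc_frequency(CLASS_NODE, feature)

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "settings": self.settings,
            "n_networks": self.n_networks,
            "repeat_error_rates": list(self.repeat_error_rates),
            "arc_counts": [
                {"source": _jsonable(u), "target": _jsonable(v), "count": c}
                for (u, v), c in sorted(
                    self.arc_counts.items(), key=lambda kv: (-kv[1], str(kv[0]))
                )
            ],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StabilityReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        counts = {
            (row["source"], row["target"]): row["count"] for row in obj["arc_counts"]
        }
        return cls(
            arc_counts=counts,
            repeat_error_rates=obj["repeat_error_rates"],
            n_networks=obj["n_networks"],
            settings=obj.get("settings", {}),
        )


def _jsonable(x):
    return x.item() if isinstance(x, np.generic) else x


def run_cv(
    table: SampleTable,
    plan: CVPlan | None = None,
    n_perm: int = 100,
    multiplier: float = 3.2,
    drop_threshold: float = 0.75,
    pseudocount: float = 1.0,
    decision_threshold: float = 0.5,
    exhaustive_cap: int = 64,
    n_quantiles: int = 64,
    threshold: ThresholdSpec | None = None,
    recompute_baseline_per_fold: bool = False,
    keep_boundaries: bool = False,
    keep_classifiers: bool = False,
) -> StabilityReport:
    """Repeated stratified k-fold CV of the full pipeline.

    The permutation significance baseline is computed once from the whole
    training table before the folds are drawn (set
    ``recompute_baseline_per_fold`` to redo it inside every training fold).
    Discretization boundaries, network structure, and CPTs are always
    re-learned from the training fold alone; the held-out fold is binned
    with the training boundaries and classified.  Per repeat, every case is
    tested exactly once and one error rate is recorded; arcs are tallied
    over all n*k networks.  Fully deterministic given ``plan.seed``.
    """
    plan = plan or CVPlan()
    if table.class_labels is None:
        raise ValueError("cross-validation needs class labels")
    y = table.class_codes
    class_counts = np.bincount(y)
    if plan.stratified and plan.k > class_counts.min():
        raise ValueError(
            f"k={plan.k} exceeds the smallest class count ({class_counts.min()})"
        )
    if plan.k > table.n_cases:
        raise ValueError(f"k={plan.k} exceeds the number of cases")
    root = np.random.SeedSequence(plan.seed)
    # one 31-bit substream per repeat (+1 for the baseline) so any single
    # repeat can be reproduced in isolation
    states = root.generate_state(plan.n_repeats + 1 + plan.n_repeats * plan.k) % (2**31)
    base_seed = int(states[0])
    repeat_states = states[1 : plan.n_repeats + 1]
    fold_states = states[plan.n_repeats + 1 :]

    if threshold is None and not recompute_baseline_per_fold:
        threshold = permutation_baseline(
            table.abundances,
            class_labels=y,
            n_perm=n_perm,
            multiplier=multiplier,
            seed=base_seed,
            exhaustive_cap=exhaustive_cap,
            n_quantiles=n_quantiles,
        )

    fids = list(table.feature_ids)
    arc_counts: dict = {}
    repeat_errors: list[float] = []
    boundaries_log: list = [] if keep_boundaries else None
    fold_classifiers: list = [] if keep_classifiers else None

    for r in range(plan.n_repeats):
        rs = int(repeat_states[r])
        if plan.use_groups and table.groups is not None:
            splitter = StratifiedGroupKFold(plan.k, shuffle=True, random_state=rs)
            splits = splitter.split(table.abundances, y, groups=table.groups)
        elif plan.stratified:
            splitter = StratifiedKFold(plan.k, shuffle=True, random_state=rs)
            splits = splitter.split(table.abundances, y)
        else:
            splitter = KFold(plan.k, shuffle=True, random_state=rs)
            splits = splitter.split(table.abundances)
        n_wrong = 0
        for fold_i, (train, test) in enumerate(splits):
            clf = BayesNetClassifier(
                n_permutations=n_perm,
                threshold_multiplier=multiplier,
                drop_threshold=drop_threshold,
                pseudocount=pseudocount,
                decision_threshold=decision_threshold,
                exhaustive_cap=exhaustive_cap,
                n_quantiles=n_quantiles,
                threshold=threshold,
                feature_ids=fids,
                random_state=int(fold_states[r * plan.k + fold_i]),
            )
            try:
                clf.fit(table.abundances[train], table.class_labels[train])
            except ValueError as exc:
                if "significance threshold" not in str(exc):
                    raise
                # nothing screened in this fold: empty network, majority call
                logger.warning("repeat %d fold %d: %s; majority-class fallback",
                               r, fold_i, exc)
                maj = table.classes[np.argmax(np.bincount(y[train]))]
                n_wrong += int(np.sum(table.class_labels[test] != maj))
                continue
            pred = clf.predict(table.abundances[test])
            n_wrong += int(np.sum(pred != table.class_labels[test]))
            for u, v, _level in clf.network_.arcs():
                arc_counts[(u, v)] = arc_counts.get((u, v), 0) + 1
            if keep_boundaries:
                boundaries_log.append(
                    (r, fold_i, np.sort(train), clf.discretizer_.boundaries_.copy())
                )
            if keep_classifiers:
                fold_classifiers.append((r, fold_i, clf.params_))
        repeat_errors.append(n_wrong / table.n_cases)

    settings = {
        "k": plan.k,
        "n_repeats": plan.n_repeats,
        "stratified": plan.stratified,
        "use_groups": plan.use_groups,
        "seed": plan.seed,
        "n_perm": n_perm,
        "multiplier": multiplier,
        "drop_threshold": drop_threshold,
        "pseudocount": pseudocount,
        "decision_threshold": decision_threshold,
        "exhaustive_cap": exhaustive_cap,
        "n_quantiles": n_quantiles,
        "recompute_baseline_per_fold": recompute_baseline_per_fold,
        "baseline_mi": None if threshold is None else threshold.baseline_mi,
        "effective_threshold": None if threshold is None else threshold.effective_threshold,
    }
    return StabilityReport(
        arc_counts=arc_counts,
        repeat_error_rates=repeat_errors,
        n_networks=plan.n_repeats * plan.k,
        settings=settings,
        boundaries_log=boundaries_log,
        fold_classifiers=fold_classifiers,
    )


def error_summary(report: StabilityReport) -> tuple[float, float]:
    """Mean and sample SD of the per-repeat cross-validated error rates."""
    rates = np.asarray(report.repeat_error_rates, dtype=float)
    if rates.size == 0:
        raise ValueError("report holds no error rates")
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return float(rates.mean()), sd


def plot_arc_frequencies(report: StabilityReport, path=None, top: int = 20):
    """Bar chart of class-arc selection frequencies (most frequent first)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = [
        (v, c / report.n_networks)
        for (u, v), c in report.arc_counts.items()
        if u == CLASS_NODE
    ]
    pairs.sort(key=lambda t: -t[1])
    pairs = pairs[:top]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(pairs)), [f for _, f in pairs])
    ax.set_xticks(range(len(pairs)))
    ax.set_xticklabels([str(v) for v, _ in pairs], rotation=90, fontsize=7)
    ax.axhline(0.5, color="red", ls="--", lw=1)
    ax.set_ylabel("class-arc frequency")
    ax.set_xlabel("feature (m/z)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
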