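"""Class-rooted Bayesian-network structure over screened peak features.

The structure is learned in the two-level scheme the package is built
around: the class node is fixed as the sole root; features whose (binned)
MI with the class beats the permutation-derived threshold become
"first-level" candidates; remaining dependencies between features are found
by MI on the already-binned values, and arcs among first-level features are
oriented or demoted by the conditional-MI drop test (a serial chain
C -> V1 -> V2 reveals itself because MI(C;V2|V1) collapses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .info import (
    ThresholdSpec,
    conditional_mutual_information,
    mutual_information,
)

__all__ = [
    "CLASS_NODE",
    "BayesNet",
    "ArcDecision",
    "select_first_level",
    "link_features",
    "orient_and_prune",
    "build_consensus",
    "export_network",
    "import_edge_csv",
]

logger = logging.getLogger(__name__)

#: reserved node id for the disease-class root
CLASS_NODE = "class"

FIRST_LEVEL = "first-level"
CHILD = "child"


@dataclass(frozen=True)
class ArcDecision:
    """Audit record of one structure decision (kept for every tested pair)."""

    source: object
    target: object
    #: class-link | serial-chain-demotion | cmi-direction | skipped-demoted |
    #: skipped-cycle | child-attachment
    rule: str
    mi_before: float
    mi_after: float

    @property
    def drop_fraction(self) -> float | None:
        if self.rule != "serial-chain-demotion":
            return None
        return 1.0 - self.mi_after / self.mi_before

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drop_fraction"] = self.drop_fraction
        return d


class BayesNet:
    """DAG over {class node} + feature nodes with level-tagged arcs.

    Thin wrapper around a :class:`networkx.DiGraph`; arcs carry a ``level``
    tag ("first-level" for class->feature, "child" for feature->feature) and
    optionally a ``frequency`` (for consensus networks).
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self.graph.add_node(CLASS_NODE)

    def add_arc(self, source, target, level: str, frequency: float | None = None) -> None:
        if target == CLASS_NODE:
            raise ValueError("the class node cannot have parents")
        if source != CLASS_NODE and level != CHILD:
            raise ValueError("feature->feature arcs must be level 'child'")
        attrs = {"level": level}
        if frequency is not None:
            attrs["frequency"] = float(frequency)
        self.graph.add_edge(source, target, **attrs)
        if not nx.is_directed_acyclic_graph(self.graph):
            self.graph.remove_edge(source, target)
            raise ValueError(f"arc {source}->{target} would create a cycle")

    def remove_arc(self, source, target) -> None:
        self.graph.remove_edge(source, target)

    def would_cycle(self, source, target) -> bool:
        if source == CLASS_NODE:
            return False
        if source not in self.graph or target not in self.graph:
            return False
        return nx.has_path(self.graph, target, source)

    @property
    def first_level(self) -> list:
        return sorted(
            (t for _, t, d in self.graph.out_edges(CLASS_NODE, data=True)
             if d["level"] == FIRST_LEVEL),
        )

    @property
    def feature_nodes(self) -> list:
        return sorted(n for n in self.graph.nodes if n != CLASS_NODE)

    def arcs(self) -> list[tuple]:
        """All arcs as (source, target, level) triples."""
        return [(u, v, d["level"]) for u, v, d in self.graph.edges(data=True)]

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("network contains a cycle")
        if self.graph.in_degree(CLASS_NODE) != 0:
            raise ValueError("class node has parents")
        for n in self.feature_nodes:
            if self.graph.degree(n) == 0:
                raise ValueError(f"isolated feature node {n}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, BayesNet):
            return NotImplemented
        return set(self.arcs()) == set(other.arcs())

    def __repr__(self) -> str:
        return (
            f"BayesNet({len(self.first_level)} first-level, "
            f"{self.graph.number_of_edges()} arcs)"
        )


def select_first_level(per_feature_mi: Mapping, thr: ThresholdSpec) -> list:
    """Features whose MI(class; binned feature) strictly exceeds the threshold.

    ``per_feature_mi`` maps feature id -> MI in bits.  A feature exactly at
    the threshold is excluded.  An empty result is allowed (logged).
    """
    cut = thr.effective_threshold
    selected = [f for f, mi in per_feature_mi.items() if mi > cut]
    if not selected:
        logger.warning(
            "no feature exceeded the MI threshold %.4f bits (max observed %.4f)",
            cut, max(per_feature_mi.values(), default=0.0),
        )
    return selected


def _alphabet(col: np.ndarray) -> int:
    return int(np.unique(col).size)


def link_features(
    bins: np.ndarray,
    feature_ids: Sequence,
    first_level: Iterable,
    thr: ThresholdSpec,
    n_classes: int = 2,
) -> list[tuple]:
    """Scan (first-level, other) pairs for dependencies on the binned values.

    MI between the already-discretized columns is compared against the class
    threshold after adjusting both sides for the scale of their maximum
    attainable MI: the pair's MI is divided by log2 of the smaller alphabet
    of the two columns, the threshold by log2(#classes).  Returns tuples
    ``(first_level_feature, other_feature, mi)`` for every passing pair
    (each unordered pair reported once).
    """
    fid = list(feature_ids)
    idx = {f: i for i, f in enumerate(fid)}
    first = [f for f in fid if f in set(first_level)]  # keep column order
    first_set = set(first)
    thr_scaled = thr.effective_threshold / np.log2(n_classes) if n_classes > 1 else np.inf
    alph = {f: _alphabet(bins[:, idx[f]]) for f in fid}
    links: list[tuple] = []
    seen: set[frozenset] = set()
    for f in first:
        for g in fid:
            if g == f or frozenset((f, g)) in seen:
                continue
            if g in first_set:
                seen.add(frozenset((f, g)))
            k = min(alph[f], alph[g])
            if k < 2:
                continue  # constant column: no dependency measurable
            mi = mutual_information(bins[:, idx[f]], bins[:, idx[g]])
            if mi / np.log2(k) > thr_scaled:
                links.append((f, g, mi))
    return links


def orient_and_prune(
    bins: np.ndarray,
    feature_ids: Sequence,
    class_codes: np.ndarray,
    per_feature_mi: Mapping,
    first_level: Sequence,
    links: Sequence[tuple],
    drop_threshold: float = 0.75,
) -> tuple[BayesNet, list[ArcDecision]]:
    """Resolve candidate arcs into a class-rooted DAG.

    For each linked pair of first-level features (V1, V2), ordered so V1 has
    the larger MI with the class, both conditional values are computed.  A
    fractional drop 1 - CMI(C;V2|V1)/MI(C;V2) strictly greater than
    ``drop_threshold`` demotes V2 to a child of V1 (the class arc to V2 is
    removed); if both directions drop, the larger drop decides.  If neither
    drops, both stay first-level and the arc runs from the feature whose
    conditional MI with the class is greater.  Pairs are processed in
    descending order of the stronger member's class MI; an orientation that
    would close a cycle is skipped and logged.  Non-first-level linked
    features are attached as children of their single strongest linked
    parent (by pair MI).
    """
    if not 0.0 < drop_threshold < 1.0:
        raise ValueError(f"drop_threshold must be in (0,1), got {drop_threshold}")
    idx = {f: i for i, f in enumerate(feature_ids)}
    col = lambda f: bins[:, idx[f]]

    net = BayesNet()
    decisions: list[ArcDecision] = []
    current_first = set(first_level)
    for f in first_level:
        net.add_arc(CLASS_NODE, f, FIRST_LEVEL)
        decisions.append(ArcDecision(CLASS_NODE, f, "class-link", per_feature_mi[f], per_feature_mi[f]))

    ff_pairs = [(f, g, mi) for f, g, mi in links if g in current_first]
    child_links = [(f, g, mi) for f, g, mi in links if g not in current_first]

    def pair_key(t):
        f, g, _ = t
        hi = max(per_feature_mi[f], per_feature_mi[g])
        lo = min(per_feature_mi[f], per_feature_mi[g])
        return (-hi, -lo, str(f), str(g))

    for f, g, pair_mi in sorted(ff_pairs, key=pair_key):
        if f not in current_first or g not in current_first:
            src = f if f not in current_first else g
            decisions.append(ArcDecision(src, g if src == f else f, "skipped-demoted", pair_mi, pair_mi))
            continue
        # V1 = stronger class association
        v1, v2 = (f, g) if per_feature_mi[f] >= per_feature_mi[g] else (g, f)
        cmi_2_given_1 = conditional_mutual_information(class_codes, col(v2), col(v1))
        cmi_1_given_2 = conditional_mutual_information(class_codes, col(v1), col(v2))
        mi1, mi2 = per_feature_mi[v1], per_feature_mi[v2]
        drop2 = 1.0 - cmi_2_given_1 / mi2 if mi2 > 0 else 0.0
        drop1 = 1.0 - cmi_1_given_2 / mi1 if mi1 > 0 else 0.0
        demote2 = drop2 > drop_threshold
        demote1 = drop1 > drop_threshold
        if demote1 and demote2:
            # both conditionally near-independent of the class: demote the
            # weaker (larger-drop) one, keep the stronger as its parent
            if drop2 >= drop1:
                demote1 = False
            else:
                demote2 = False
        if demote2 or demote1:
            parent, child_ = (v1, v2) if demote2 else (v2, v1)
            if net.would_cycle(parent, child_):
                decisions.append(ArcDecision(parent, child_, "skipped-cycle", pair_mi, pair_mi))
                continue
            net.remove_arc(CLASS_NODE, child_)
            net.add_arc(parent, child_, CHILD)
            current_first.discard(child_)
            decisions.append(
                ArcDecision(
                    parent, child_, "serial-chain-demotion",
                    mi_before=per_feature_mi[child_],
                    mi_after=cmi_2_given_1 if demote2 else cmi_1_given_2,
                )
            )
        else:
            src, tgt = (v1, v2) if cmi_1_given_2 >= cmi_2_given_1 else (v2, v1)
            if net.would_cycle(src, tgt):
                decisions.append(ArcDecision(src, tgt, "skipped-cycle", pair_mi, pair_mi))
                continue
            net.add_arc(src, tgt, CHILD)
            decisions.append(
                ArcDecision(src, tgt, "cmi-direction",
                            mi_before=max(cmi_1_given_2, cmi_2_given_1),
                            mi_after=min(cmi_1_given_2, cmi_2_given_1))
            )

    # children: single strongest linked parent (by pair MI, ties by id)
    by_child: dict = {}
    for f, g, mi in child_links:
        best = by_child.get(g)
        if best is None or (mi, str(f)) > (best[1], str(best[0])):
            by_child[g] = (f, mi)
    for g, (f, mi) in sorted(by_child.items(), key=lambda kv: str(kv[0])):
        net.add_arc(f, g, CHILD)
        decisions.append(ArcDecision(f, g, "child-attachment", mi, mi))

    net.validate()
    return net, decisions


def build_consensus(report, freq_threshold: float = 0.5) -> BayesNet:
    """Majority ("average") network over all recorded per-fold networks.

    An undirected connection is kept when its total occurrence count (both
    directions pooled) is strictly greater than ``freq_threshold`` of the
    n*k networks; the surviving arc takes the majority direction.  Arcs are
    added in descending frequency order and any arc that would close a cycle
    is skipped (logged).
    """
    if report.n_networks < 1 or not report.arc_counts:
        raise ValueError("empty stability report")
    total = report.n_networks
    pooled: dict[frozenset, dict] = {}
    for (u, v), cnt in report.arc_counts.items():
        key = frozenset((u, v))
        pooled.setdefault(key, {})[(u, v)] = cnt
    net = BayesNet()
    kept = []
    for key, directions in pooled.items():
        count = sum(directions.values())
        if count / total > freq_threshold:
            (u, v), c = max(directions.items(), key=lambda kv: (kv[1], str(kv[0])))
            if len(directions) > 1:
                logger.info(
                    "conflicting directions for %s: kept %s->%s (%d of %d)",
                    set(key), u, v, c, count,
                )
            kept.append((u, v, count / total))
    kept.sort(key=lambda t: (-t[2], str(t[0]), str(t[1])))
    for u, v, freq in kept:
        level = FIRST_LEVEL if u == CLASS_NODE else CHILD
        if net.would_cycle(u, v):
            logger.warning("consensus arc %s->%s skipped (cycle)", u, v)
            continue
        net.add_arc(u, v, level, frequency=freq)
    # drop feature nodes that ended isolated (e.g. all their arcs skipped)
    for n in list(net.feature_nodes):
        if net.graph.degree(n) == 0:
            net.graph.remove_node(n)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# serialization

def export_network(net: BayesNet, path: str | Path, format: str = "edge-csv") -> None:
    """Write a network as DOT, GraphML, or a 3/4-column edge CSV.

    The edge CSV has columns ``source,target,level[,frequency]`` and its
    re-import reproduces the arc set exactly.
    """
    net.validate()
    if not net.feature_nodes:
        raise ValueError("refusing to export a network with no feature nodes")
    path = Path(path)
    if format == "edge-csv":
        has_freq = any("frequency" in d for _, _, d in net.graph.edges(data=True))
        with open(path, "w") as fh:
            fh.write("source,target,level" + (",frequency" if has_freq else "") + "\n")
            for u, v, d in sorted(net.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
                row = f"{_node_str(u)},{_node_str(v)},{d['level']}"
                if has_freq:
                    row += f",{d.get('frequency', '')}"
                fh.write(row + "\n")
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("digraph bn {\n  rankdir=TB;\n")
            fh.write(f'  "{CLASS_NODE}" [shape=box];\n')
            for u, v, d in sorted(net.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
                attrs = [f'label="{d["level"]}"']
                if "frequency" in d:
                    attrs.append(f'tooltip="{d["frequency"]:.3f}"')
                fh.write(f'  "{_node_str(u)}" -> "{_node_str(v)}" [{", ".join(attrs)}];\n')
            fh.write("}\n")
    elif format == "graphml":
        g = nx.relabel_nodes(net.graph, {n: _node_str(n) for n in net.graph.nodes})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected dot, graphml, edge-csv)")


def import_edge_csv(path: str | Path) -> BayesNet:
    """Re-read an edge CSV written by :func:`export_network`."""
    net = BayesNet()
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        has_freq = "frequency" in header
        for line in fh:
            parts = line.strip().split(",")
            if len(parts) < 3:
                continue
            u, v, level = _node_parse(parts[0]), _node_parse(parts[1]), parts[2]
            freq = float(parts[3]) if has_freq and len(parts) > 3 and parts[3] else None
            net.add_arc(u, v, level, frequency=freq)
    net.validate()
    return net


def _node_str(n) -> str:
    # repr is the shortest exactly round-tripping decimal form
    if isinstance(n, (float, np.floating)):
        s = repr(float(n))
        return s[:-2] if s.endswith(".0") else s
    return str(n)


def _node_parse(s: str):
    if s == CLASS_NODE:
        return s
    try:
        return float(s)
    except ValueError:
        return s
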