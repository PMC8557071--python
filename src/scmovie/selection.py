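"""Constraint-based subpopulation selection on lineage/division forests.

A selection keeps the nodes that satisfy *all* given constraints (logical
AND); unions of selections (logical OR) are formed with
:func:`unite_trees`.  The result keeps the synthetic roots and may be a
disconnected graph, but remains a valid input to every analytics function
and to further selections — allowing ad-hoc drill-down into colonies,
generations, outlier cells, etc.
"""

from __future__ import annotations

import math
import operator
import statistics
from dataclasses import dataclass

from .lineage_forest import DivisionForest, LineageForest, is_synthetic

_OPS = {
    "<": operator.lt,
    "<=": operator.le,
    "=": operator.eq,
    "==": operator.eq,
    ">=": operator.ge,
    ">": operator.gt,
    "!=": operator.ne,
}
_ORDERING = ("<", "<=", ">=", ">")


@dataclass(frozen=True)
class Constraint:
    """One atomic condition: attribute, comparison operator, threshold.

    ``attr`` may be any node attribute (instance attributes on the FLT,
    life attributes on the FDT; ``colony`` and ``generation`` are
    selectable on both).  ``atol`` turns ``=`` into a tolerant comparison
    for float-valued measured attributes.
    """

    attr: str
    op: str
    value: object
    atol: float = 0.0

    def __post_init__(self):
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}; use one of {sorted(_OPS)}")

    def check(self, node_value) -> bool:
        if self.op in _ORDERING and not isinstance(node_value, (int, float)):
            raise TypeError(
                f"ordering operator {self.op!r} on non-numeric attribute "
                f"{self.attr!r} (value {node_value!r})"
            )
        if self.op in ("=", "==") and self.atol > 0:
            return math.isclose(node_value, self.value, abs_tol=self.atol)
        return _OPS[self.op](node_value, self.value)


def _subset_forest(forest, keep: set):
    """New forest of the same class containing `keep` + synthetic roots."""
    nodes = {n for n in forest.graph.nodes if is_synthetic(n)} | keep
    graph = forest.graph.subgraph(nodes).copy()
    if isinstance(forest, LineageForest):
        out = LineageForest(
            graph=graph,
            frame_period=forest.frame_period,
            n_frames=forest.n_frames,
            motherless_store=list(forest.motherless_store),
            parent=forest,
        )
    else:
        out = DivisionForest(
            graph=graph,
            frame_period=forest.frame_period,
            filters_applied=dict(getattr(forest, "filters_applied", {})),
            parent=forest,
        )
    return out


def _available_attrs(forest) -> set:
    attrs: set = set()
    for n, data in forest.graph.nodes(data=True):
        if not is_synthetic(n):
            attrs |= data.keys()
    return attrs


def select_subtree(forest, constraints) -> "LineageForest | DivisionForest":
    """Select the nodes satisfying all constraints (AND composition).

    Equivalent to sequential selections: selecting with ``[c1, c2]``
    yields the same node set as selecting with ``[c1]`` then ``[c2]``.
    The parent forest is never mutated.
    """
    constraints = list(constraints)
    available = _available_attrs(forest)
    for c in constraints:
        if c.attr not in available:
            raise KeyError(
                f"unknown attribute {c.attr!r}; available: {sorted(available)}"
            )
    keep = set()
    for n, data in forest.graph.nodes(data=True):
        if is_synthetic(n):
            continue
        try:
            ok = all(c.attr in data and c.check(data[c.attr]) for c in constraints)
        except TypeError:
            raise
        if ok:
            keep.add(n)
    return _subset_forest(forest, keep)


def _root_forest(forest):
    while forest.parent is not None:
        forest = forest.parent
    return forest


def unite_trees(forests) -> "LineageForest | DivisionForest":
    """Union of selections derived from the same parent forest (OR).

    Node sets are united; edges are restored from the common ancestor
    forest wherever both endpoints are present.
    """
    forests = list(forests)
    if not forests:
        raise ValueError("need at least one forest")
    roots = {id(_root_forest(f)) for f in forests}
    if len(roots) != 1:
        raise ValueError("forests derive from different parent forests")
    parent = _root_forest(forests[0])
    keep: set = set()
    for f in forests:
        keep |= {n for n in f.graph.nodes if not is_synthetic(n)}
    return _subset_forest(parent, keep)


def flag_outliers_mean_sd(forest, attr: str, k: float = 1.0):
    """Mean-and-standard-deviation outlier selection.

    Selects the nodes whose ``attr`` lies below mean - k*sd or above
    mean + k*sd, with mean and sample sd computed over the queried
    forest's own (non-synthetic) nodes.
    """
    values = [
        data[attr]
        for n, data in forest.graph.nodes(data=True)
        if not is_synthetic(n) and attr in data
    ]
    if len(values) < 2:
        raise ValueError(f"need >= 2 values of {attr!r} to compute mean/sd, got {len(values)}")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values)
    lo, hi = mean - k * sd, mean + k * sd
    keep = {
        n
        for n, data in forest.graph.nodes(data=True)
        if not is_synthetic(n) and attr in data and (data[attr] < lo or data[attr] > hi)
    }
    return _subset_forest(forest, keep)
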