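"""Kin-pair enumeration and correlation of life attributes.

Cells related through recent common ancestors — siblings (same mother),
cousins (same grandmother, different mothers), mother–daughter and
grandmother–granddaughter — carry correlated growth parameters when
division characteristics are inherited.  This module enumerates the pairs
on a division forest and computes, per generation, the Pearson
correlation and least-squares regression of any life attribute between
pair members.

Same-generation relations (sibling, cousin) are unordered; statistics are
computed on the symmetrized pair set (each pair contributing both
orderings) so r and the slope do not depend on an arbitrary orientation.
Cross-generation relations are ordered ancestor -> descendant and the
regression is descendant on ancestor.  The generation index of a pair is
the descendant's generation; sibling pairs exist from generation 1,
cousin pairs from generation 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .lineage_forest import DivisionForest

RELATIONS = ("sibling", "cousin", "mother_daughter", "grandmother_granddaughter")

_SYMMETRIC = ("sibling", "cousin")


@dataclass(frozen=True)
class RelativePair:
    relation: str
    cell_a: str
    cell_b: str
    generation: int


def enumerate_pairs(fdt: DivisionForest, relation: str) -> list[RelativePair]:
    """Exhaustive, duplicate-free enumeration of kin pairs on the FDT.

    Unordered same-generation pairs are emitted once (members in sorted
    id order); cross-generation pairs are ordered ancestor first.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; choose from {RELATIONS}")
    pairs: list[RelativePair] = []
    for cell in sorted(fdt.cell_nodes()):
        gen = fdt.graph.nodes[cell]["generation"]
        daughters = fdt.daughters(cell)
        if relation == "sibling":
            for a, b in combinations(sorted(daughters), 2):
                pairs.append(RelativePair(relation, a, b, gen + 1))
        elif relation == "cousin":
            # grandchildren through different daughters
            for da, db in combinations(sorted(daughters), 2):
                for a in fdt.daughters(da):
                    for b in fdt.daughters(db):
                        x, y = sorted((a, b))
                        pairs.append(RelativePair(relation, x, y, gen + 2))
        elif relation == "mother_daughter":
            for d in daughters:
                pairs.append(RelativePair(relation, cell, d, gen + 1))
        else:  # grandmother_granddaughter
            for d in daughters:
                for gd in fdt.daughters(d):
                    pairs.append(RelativePair(relation, cell, gd, gen + 2))
    return pairs


def pair_stats(
    fdt: DivisionForest,
    pairs: list[RelativePair],
    attr: str,
    per_generation: bool = True,
) -> dict:
    """Pearson r and regression of a life attribute between pair members.

    Returns per group (generation index, or "all") a dict with ``r``,
    ``slope``, ``intercept``, ``r_squared`` and ``n_pairs``.  Groups with
    fewer than 3 pairs report NaN statistics and their count.
    """
    if not pairs:
        raise ValueError("no pairs to analyze")

    def value(cell):
        v = fdt.graph.nodes[cell].get(attr)
        if v is None or not np.isfinite(v):
            raise KeyError(f"attribute {attr!r} missing or non-finite on cell {cell!r}")
        return float(v)

    groups: dict[object, list[RelativePair]] = {}
    for p in pairs:
        key = p.generation if per_generation else "all"
        groups.setdefault(key, []).append(p)

    out: dict[object, dict] = {}
    for key in sorted(groups, key=str):
        members = groups[key]
        xs, ys = [], []
        for p in members:
            a, b = value(p.cell_a), value(p.cell_b)
            xs.append(a)
            ys.append(b)
            if p.relation in _SYMMETRIC:
                xs.append(b)
                ys.append(a)
        x = np.array(xs)
        y = np.array(ys)
        if len(members) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[key] = {
                "r": math.nan,
                "slope": math.nan,
                "intercept": math.nan,
                "r_squared": math.nan,
                "n_pairs": len(members),
            }
            continue
        reg = stats.linregress(x, y)
        r = float(stats.pearsonr(x, y).statistic)
        out[key] = {
            "r": r,
            "slope": float(reg.slope),
            "intercept": float(reg.intercept),
            "r_squared": r * r,
            "n_pairs": len(members),
        }
    return out
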