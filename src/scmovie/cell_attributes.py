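"""Derived instance attributes and per-lifespan life attributes.

Instance-level: cell age (minutes since birth) and the instantaneous rate
of change (roc) of any numeric attribute, optionally normalized to percent
change per frame — the workhorse of frame-to-frame QC.

Life-level: each FDT node is annotated with birth/division times, the
interdivision time, min/max/mean/sd of every numeric attribute over the
lifespan, and the majority value of every boolean attribute.
"""

from __future__ import annotations

import logging
import math
import statistics

from .lineage_forest import DivisionForest, LineageForest, instance_key, is_synthetic

logger = logging.getLogger(__name__)


def add_age(flt: LineageForest) -> LineageForest:
    """Annotate every instance with ``age`` = (frame - birth frame) * Δt minutes."""
    for graph in [flt.graph] + [b.graph for b in flt.motherless_store]:
        births: dict[str, int] = {}
        for n in graph.nodes:
            if not is_synthetic(n):
                births[n[0]] = min(births.get(n[0], n[1]), n[1])
        for n in graph.nodes:
            if not is_synthetic(n):
                graph.nodes[n]["age"] = (n[1] - births[n[0]]) * flt.frame_period
    return flt


def add_roc(flt: LineageForest, attr: str, normalized: bool = False) -> LineageForest:
    """Annotate instances with the forward-difference rate of change of ``attr``.

    ``roc_<attr>`` = (x[f+1] - x[f]) / Δt per minute; with ``normalized``,
    ``roc_<attr>_pct`` = 100 * (x[f+1] - x[f]) / x[f] percent per frame.
    The last instance of every lifespan gets NaN (division boundaries are
    never crossed).  A zero value with ``normalized`` yields NaN with a
    warning.
    """
    out_name = f"roc_{attr}_pct" if normalized else f"roc_{attr}"
    for graph in [flt.graph] + [b.graph for b in flt.motherless_store]:
        spans: dict[str, list[int]] = {}
        for n in graph.nodes:
            if not is_synthetic(n):
                spans.setdefault(n[0], []).append(n[1])
        for cell_id, frames in spans.items():
            frames.sort()
            for i, frame in enumerate(frames):
                node = instance_key(cell_id, frame)
                if attr not in graph.nodes[node]:
                    raise KeyError(f"attribute {attr!r} missing on instance {node!r}")
                if i == len(frames) - 1:
                    graph.nodes[node][out_name] = math.nan
                    continue
                x0 = graph.nodes[node][attr]
                x1 = graph.nodes[instance_key(cell_id, frames[i + 1])][attr]
                if normalized:
                    if x0 == 0:
                        logger.warning(
                            "normalized roc undefined at %r (zero %s)", node, attr
                        )
                        graph.nodes[node][out_name] = math.nan
                    else:
                        graph.nodes[node][out_name] = 100.0 * (x1 - x0) / x0
                else:
                    graph.nodes[node][out_name] = (x1 - x0) / flt.frame_period
    return flt


def compute_life_attributes(
    flt: LineageForest,
    fdt: DivisionForest,
    duration_convention: str = "inclusive",
) -> DivisionForest:
    """Populate life attributes on every FDT node from its FLT lifespan.

    Stored per cell: ``birth_time`` and ``division_time_abs`` in minutes
    (first and last observed instance), ``division_duration`` (the
    interdivision time), and per numeric attribute ``<attr>_min/_max/
    _mean/_sd`` (sample sd, n-1 denominator; sd of a single observation
    is 0).  Boolean attributes reduce to their strict-majority value; a
    tie reduces to False and is flagged in ``<attr>_majority_tie``.

    ``duration_convention``: with "inclusive" (default) the interdivision
    time is ``lifespan_frames * Δt`` — the division falls between the last
    observed frame and the next, so back-to-back generations tile the
    movie.  "exclusive" uses ``(lifespan_frames - 1) * Δt``, the elapsed
    time between first and last observation.
    """
    if duration_convention not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown duration convention {duration_convention!r}")
    dt = flt.frame_period
    spans = flt.cells()
    for cell_id in fdt.cell_nodes():
        nodes = [instance_key(cell_id, f) for f in spans[cell_id]]
        data = [flt.graph.nodes[n] for n in nodes]
        first, last = nodes[0][1], nodes[-1][1]
        n = len(nodes)
        attrs = fdt.graph.nodes[cell_id]
        attrs["birth_time"] = flt.time_of_frame(first)
        attrs["division_time_abs"] = flt.time_of_frame(last)
        attrs["lifespan_frames"] = n
        attrs["division_duration"] = (
            n * dt if duration_convention == "inclusive" else (n - 1) * dt
        )

        numeric = sorted(
            k
            for k, v in data[0].items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
            and k not in ("frame", "generation")
        )
        for name in numeric:
            series = [d[name] for d in data if name in d]
            attrs[f"{name}_min"] = min(series)
            attrs[f"{name}_max"] = max(series)
            attrs[f"{name}_mean"] = statistics.fmean(series)
            attrs[f"{name}_sd"] = statistics.stdev(series) if len(series) > 1 else 0.0
        for name in sorted(k for k, v in data[0].items() if isinstance(v, bool)):
            series = [bool(d[name]) for d in data if name in d]
            trues = sum(series)
            tie = 2 * trues == len(series)
            attrs[name] = trues > len(series) - trues
            if tie:
                attrs[f"{name}_majority_tie"] = True
                logger.warning(
                    "cell %r: boolean attribute %r tied; reduced to False", cell_id, name
                )
    return fdt
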