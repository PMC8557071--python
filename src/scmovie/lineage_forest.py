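"""Forest-of-lineage-trees (FLT) and forest-of-division-trees (FDT).

The FLT represents every *cell instance* (one cell at one frame) as a node.
Edges connect consecutive instances of the same cell, and the last instance
of a mother to the first instance of each daughter.  A synthetic master
root sits above one synthetic root per colony, so an instance at frame
``f`` lives at tree level ``f + 2`` (master = level 1, colony roots =
level 2).  Cells that appear after frame 1 without a resolved mother are
kept out of the main forest, in a motherless-branch store, so that only
real division events feed the analytics; tracking errors can later be
repaired by gluing a stored branch back onto its true mother
(:func:`add_branch`).

The FDT collapses each lifespan to a single node; its levels are cell
generations (a generation-``g`` cell sits at level ``g + 3``, generations
counting from 0 at the progenitors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable

import networkx as nx
import pandas as pd

from .io_cell_lists import CellList, CellRecord

logger = logging.getLogger(__name__)

MASTER = ("master",)


def colony_root(colony_id: str) -> tuple:
    return ("colony", colony_id)


def instance_key(cell_id: str, frame: int) -> tuple:
    return (cell_id, frame)


def is_synthetic(node: Hashable) -> bool:
    return isinstance(node, tuple) and len(node) > 0 and node[0] in ("master", "colony")


@dataclass
class Branch:
    """A detached sub-forest of cell instances, re-attachable atomically."""

    graph: nx.DiGraph
    root: tuple

    @property
    def root_cell_id(self) -> str:
        return self.graph.nodes[self.root]["cell_id"]

    @property
    def root_frame(self) -> int:
        return self.graph.nodes[self.root]["frame"]

    def size(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class LineageForest:
    """Per-frame cell-instance forest of a single-cell movie."""

    graph: nx.DiGraph
    frame_period: float
    n_frames: int
    motherless_store: list[Branch] = field(default_factory=list)
    parent: "LineageForest | None" = None  # provenance for selections

    # -- structure queries ------------------------------------------------

    @property
    def colony_ids(self) -> list[str]:
        return sorted(n[1] for n in self.graph.successors(MASTER))

    def instance_nodes(self) -> list[tuple]:
        return [n for n in self.graph.nodes if not is_synthetic(n)]

    def n_instances(self) -> int:
        return sum(1 for n in self.graph.nodes if not is_synthetic(n))

    def level(self, node: tuple) -> int:
        """Tree level: master = 1, colony roots = 2, frame f = f + 2."""
        if node == MASTER:
            return 1
        if is_synthetic(node):
            return 2
        return self.graph.nodes[node]["frame"] + 2

    def cells(self) -> dict[str, list[int]]:
        """Mapping cell_id -> sorted frames present in the main forest."""
        out: dict[str, list[int]] = {}
        for n in self.graph.nodes:
            if is_synthetic(n):
                continue
            out.setdefault(n[0], []).append(n[1])
        for frames in out.values():
            frames.sort()
        return out

    def lifespan_nodes(self, cell_id: str) -> list[tuple]:
        frames = self.cells().get(cell_id)
        if frames is None:
            raise KeyError(f"cell {cell_id!r} not in forest")
        return [instance_key(cell_id, f) for f in frames]

    def last_instance(self, cell_id: str) -> tuple:
        return self.lifespan_nodes(cell_id)[-1]

    def first_instance(self, cell_id: str) -> tuple:
        return self.lifespan_nodes(cell_id)[0]

    def daughters(self, cell_id: str) -> list[str]:
        """Cells whose first instance is a child of this cell's last instance."""
        last = self.last_instance(cell_id)
        return sorted(
            {c[0] for c in self.graph.successors(last) if c[0] != cell_id}
        )

    def mother(self, cell_id: str) -> str | None:
        first = self.first_instance(cell_id)
        preds = [p for p in self.graph.predecessors(first) if not is_synthetic(p)]
        if preds and preds[0][0] != cell_id:
            return preds[0][0]
        return None

    def division_nodes(self) -> list[tuple]:
        """Instance nodes with >= 2 children (observed division events)."""
        return [
            n
            for n in self.graph.nodes
            if not is_synthetic(n) and self.graph.out_degree(n) >= 2
        ]

    def time_of_frame(self, frame: int) -> float:
        return (frame - 1) * self.frame_period

    # -- attribute helpers -------------------------------------------------

    def instance_attr(self, node: tuple, attr: str):
        return self.graph.nodes[node][attr]

    def attr_series(self, cell_id: str, attr: str) -> list:
        return [self.graph.nodes[n][attr] for n in self.lifespan_nodes(cell_id)]

    def copy(self) -> "LineageForest":
        return LineageForest(
            graph=self.graph.copy(),
            frame_period=self.frame_period,
            n_frames=self.n_frames,
            motherless_store=[Branch(b.graph.copy(), b.root) for b in self.motherless_store],
            parent=self.parent,
        )


@dataclass
class DivisionForest:
    """Per-cell (lifespan-collapsed) forest; levels are generations."""

    graph: nx.DiGraph
    frame_period: float
    filters_applied: dict = field(default_factory=dict)
    orphaned: list[str] = field(default_factory=list)
    parent: "DivisionForest | None" = None

    @property
    def colony_ids(self) -> list[str]:
        return sorted(n[1] for n in self.graph.successors(MASTER))

    def cell_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if not is_synthetic(n)]

    def n_cells(self) -> int:
        return len(self.cell_nodes())

    def level(self, node) -> int:
        """Tree level: master = 1, colony roots = 2, generation g = g + 3."""
        if node == MASTER:
            return 1
        if is_synthetic(node):
            return 2
        return self.graph.nodes[node]["generation"] + 3

    def mother(self, cell_id: str) -> str | None:
        preds = [p for p in self.graph.predecessors(cell_id) if not is_synthetic(p)]
        return preds[0] if preds else None

    def daughters(self, cell_id: str) -> list[str]:
        return sorted(self.graph.successors(cell_id))

    def life_attr(self, cell_id: str, attr: str):
        return self.graph.nodes[cell_id][attr]

    def copy(self) -> "DivisionForest":
        return DivisionForest(
            graph=self.graph.copy(),
            frame_period=self.frame_period,
            filters_applied=dict(self.filters_applied),
            orphaned=list(self.orphaned),
            parent=self.parent,
        )


# ---------------------------------------------------------------------------
# construction


def _chain_record(graph: nx.DiGraph, rec: CellRecord, colony: str) -> None:
    """Add a cell's instance chain (nodes + persistence edges) to a graph."""
    prev = None
    for i, frame in enumerate(rec.frames):
        node = instance_key(rec.cell_id, frame)
        attrs: dict = {
            "cell_id": rec.cell_id,
            "frame": frame,
            "colony": colony,
        }
        for name, series in rec.numeric_attrs.items():
            attrs[name] = float(series[i])
        for name, series in rec.boolean_attrs.items():
            attrs[name] = bool(series[i])
        if rec.centroid is not None:
            attrs["centroid"] = tuple(rec.centroid[i])
        graph.add_node(node, **attrs)
        if prev is not None:
            graph.add_edge(prev, node)
        prev = node


def build_flt(cells: CellList) -> LineageForest:
    """Transform a validated cell list into a forest of lineage trees.

    Progenitors (cells present at frame 1, or declared motherless at frame
    1) attach under their colony's synthetic root.  Cells that appear
    later without a resolved mother seed motherless branches, stored
    separately together with their whole progeny.  Colony labels are
    inherited from each cell's progenitor (so they survive colony
    merges), and generation labels count cell boundaries from the
    progenitor.
    """
    cells.validate()
    by_id = cells.by_id()
    children: dict[str, list[str]] = {}
    for rec in cells.cells:
        if rec.mother_id is not None:
            children.setdefault(rec.mother_id, []).append(rec.cell_id)
    for kids in children.values():
        kids.sort()

    progenitors = [
        rec for rec in cells.cells if rec.mother_id is None and rec.first_frame == 1
    ]
    motherless_roots = [
        rec for rec in cells.cells if rec.mother_id is None and rec.first_frame > 1
    ]

    graph = nx.DiGraph()
    graph.add_node(MASTER)

    def grow(graph: nx.DiGraph, root_rec: CellRecord, colony: str, generation: int):
        """DFS-attach root_rec and its progeny, labeling colony/generation."""
        stack = [(root_rec, generation, None)]
        while stack:
            rec, gen, attach_to = stack.pop()
            _chain_record(graph, rec, colony)
            first = instance_key(rec.cell_id, rec.first_frame)
            for n in (instance_key(rec.cell_id, f) for f in rec.frames):
                graph.nodes[n]["generation"] = gen
            if attach_to is not None:
                graph.add_edge(attach_to, first)
            last = instance_key(rec.cell_id, rec.last_frame)
            for kid in children.get(rec.cell_id, []):
                stack.append((by_id[kid], gen + 1, last))

    for rec in sorted(progenitors, key=lambda r: r.cell_id):
        root = colony_root(rec.colony_id)
        if root not in graph:
            graph.add_node(root)
            graph.add_edge(MASTER, root)
        grow(graph, rec, rec.colony_id, 0)
        graph.add_edge(root, instance_key(rec.cell_id, rec.first_frame))

    store: list[Branch] = []
    for rec in sorted(motherless_roots, key=lambda r: r.cell_id):
        bgraph = nx.DiGraph()
        grow(bgraph, rec, rec.colony_id, 0)
        store.append(Branch(bgraph, instance_key(rec.cell_id, rec.first_frame)))
        logger.info(
            "motherless branch: cell %r first seen at frame %d (%d instances)",
            rec.cell_id,
            rec.first_frame,
            bgraph.number_of_nodes(),
        )

    return LineageForest(
        graph=graph,
        frame_period=cells.frame_period,
        n_frames=cells.n_frames,
        motherless_store=store,
    )


def _cell_spans(flt: LineageForest) -> dict[str, list[int]]:
    return flt.cells()


def build_fdt(
    flt: LineageForest,
    min_life_frames: int = 1,
    require_complete: bool = False,
) -> DivisionForest:
    """Collapse lifespans to single nodes, filtering unreliable cells.

    Cells observed for fewer than ``min_life_frames`` frames are excluded.
    With ``require_complete``, cells whose trajectory terminates in a leaf
    (no observed division — movie end, death, or tracking loss) are
    excluded as well, so only complete birth-to-division lifespans remain.
    Descendants of an excluded cell are dropped from the FDT and reported
    in ``orphaned``.
    """
    if min_life_frames < 1:
        raise ValueError(f"min_life_frames must be >= 1, got {min_life_frames}")
    spans = _cell_spans(flt)

    def excluded_here(cell_id: str) -> bool:
        frames = spans[cell_id]
        if len(frames) < min_life_frames:
            return True
        if require_complete:
            last = instance_key(cell_id, frames[-1])
            if flt.graph.out_degree(last) == 0:
                return True
        return False

    graph = nx.DiGraph()
    graph.add_node(MASTER)
    orphaned: list[str] = []

    # walk cell-level tree from progenitors so exclusion cascades
    for cid in flt.colony_ids:
        root = colony_root(cid)
        graph.add_node(root)
        graph.add_edge(MASTER, root)
    for cell_id in sorted(spans):
        first = instance_key(cell_id, spans[cell_id][0])
        preds = list(flt.graph.predecessors(first))
        if preds and is_synthetic(preds[0]):
            _collapse_subtree(flt, graph, spans, cell_id, preds[0], excluded_here, orphaned)

    fdt = DivisionForest(
        graph=graph,
        frame_period=flt.frame_period,
        filters_applied={
            "min_life_frames": min_life_frames,
            "require_complete": require_complete,
        },
        orphaned=orphaned,
    )
    if orphaned:
        logger.info("FDT: %d cells dropped as descendants of excluded cells", len(orphaned))
    return fdt


def _collapse_subtree(flt, graph, spans, cell_id, attach_to, excluded_here, orphaned):
    stack = [(cell_id, attach_to, False)]
    while stack:
        cid, parent, ancestor_excluded = stack.pop()
        frames = spans[cid]
        drop = excluded_here(cid)
        if ancestor_excluded and not drop:
            orphaned.append(cid)
        keep = not drop and not ancestor_excluded
        if keep:
            node_attrs = flt.graph.nodes[instance_key(cid, frames[0])]
            graph.add_node(
                cid,
                colony=node_attrs["colony"],
                generation=node_attrs["generation"],
                lifespan_frames=len(frames),
                first_frame=frames[0],
                last_frame=frames[-1],
            )
            graph.add_edge(parent, cid)
        last = instance_key(cid, frames[-1])
        for succ in flt.graph.successors(last):
            if succ[0] != cid:
                stack.append((succ[0], cid if keep else parent, drop or ancestor_excluded))


# ---------------------------------------------------------------------------
# branch surgery


def extract_branch(flt: LineageForest, node: tuple) -> tuple[LineageForest, Branch]:
    """Detach the subtree rooted at an instance node into the motherless store.

    The forest is modified in place and returned together with the
    detached branch.
    """
    if node not in flt.graph:
        raise KeyError(f"node {node!r} not in forest")
    if is_synthetic(node):
        raise KeyError(f"node {node!r} is synthetic; only cell instances can be extracted")
    members = {node} | nx.descendants(flt.graph, node)
    bgraph = flt.graph.subgraph(members).copy()
    flt.graph.remove_nodes_from(members)
    branch = Branch(bgraph, node)
    flt.motherless_store.append(branch)
    return flt, branch


def add_branch(flt: LineageForest, branch: Branch, target: tuple) -> LineageForest:
    """Glue a detached branch under an instance node of the forest.

    The branch root's frame must be the target's frame + 1 (frame
    continuity).  If the branch root belongs to a different cell than the
    target, the target gains a daughter; a target that thereby reaches two
    or more children recovers a previously missed division event.  If the
    root is the same cell (a lifespan split in two), the lifespan is
    rejoined without a division.  Colony and generation labels of the
    branch are recomputed from the attachment site.
    """
    if target in branch.graph:
        raise ValueError(f"target {target!r} lies inside the branch being attached (cycle)")
    if target not in flt.graph:
        raise KeyError(f"target {target!r} not in forest")
    if is_synthetic(target):
        raise KeyError(f"target {target!r} is synthetic")
    tframe = flt.graph.nodes[target]["frame"]
    rframe = branch.graph.nodes[branch.root]["frame"]
    if rframe != tframe + 1:
        raise ValueError(
            f"frame discontinuity: target at frame {tframe}, branch root at "
            f"frame {rframe} (expected {tframe + 1})"
        )
    overlap = set(branch.graph.nodes) & set(flt.graph.nodes)
    if overlap:
        raise ValueError(f"branch nodes already present in forest: {sorted(overlap)[:3]}")

    flt.graph.update(branch.graph)
    flt.graph.add_edge(target, branch.root)
    flt.motherless_store = [b for b in flt.motherless_store if b.root != branch.root]

    # relabel colony and generation downstream of the attachment
    colony = flt.graph.nodes[target]["colony"]
    tgen = flt.graph.nodes[target]["generation"]
    tcell = flt.graph.nodes[target]["cell_id"]
    for n in branch.graph.nodes:
        flt.graph.nodes[n]["colony"] = colony
    # generation = target generation + number of cell boundaries crossed
    stack = [(branch.root, tgen + (0 if branch.root[0] == tcell else 1))]
    while stack:
        n, gen = stack.pop()
        flt.graph.nodes[n]["generation"] = gen
        for succ in flt.graph.successors(n):
            if succ in branch.graph:
                stack.append((succ, gen + (0 if succ[0] == n[0] else 1)))
    if branch.root[0] != tcell and flt.graph.out_degree(target) >= 2:
        logger.info(
            "add_branch: recovered division of cell %r at frame %d", tcell, tframe
        )
    return flt


# ---------------------------------------------------------------------------
# cell-life inspection


def cell_life_table(flt: LineageForest, cell_id: str) -> pd.DataFrame:
    """Chronological per-frame report of one cell's life.

    One row per instance with all attribute values, flags for the birth
    and division frames, the mother and daughters, and — when centroids
    are available — the nearest-neighbor cell per frame.  Supports visual
    error hunting (e.g. spotting an abrupt length drop mid-trajectory
    where a division was missed) without access to the movie images.
    """
    spans = flt.cells()
    store_cells = {n[0] for b in flt.motherless_store for n in b.graph.nodes}
    in_store = cell_id in store_cells
    if cell_id not in spans and not in_store:
        raise KeyError(f"cell {cell_id!r} not in forest or motherless store")

    if in_store:
        branch = next(
            b for b in flt.motherless_store if any(n[0] == cell_id for n in b.graph.nodes)
        )
        graph = branch.graph
        frames = sorted(n[1] for n in graph.nodes if n[0] == cell_id)
    else:
        graph = flt.graph
        frames = spans[cell_id]

    rows = []
    for frame in frames:
        node = instance_key(cell_id, frame)
        attrs = dict(graph.nodes[node])
        row = {
            "frame": frame,
            "time_min": flt.time_of_frame(frame),
            "is_birth": frame == frames[0],
            "is_division": frame == frames[-1] and graph.out_degree(node) >= 2,
        }
        for k, v in attrs.items():
            if k in ("cell_id", "frame"):
                continue
            if k == "centroid":
                row["centroid_x"], row["centroid_y"] = v
            else:
                row[k] = v
        if "centroid" in attrs:
            row["nearest_neighbor"] = _nearest_neighbor(flt, cell_id, frame)
        rows.append(row)
    table = pd.DataFrame(rows)

    first = instance_key(cell_id, frames[0])
    preds = [p for p in graph.predecessors(first) if not is_synthetic(p)]
    mother = preds[0][0] if preds and preds[0][0] != cell_id else None
    last = instance_key(cell_id, frames[-1])
    daughters = sorted({s[0] for s in graph.successors(last) if s[0] != cell_id})
    table.attrs["cell_id"] = cell_id
    table.attrs["mother"] = mother
    table.attrs["motherless"] = mother is None and frames[0] > 1
    table.attrs["daughters"] = daughters
    return table


def _nearest_neighbor(flt: LineageForest, cell_id: str, frame: int) -> str | None:
    me = instance_key(cell_id, frame)
    if me not in flt.graph or "centroid" not in flt.graph.nodes[me]:
        return None
    x0, y0 = flt.graph.nodes[me]["centroid"]
    best, best_d = None, float("inf")
    for n, data in flt.graph.nodes(data=True):
        if is_synthetic(n) or n[0] == cell_id or n[1] != frame:
            continue
        c = data.get("centroid")
        if c is None:
            continue
        d = (c[0] - x0) ** 2 + (c[1] - y0) ** 2
        if d < best_d:
            best, best_d = n[0], d
    return best


# ---------------------------------------------------------------------------
# export


def export_graphml(forest, path) -> None:
    """Write a forest (FLT or FDT) as GraphML with attribute payloads."""
    g = nx.DiGraph()
    for n, data in forest.graph.nodes(data=True):
        name = "|".join(str(p) for p in n) if isinstance(n, tuple) else str(n)
        clean = {}
        for k, v in data.items():
            if k == "centroid":
                clean["centroid_x"], clean["centroid_y"] = float(v[0]), float(v[1])
            elif v is not None:
                clean[k] = v
        g.add_node(name, **clean)
    for a, b in forest.graph.edges:
        sa = "|".join(str(p) for p in a) if isinstance(a, tuple) else str(a)
        sb = "|".join(str(p) for p in b) if isinstance(b, tuple) else str(b)
        g.add_edge(sa, sb)
    nx.write_graphml(g, path)
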