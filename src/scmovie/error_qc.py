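"""Detection of likely segmentation/tracking errors from the forest.

Three complementary signatures, all report-only (repair is explicit
surgery via :mod:`scmovie.lineage_forest`):

* **Motherless branches** — a cell that appears after frame 1 without a
  resolved mother is, absent cell migration into the field of view, a
  missed division.  For each stored branch, candidate mothers are ranked
  among the cells present at the previous frame, scoring frame-adjacent
  cells by the abruptness of their size drop at the branch's birth (a
  mother that "absorbed" a daughter keeps growing, then drops) and, when
  centroids exist, spatial proximity.
* **Exponential-fit outliers** — cells whose length trajectory fails the
  exponential model or fits it with a large RMSE.
* **roc anomalies** — instances whose frame-to-frame percent change of
  length/area exceeds a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineage_forest import LineageForest, instance_key, is_synthetic


@dataclass
class MotherlessReport:
    root_cell_id: str
    first_frame: int
    size: int
    candidates: list[tuple[str, float]] = field(default_factory=list)
    """Candidate mother cell ids with scores, best first."""


def list_motherless(
    flt: LineageForest,
    attr: str = "length",
    drop_weight: float = 1.0,
    proximity_weight: float = 1.0,
) -> list[MotherlessReport]:
    """Report every stored motherless branch with candidate attachment sites.

    Candidates are cells whose trajectory spans the frame just before the
    branch's first frame.  Each is scored by the normalized drop of
    ``attr`` across that frame boundary (an abrupt decrease suggests a
    missed division there) plus, when centroids are available, closeness
    to the branch root.  Scores are for triage; attachment is the user's
    call.
    """
    reports = []
    for branch in flt.motherless_store:
        root = branch.root
        root_frame = branch.graph.nodes[root]["frame"]
        root_centroid = branch.graph.nodes[root].get("centroid")
        prev_frame = root_frame - 1
        scored: list[tuple[str, float]] = []
        # candidates may live in the main forest or inside *other* stored
        # branches (nested tracking errors)
        graphs = [flt.graph] + [b.graph for b in flt.motherless_store if b is not branch]
        for graph in graphs:
            for n, data in graph.nodes(data=True):
                if is_synthetic(n) or n[1] != prev_frame:
                    continue
                nxt = instance_key(n[0], root_frame)
                score = 0.0
                root_size = branch.graph.nodes[root].get(attr)
                if nxt in graph and attr in data and attr in graph.nodes[nxt]:
                    x0, x1 = data[attr], graph.nodes[nxt][attr]
                    if x0 > 0 and x1 < x0:
                        score += drop_weight * (x0 - x1) / x0
                elif nxt not in graph:
                    # track ends exactly where the orphan begins: the classic
                    # unmatched-division mother.  A division halves the
                    # mother, so rank ended tracks by how close the orphan's
                    # birth size is to half the candidate's final size.
                    score += drop_weight * 0.5
                    if root_size and attr in data and data[attr] > 0:
                        mismatch = abs(data[attr] / 2.0 - root_size) / root_size
                        score += drop_weight * 0.5 / (1.0 + mismatch)
                if root_centroid is not None and data.get("centroid") is not None:
                    d = math.dist(root_centroid, data["centroid"])
                    score += proximity_weight / (1.0 + d)
                if score > 0:
                    scored.append((n[0], score))
        scored.sort(key=lambda t: (-t[1], t[0]))
        reports.append(
            MotherlessReport(
                root_cell_id=branch.root_cell_id,
                first_frame=root_frame,
                size=branch.size(),
                candidates=scored,
            )
        )
    return sorted(reports, key=lambda r: (r.first_frame, r.root_cell_id))


def detect_bad_fits(fits, rmse_threshold="auto") -> dict:
    """Cells whose growth fit failed or deviates beyond an RMSE threshold.

    ``fits`` is the per-cell mapping from :func:`fit_forest_growth`.
    With ``rmse_threshold="auto"`` the threshold is proposed from the
    distribution of all converged cells' RMSE values as mean + 2 sd — a
    transparent stand-in for eyeballing the RMSE histogram.  Returns the
    flagged ids, the non-converged ids, and the threshold used.
    """
    if not fits:
        raise ValueError("no fits supplied")
    items = fits.items() if isinstance(fits, dict) else ((f.cell_id, f) for f in fits)
    items = list(items)
    failed = [cid for cid, f in items if not f.converged]
    rmses = np.array([f.rmse for _, f in items if f.converged])
    if rmse_threshold == "auto":
        if rmses.size == 0:
            rmse_threshold = math.inf
        else:
            rmse_threshold = float(np.mean(rmses) + 2 * np.std(rmses, ddof=1 if rmses.size > 1 else 0))
    high = [cid for cid, f in items if f.converged and f.rmse > rmse_threshold]
    return {
        "suspects": sorted(set(failed) | set(high)),
        "failed_fit": sorted(failed),
        "high_rmse": sorted(high),
        "threshold": rmse_threshold,
    }


def detect_roc_anomalies(
    flt: LineageForest, attr: str = "length", pct_threshold: float = 30.0
) -> pd.DataFrame:
    """Instances whose normalized rate of change exceeds a percent threshold.

    Requires :func:`scmovie.cell_attributes.add_roc` with
    ``normalized=True`` to have been run for ``attr``.  Returns a frame
    with one row per anomalous instance (cell_id, frame, pct change),
    grouped by cell.
    """
    col = f"roc_{attr}_pct"
    rows = []
    missing = True
    for n, data in flt.graph.nodes(data=True):
        if is_synthetic(n):
            continue
        if col in data:
            missing = False
            v = data[col]
            if np.isfinite(v) and abs(v) > pct_threshold:
                rows.append({"cell_id": n[0], "frame": n[1], "roc_pct": v})
    if missing:
        raise KeyError(
            f"attribute {col!r} not present; run add_roc({attr!r}, normalized=True) first"
        )
    df = pd.DataFrame(rows, columns=["cell_id", "frame", "roc_pct"])
    return df.sort_values(["cell_id", "frame"]).reset_index(drop=True)


def suspected_lost_divisions(flt: LineageForest) -> list[str]:
    """Cells ending mid-movie with exactly one successor cell.

    A trajectory that stops before the last frame and hands over to a
    single "daughter" is the classic signature of a division whose second
    daughter was not matched; such cells are flagged for inspection.
    """
    flagged = []
    for cell_id, frames in flt.cells().items():
        if frames[-1] >= flt.n_frames:
            continue
        last = instance_key(cell_id, frames[-1])
        kids = {s[0] for s in flt.graph.successors(last) if s[0] != cell_id}
        if len(kids) == 1:
            flagged.append(cell_id)
    return sorted(flagged)
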