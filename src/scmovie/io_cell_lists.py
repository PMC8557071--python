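"""Canonical cell-list interchange format.

Cell trackers emit one record per tracked cell: the colony it belongs to,
its mother (if the tracker resolved the division), the contiguous range of
movie frames over which it was observed, and one measurement per frame for
each numeric or boolean attribute (length, area, fluorescence, touching
flag, ...).  This module defines that record as a validated in-memory
structure, reads/writes it as JSON, and adapts long-format CSV exports of
third-party trackers.

Conventions: frames are 1-based; the time of frame ``f`` is
``(f - 1) * frame_period`` minutes, so t = 0 at movie start.  A missing
``mother_id`` on a first-frame cell marks a progenitor; a missing
``mother_id`` later in the movie marks a motherless branch (a cell that
entered the field of view, or a tracking error).  A ``mother_id`` that
names no record in the list is a validation error, not a motherless cell.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Attribute names with conventional meaning used by growth/QC defaults.
RESERVED_ATTRS = ("length", "area")


class ValidationError(ValueError):
    """A cell list violates the interchange-format invariants."""


class FormatError(ValueError):
    """A file cannot be parsed as the expected format."""


@dataclass
class CellRecord:
    """One tracked cell: its lifespan and per-frame measurements.

    Parameters
    ----------
    cell_id :
        Unique identifier within the movie.
    colony_id :
        Identifier of the colony the cell emanated from.
    mother_id :
        ``cell_id`` of the mother, or ``None`` for progenitors and
        motherless cells.
    frames :
        1-based frame indices, strictly increasing with step 1.
    numeric_attrs :
        Mapping attribute name -> one real value per frame.
    boolean_attrs :
        Mapping attribute name -> one boolean per frame.
    centroid :
        Optional per-frame ``(x, y)`` pixel coordinates.
    """

    cell_id: str
    colony_id: str
    mother_id: str | None
    frames: list[int]
    numeric_attrs: dict[str, list[float]] = field(default_factory=dict)
    boolean_attrs: dict[str, list[bool]] = field(default_factory=dict)
    centroid: list[tuple[float, float]] | None = None

    @property
    def first_frame(self) -> int:
        return self.frames[0]

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def lifespan(self) -> int:
        """Number of frames the cell was observed (>= 1)."""
        return len(self.frames)

    def validate(self) -> None:
        if not self.frames:
            raise ValidationError(f"cell {self.cell_id!r}: empty frame list")
        for a, b in zip(self.frames, self.frames[1:]):
            if b != a + 1:
                raise ValidationError(
                    f"cell {self.cell_id!r}: non-contiguous frames "
                    f"({a} followed by {b})"
                )
        n = len(self.frames)
        for name, series in self.numeric_attrs.items():
            if len(series) != n:
                raise ValidationError(
                    f"cell {self.cell_id!r}: numeric attribute {name!r} has "
                    f"{len(series)} values for {n} frames"
                )
        for name, series in self.boolean_attrs.items():
            if len(series) != n:
                raise ValidationError(
                    f"cell {self.cell_id!r}: boolean attribute {name!r} has "
                    f"{len(series)} values for {n} frames"
                )
        if self.centroid is not None and len(self.centroid) != n:
            raise ValidationError(
                f"cell {self.cell_id!r}: centroid has {len(self.centroid)} "
                f"points for {n} frames"
            )


@dataclass
class CellList:
    """All tracked cells of one single-cell movie.

    ``frame_period`` is the sampling period in minutes per frame.
    """

    frame_period: float
    n_frames: int
    cells: list[CellRecord] = field(default_factory=list)
    provenance: str = ""

    def validate(self) -> None:
        if not (self.frame_period > 0):
            raise ValidationError(f"frame_period must be > 0, got {self.frame_period}")
        seen: dict[str, CellRecord] = {}
        for rec in self.cells:
            rec.validate()
            if rec.cell_id in seen:
                raise ValidationError(f"duplicate cell_id {rec.cell_id!r}")
            seen[rec.cell_id] = rec
            if rec.first_frame < 1 or rec.last_frame > self.n_frames:
                raise ValidationError(
                    f"cell {rec.cell_id!r}: frames [{rec.first_frame}, "
                    f"{rec.last_frame}] outside movie range [1, {self.n_frames}]"
                )
        for rec in self.cells:
            if rec.mother_id is None:
                continue
            mother = seen.get(rec.mother_id)
            if mother is None:
                raise ValidationError(
                    f"cell {rec.cell_id!r}: mother_id {rec.mother_id!r} names "
                    f"no cell in the list"
                )
            if mother.last_frame != rec.first_frame - 1:
                raise ValidationError(
                    f"cell {rec.cell_id!r}: mother {rec.mother_id!r} last seen "
                    f"at frame {mother.last_frame}, daughter first seen at "
                    f"frame {rec.first_frame} (expected {mother.last_frame + 1})"
                )

    def by_id(self) -> dict[str, CellRecord]:
        return {rec.cell_id: rec for rec in self.cells}

    def time_of_frame(self, frame: int) -> float:
        """Time in minutes of a 1-based frame index (frame 1 -> 0 min)."""
        return (frame - 1) * self.frame_period


def _record_to_obj(rec: CellRecord) -> dict:
    return {
        "cell_id": rec.cell_id,
        "colony_id": rec.colony_id,
        "mother_id": rec.mother_id,
        "frames": list(rec.frames),
        "numeric_attrs": {k: [float(v) for v in s] for k, s in rec.numeric_attrs.items()},
        "boolean_attrs": {k: [bool(v) for v in s] for k, s in rec.boolean_attrs.items()},
        "centroid": None
        if rec.centroid is None
        else [[float(x), float(y)] for x, y in rec.centroid],
    }


def _record_from_obj(obj: dict) -> CellRecord:
    try:
        centroid = obj.get("centroid")
        return CellRecord(
            cell_id=str(obj["cell_id"]),
            colony_id=str(obj["colony_id"]),
            mother_id=None if obj.get("mother_id") is None else str(obj["mother_id"]),
            frames=[int(f) for f in obj["frames"]],
            numeric_attrs={
                str(k): [float(v) for v in s]
                for k, s in obj.get("numeric_attrs", {}).items()
            },
            boolean_attrs={
                str(k): [bool(v) for v in s]
                for k, s in obj.get("boolean_attrs", {}).items()
            },
            centroid=None if centroid is None else [(float(x), float(y)) for x, y in centroid],
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed cell record: {exc}") from exc


def read_cell_list(path) -> CellList:
    """Read and validate a canonical cell-list JSON file.

    Raises
    ------
    FormatError
        If the file is not parseable as the canonical schema.
    ValidationError
        If the content violates a cell-list invariant (non-contiguous
        frames, duplicate ids, unresolvable or frame-mismatched mothers,
        attribute/frame length mismatch).
    """
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(obj, dict) or "cells" not in obj:
        raise FormatError(f"{path}: missing top-level 'cells' array")
    try:
        cells = CellList(
            frame_period=float(obj["frame_period_minutes"]),
            n_frames=int(obj["n_frames"]),
            cells=[_record_from_obj(c) for c in obj["cells"]],
            provenance=str(obj.get("provenance", "")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, (FormatError, ValidationError)):
            raise
        raise FormatError(f"{path}: malformed header: {exc}") from exc
    cells.validate()
    return cells


def write_cell_list(cells: CellList, path) -> None:
    """Write a validated cell list as canonical JSON (UTF-8).

    The list is validated first; an invariant-violating list is refused so
    that every file on disk round-trips through :func:`read_cell_list`.
    """
    cells.validate()
    obj = {
        "frame_period_minutes": cells.frame_period,
        "n_frames": cells.n_frames,
        "provenance": cells.provenance,
        "cells": [_record_to_obj(rec) for rec in cells.cells],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


#: column_map keys with structural meaning; all other mapped columns become
#: numeric or boolean attributes keyed by their mapped name.
_STRUCTURAL_FIELDS = ("cell_id", "frame", "colony_id", "mother_id")


def import_tracker_csv(
    path,
    frame_period: float,
    column_map: Mapping[str, str],
    *,
    delimiter: str = ",",
    n_frames: int | None = None,
    provenance: str = "csv-import",
) -> CellList:
    """Import a long-format tracker export (one row per cell instance).

    ``column_map`` maps CSV column names to canonical fields: ``cell_id``
    and ``frame`` are required; ``colony_id`` and ``mother_id`` are
    optional; every other mapped column becomes an attribute series (bool
    dtype columns become boolean attributes).  The NA token is "NA".

    A gap in a cell's frame sequence splits the cell into separate
    records: the later fragment is renamed ``<id>#2``, ``<id>#3``, ...,
    becomes motherless, and the split is logged.  Trackers that lose a
    cell for a frame have, in truth, lost the track; the adapter surfaces
    the discontinuity instead of interpolating over it.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, na_values=["NA"])
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty CSV") from exc
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: cannot read CSV: {exc}") from exc
    if df.empty:
        raise ValidationError(f"{path}: empty CSV")
    for col in column_map:
        if col not in df.columns:
            raise FormatError(f"{path}: mapped column {col!r} not in header")
    field_of = dict(column_map)
    for required in ("cell_id", "frame"):
        if required not in field_of.values():
            raise FormatError(f"column_map must map a column to {required!r}")
    inv = {v: k for k, v in field_of.items()}
    attr_cols = [c for c in column_map if field_of[c] not in _STRUCTURAL_FIELDS]

    records: list[CellRecord] = []
    max_frame = 0
    for cell_id, group in df.groupby(df[inv["cell_id"]].astype(str), sort=True):
        group = group.sort_values(inv["frame"])
        frames = [int(f) for f in group[inv["frame"]]]
        colony = (
            str(group[inv["colony_id"]].iloc[0]) if "colony_id" in inv else "colony_1"
        )
        mother_raw = group[inv["mother_id"]].iloc[0] if "mother_id" in inv else None
        mother = (
            None
            if mother_raw is None or (isinstance(mother_raw, float) and math.isnan(mother_raw))
            else str(mother_raw)
        )
        # split on gaps: each contiguous run becomes its own record
        runs: list[list[int]] = [[0]]
        for i in range(1, len(frames)):
            if frames[i] == frames[runs[-1][-1]] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        if len(runs) > 1:
            logger.warning(
                "cell %r has %d frame gap(s); splitting into %d records",
                cell_id,
                len(runs) - 1,
                len(runs),
            )
        for run_idx, run in enumerate(runs):
            sub = group.iloc[run]
            rec_id = cell_id if run_idx == 0 else f"{cell_id}#{run_idx + 1}"
            numeric: dict[str, list[float]] = {}
            boolean: dict[str, list[bool]] = {}
            for col in attr_cols:
                name = field_of[col]
                if sub[col].dtype == bool:
                    boolean[name] = [bool(v) for v in sub[col]]
                else:
                    numeric[name] = [float(v) for v in sub[col]]
            records.append(
                CellRecord(
                    cell_id=rec_id,
                    colony_id=colony,
                    mother_id=mother if run_idx == 0 else None,
                    frames=[frames[i] for i in run],
                    numeric_attrs=numeric,
                    boolean_attrs=boolean,
                )
            )
        max_frame = max(max_frame, frames[-1])

    cells = CellList(
        frame_period=frame_period,
        n_frames=n_frames if n_frames is not None else max_frame,
        cells=records,
        provenance=provenance,
    )
    cells.validate()
    return cells


def export_tracker_csv(cells: CellList, path, *, delimiter: str = ",") -> None:
    """Write a cell list as a long-format CSV (one row per cell instance)."""
    rows = []
    for rec in cells.cells:
        for i, frame in enumerate(rec.frames):
            row: dict[str, object] = {
                "cell_id": rec.cell_id,
                "frame": frame,
                "colony_id": rec.colony_id,
                "mother_id": rec.mother_id if rec.mother_id is not None else "NA",
            }
            for name, series in rec.numeric_attrs.items():
                row[name] = series[i]
            for name, series in rec.boolean_attrs.items():
                row[name] = series[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
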