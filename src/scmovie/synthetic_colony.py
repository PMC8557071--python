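"""Seeded agent-based simulator of growing bacterial micro-colonies.

Each colony starts from a single progenitor.  A cell born at time ``t_b``
with length ``L_b`` elongates exponentially, ``L(t) = L_b * exp(k * age)``
with its personal elongation rate ``k`` (1/hour) drawn from a
generation-indexed Gamma distribution.  It divides when it reaches its
drawn division length ``L_div`` (a "sizer" trigger, also Gamma per
generation); the two daughters receive ``L_div/2 * (1 ± eps)`` with the
asymmetry ``eps ~ Normal(0, asymmetry_sd)``.  The movie samples every
cell's length on a fixed frame grid with optional multiplicative
lognormal measurement noise.  Division characteristics can instead be
*inherited* (daughter's target copied from the mother with small
multiplicative noise), which makes close kin strongly correlated — the
regime used to study sibling/cousin correlation of division attributes.

Randomness is reproducible at the cell level: every cell's draws come
from an RNG stream derived from ``(seed, cell_id)``, so the same seed
yields byte-identical output, and corrupting a movie does not perturb the
simulation itself.

A companion tool injects tracking errors ("lost divisions") with a
ground-truth log, for testing the error-QC and repair workflow.
"""

from __future__ import annotations

import copy
import logging
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .io_cell_lists import CellList, CellRecord

logger = logging.getLogger(__name__)

MIN_PER_HOUR = 60.0


def _per_generation(spec, generation: int):
    """Resolve a per-generation parameter spec.

    ``spec`` may be a single value (used for every generation), a mapping
    generation -> value (missing generations fall back to the largest
    configured index), or a sequence indexed by generation (clamped to
    the last entry).
    """
    if isinstance(spec, dict):
        if generation in spec:
            return spec[generation]
        return spec[max(spec)]
    if isinstance(spec, (list, tuple)) and spec and isinstance(spec[0], (list, tuple)):
        return spec[min(generation, len(spec) - 1)]
    return spec


def _draw(rng, spec, generation: int) -> float:
    """Draw from a Gamma(alpha, rate beta) spec, or return a fixed scalar."""
    val = _per_generation(spec, generation)
    if isinstance(val, (int, float)):
        return float(val)
    alpha, beta = val
    return float(rng.gamma(alpha, 1.0 / beta))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated movie.

    Defaults emulate a multi-colony *S.* Typhimurium micro-colony movie:
    12 progenitors observed for 78 frames at 5 min per frame, elongation
    rates Gamma(3.026, 4.520) per hour (mean ~0.67/h) and division
    lengths Gamma(10.666, 3.474) um (mean ~3.07 um), progenitor birth
    length 1.9 um, mild division asymmetry and 2% multiplicative length
    measurement noise.
    """

    seed: int = 0
    n_progenitors: int = 12
    frame_period: float = 5.0  # minutes
    n_frames: int = 78
    #: Gamma(shape, rate) in 1/hour; scalar = fixed rate; dict maps generation.
    elongation_rate_dist: object = (3.026, 4.520)
    #: Gamma(shape, rate) in um; scalar = fixed length; dict maps generation.
    division_length_dist: object = (10.666, 3.474)
    birth_length: float = 1.9  # um, progenitors
    asymmetry_sd: float = 0.04  # fraction of half the division length
    length_noise_sd: float = 0.02  # multiplicative measurement noise
    #: lognormal sd of daughter/mother ratio for inherited division length;
    #: None draws independently from division_length_dist each generation.
    division_length_inheritance_sd: float | None = None
    #: same, for the elongation rate.
    elongation_rate_inheritance_sd: float | None = None
    #: optional synthetic expression marker: dict(gain=..., noise_sd=...,
    #: length_coupling=...) giving value = gain*generation
    #: - length_coupling*division_length + noise at every instance.
    expression_marker: dict | None = None
    max_cells: int = 50_000

    def validate(self) -> None:
        if self.n_progenitors < 1 or self.n_frames < 1:
            raise ValueError("need >= 1 progenitor and >= 1 frame")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        if self.birth_length <= 0:
            raise ValueError("birth_length must be > 0")
        div0 = _per_generation(self.division_length_dist, 0)
        if isinstance(div0, (int, float)) and math.isfinite(div0) and div0 <= self.birth_length:
            raise ValueError(
                f"fixed division length {div0} must exceed birth length {self.birth_length}"
            )


@dataclass
class GroundTruth:
    """Everything the simulator drew, keyed by cell id."""

    config: SimulationConfig
    cells: dict[str, dict] = field(default_factory=dict)
    divisions: list[tuple[str, str, str]] = field(default_factory=list)
    """(mother, daughter_a, daughter_b) division events."""
    truncated: bool = False


def _cell_rng(seed: int, cell_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(cell_id.encode())])


def simulate_movie(config: SimulationConfig) -> tuple[CellList, GroundTruth]:
    """Simulate a movie; returns the canonical cell list plus ground truth.

    The output passes all cell-list invariants and builds a clean forest
    (no motherless branches).  If ``max_cells`` is hit, the simulation is
    truncated with a warning and the flag is recorded in the truth.
    """
    config.validate()
    dt_h = config.frame_period / MIN_PER_HOUR
    horizon_h = config.n_frames * dt_h  # time just past the last frame
    truth = GroundTruth(config=config)
    records: list[CellRecord] = []

    # (cell_id, colony, mother, generation, birth_time_h, birth_length,
    #  min_first_frame, inherited division length, inherited rate)
    stack: list[tuple] = []
    for p in range(1, config.n_progenitors + 1):
        colony = f"colony_{p:02d}"
        stack.append((f"c{p:02d}", colony, None, 0, 0.0, config.birth_length, 1, None, None))

    truncated = False
    while stack:
        if len(records) >= config.max_cells:
            truncated = True
            logger.warning("max_cells=%d reached; movie truncated", config.max_cells)
            break
        cell_id, colony, mother, gen, t_birth, L_birth, min_first, inh_div, inh_rate = stack.pop()
        rng = _cell_rng(config.seed, cell_id)

        if inh_rate is not None:
            k = inh_rate * math.exp(rng.normal(0.0, config.elongation_rate_inheritance_sd))
        else:
            k = _draw(rng, config.elongation_rate_dist, gen)
        if inh_div is not None:
            L_div = inh_div * math.exp(rng.normal(0.0, config.division_length_inheritance_sd))
        else:
            L_div = _draw(rng, config.division_length_dist, gen)
        # a sizer cannot target a division length below its birth length
        if math.isfinite(L_div) and L_div <= L_birth:
            L_div = 1.05 * L_birth
        k = max(k, 1e-6)

        t_div = (
            t_birth + math.log(L_div / L_birth) / k if math.isfinite(L_div) else math.inf
        )

        # frame f samples time (f-1)*dt; the cell is observed on frames with
        # t_birth <= (f-1)*dt < t_div
        first_f = max(min_first, math.ceil(t_birth / dt_h - 1e-9) + 1)
        last_f = config.n_frames
        if math.isfinite(t_div):
            last_f = min(config.n_frames, math.floor(t_div / dt_h - 1e-9) + 1)
        if last_f < first_f:
            # whole life fell between two grid points; the track would be
            # invisible — keep one frame so lineages stay contiguous
            last_f = first_f
        if first_f > config.n_frames:
            continue  # born after the movie ended
        last_f = min(last_f, config.n_frames)

        frames = list(range(first_f, last_f + 1))
        ages_h = [(f - 1) * dt_h - t_birth for f in frames]
        lengths = [L_birth * math.exp(k * max(a, 0.0)) for a in ages_h]
        if config.length_noise_sd > 0:
            noise = rng.lognormal(0.0, config.length_noise_sd, size=len(lengths))
            lengths = [L * z for L, z in zip(lengths, noise)]

        numeric = {"length": lengths}
        if config.expression_marker is not None:
            m = config.expression_marker
            base = m.get("gain", 1.0) * gen - m.get("length_coupling", 0.0) * (
                L_div if math.isfinite(L_div) else L_birth * 2
            )
            numeric["expression"] = [
                base + rng.normal(0.0, m.get("noise_sd", 0.0)) for _ in frames
            ]

        records.append(
            CellRecord(
                cell_id=cell_id,
                colony_id=colony,
                mother_id=mother,
                frames=frames,
                numeric_attrs=numeric,
            )
        )
        truth.cells[cell_id] = {
            "colony": colony,
            "mother": mother,
            "generation": gen,
            "birth_time_h": t_birth,
            "birth_length": L_birth,
            "elongation_rate": k,
            "division_length": L_div,
            "division_time_h": t_div,
            "divided_in_movie": False,
        }

        # spawn daughters if division happens before the movie ends and the
        # mother was actually observed up to its division
        if math.isfinite(t_div) and t_div < horizon_h and last_f < config.n_frames:
            eps = rng.normal(0.0, config.asymmetry_sd)
            half = L_div / 2.0
            la, lb = half * (1.0 + eps), half * (1.0 - eps)
            ida, idb = f"{cell_id}.1", f"{cell_id}.2"
            inh_d = L_div if config.division_length_inheritance_sd is not None else None
            inh_k = k if config.elongation_rate_inheritance_sd is not None else None
            # daughters are first observed at frame last_f + 1; their birth
            # time is the division time
            stack.append((idb, colony, cell_id, gen + 1, t_div, lb, last_f + 1, inh_d, inh_k))
            stack.append((ida, colony, cell_id, gen + 1, t_div, la, last_f + 1, inh_d, inh_k))
            truth.cells[cell_id]["divided_in_movie"] = True
            truth.divisions.append((cell_id, ida, idb))

    truth.truncated = truncated
    cells = CellList(
        frame_period=config.frame_period,
        n_frames=config.n_frames,
        cells=sorted(records, key=lambda r: r.cell_id),
        provenance=f"scmovie.simulate_movie(seed={config.seed})",
    )
    cells.validate()
    return cells, truth


# ---------------------------------------------------------------------------
# corruption


@dataclass
class CorruptionLog:
    """Ground truth of injected tracking errors, for QC scoring."""

    lost_links: list[dict] = field(default_factory=list)
    """Each entry: {"daughter", "true_mother", "first_frame", "mode"}."""


def corrupt_tracking(
    cells: CellList,
    n_lost_divisions: int,
    seed: int,
    mode: str = "unlink",
) -> tuple[CellList, CorruptionLog]:
    """Inject lost-division tracking errors into a movie.

    For each of ``n_lost_divisions`` randomly sampled division events,
    one daughter's ``mother_id`` is erased, turning its subtree into a
    motherless branch.  In ``"merged"`` mode the mother's trajectory is
    additionally extended over the *other* daughter's instances (mother
    and one daughter fused into a single over-long track whose length
    drops abruptly at the missed division) and that daughter's own
    daughters become motherless too.  The returned log records the true
    links so repairs can be scored.

    The input is not modified.
    """
    if mode not in ("unlink", "merged"):
        raise ValueError(f"unknown mode {mode!r}")
    out = copy.deepcopy(cells)
    by_id = out.by_id()
    daughters: dict[str, list[str]] = {}
    for rec in out.cells:
        if rec.mother_id is not None:
            daughters.setdefault(rec.mother_id, []).append(rec.cell_id)
    divisions = sorted(m for m, d in daughters.items() if len(d) >= 2)
    if len(divisions) < n_lost_divisions:
        raise ValueError(
            f"movie has {len(divisions)} division events, cannot corrupt {n_lost_divisions}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(divisions), size=n_lost_divisions, replace=False))
    log = CorruptionLog()
    removed: set[str] = set()

    for idx in chosen:
        mother_id = divisions[idx]
        kids = sorted(daughters[mother_id])
        lost = kids[int(rng.integers(len(kids)))]
        rec = by_id[lost]
        rec.mother_id = None
        log.lost_links.append(
            {
                "daughter": lost,
                "true_mother": mother_id,
                "first_frame": rec.first_frame,
                "mode": mode,
            }
        )
        if mode == "merged":
            other = next(k for k in kids if k != lost)
            mother = by_id[mother_id]
            sib = by_id[other]
            mother.frames = mother.frames + sib.frames
            for name in mother.numeric_attrs:
                mother.numeric_attrs[name] = (
                    mother.numeric_attrs[name] + sib.numeric_attrs.get(name, [math.nan] * len(sib.frames))
                )
            for name in mother.boolean_attrs:
                mother.boolean_attrs[name] = (
                    mother.boolean_attrs[name] + sib.boolean_attrs.get(name, [False] * len(sib.frames))
                )
            removed.add(other)
            for gk in daughters.get(other, []):
                by_id[gk].mother_id = None

    out.cells = [r for r in out.cells if r.cell_id not in removed]
    out.provenance += f" + corrupt_tracking(n={n_lost_divisions}, seed={seed}, mode={mode})"
    out.validate()
    return out, log


def repair_from_log(cells: CellList, log: CorruptionLog) -> CellList:
    """Restore the true mother links recorded in a corruption log.

    Only ``"unlink"``-mode cuts are reversible from the cell list alone;
    merged tracks need branch surgery on the forest.
    """
    out = copy.deepcopy(cells)
    by_id = out.by_id()
    for entry in log.lost_links:
        if entry["mode"] != "unlink":
            raise ValueError("merged-mode corruption cannot be repaired from the log alone")
        by_id[entry["daughter"]].mother_id = entry["true_mother"]
    out.validate()
    return out
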