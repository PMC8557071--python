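"""Single-cell and population growth-model fitting.

Per cell: bacterial length (or any positive attribute) typically grows
exponentially over a lifespan, ``y = y0 * exp(k t)`` with the elongation
rate ``k`` in 1/hour.  Fits use nonlinear least squares initialized from
the log-linear regression; cells with too few time points or failed
optimizations are reported rather than silently dropped.

Per colony: cell counts over time follow the three-stage (lag /
exponential / stationary) population model of Baranyi and Roberts,

    y(t) = log10 Nmax + log10[ (-1 + e^(mu*lam) + e^(mu*t))
                / (-1 + e^(mu*t) + e^(mu*lam) * 10^(log10 Nmax - log10 N0)) ]

with y the base-10 log of the cell count, t in hours, lag time ``lam``
(hours) and maximum specific growth rate ``mu_max`` (1/hour).  As t -> 0
the curve approaches log10 N0 and as t -> infinity it saturates at
log10 Nmax.  Colonies still in exponential phase, or not growing at all,
carry no information about Nmax or mu/lambda respectively and are flagged
as failed fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lineage_forest import DivisionForest, LineageForest, instance_key, is_synthetic

logger = logging.getLogger(__name__)

MIN_PER_HOUR = 60.0


@dataclass
class GrowthFit:
    """Per-cell growth model parameters.

    ``y0`` in the attribute's units at birth; ``k`` per hour (exponential
    rate, or linear slope in units/hour); ``rmse`` in attribute units.
    """

    model: str
    y0: float
    k: float
    rmse: float
    n_points: int
    converged: bool
    cell_id: str | None = None

    def predict(self, t_hours):
        t = np.asarray(t_hours, dtype=float)
        if self.model == "exponential":
            return self.y0 * np.exp(self.k * t)
        return self.y0 + self.k * t


@dataclass
class PopulationGrowthSummary:
    """Average exponential growth curve of a population and its band."""

    y0_mean: float
    y0_var: float
    k_mean: float
    k_var: float
    n_cells: int
    failed_ids: list = field(default_factory=list)
    band: str = "variance"

    def _spread(self):
        if self.band == "variance":
            return self.y0_var, self.k_var
        return math.sqrt(self.y0_var), math.sqrt(self.k_var)

    def mean_curve(self, t_hours):
        t = np.asarray(t_hours, dtype=float)
        return self.y0_mean * np.exp(self.k_mean * t)

    def band_curves(self, t_hours):
        """Upper and lower band curves (y0_mean ± s) * exp((k_mean ± s) t)."""
        t = np.asarray(t_hours, dtype=float)
        sy, sk = self._spread()
        upper = (self.y0_mean + sy) * np.exp((self.k_mean + sk) * t)
        lower = (self.y0_mean - sy) * np.exp((self.k_mean - sk) * t)
        return upper, lower


@dataclass
class BaranyiFit:
    """Baranyi–Roberts population growth parameters for one colony."""

    log10_N0: float
    log10_Nmax: float
    lam: float
    mu_max: float
    rmse: float
    converged: bool
    colony_id: str | None = None
    reason: str = ""

    def predict(self, t_hours):
        return baranyi_curve(t_hours, self.log10_N0, self.log10_Nmax, self.lam, self.mu_max)


# ---------------------------------------------------------------------------
# per-cell fits


def fit_cell_growth(times_min, values, model: str = "exponential", cell_id=None) -> GrowthFit:
    """Fit a linear or exponential growth model to one cell trajectory.

    ``times_min`` in minutes (converted internally to hours, so rates are
    per hour).  The linear model is the closed-form least-squares line;
    the exponential model is nonlinear least squares on ``y0 * exp(k t)``
    initialized from the log-linear regression.  With fewer than 3 points
    or a failed optimization, ``converged`` is False and the cell id is
    carried on the result for reporting.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError(f"times and values have different shapes {t.shape} vs {y.shape}")
    if model not in ("linear", "exponential"):
        raise ValueError(f"unknown model {model!r}")
    n = t.size
    if n >= 2 and np.ptp(t) == 0:
        raise ValueError("all time points are equal")
    if n < 3:
        return GrowthFit(model, math.nan, math.nan, math.nan, n, False, cell_id)

    th = t / MIN_PER_HOUR
    if model == "linear":
        k, y0 = np.polyfit(th, y, 1)
        resid = y - (y0 + k * th)
        return GrowthFit("linear", float(y0), float(k), float(np.sqrt(np.mean(resid**2))), n, True, cell_id)

    if np.any(y <= 0):
        logger.warning("cell %r: nonpositive values; exponential fit failed", cell_id)
        return GrowthFit(model, math.nan, math.nan, math.nan, n, False, cell_id)
    k0, logy0 = np.polyfit(th, np.log(y), 1)

    def resid(p):
        return p[0] * np.exp(p[1] * th) - y

    try:
        sol = least_squares(
            resid,
            x0=[math.exp(logy0), k0],
            method="lm",
            max_nfev=10_000,
        )
    except Exception:
        return GrowthFit(model, math.nan, math.nan, math.nan, n, False, cell_id)
    if not sol.success:
        return GrowthFit(model, math.nan, math.nan, math.nan, n, False, cell_id)
    y0_hat, k_hat = sol.x
    rmse = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return GrowthFit(model, float(y0_hat), float(k_hat), rmse, n, True, cell_id)


def fit_forest_growth(
    flt: LineageForest,
    fdt: DivisionForest,
    attr: str = "length",
    model: str = "exponential",
) -> dict[str, GrowthFit]:
    """Fit every FDT cell's instance trajectory of ``attr``; store on the FDT.

    Fitted ``y0``, ``k`` and ``rmse`` become life attributes
    (``fit_<attr>_y0`` etc.); the ids of cells that failed to fit are
    returned on each non-converged entry.
    """
    fits: dict[str, GrowthFit] = {}
    spans = flt.cells()
    for cell_id in fdt.cell_nodes():
        nodes = [instance_key(cell_id, f) for f in spans[cell_id]]
        times = [flt.time_of_frame(n[1]) for n in nodes]
        # time is taken relative to birth so y0 is the size at birth
        times = [t - times[0] for t in times]
        values = [flt.graph.nodes[n][attr] for n in nodes]
        fit = fit_cell_growth(times, values, model=model, cell_id=cell_id)
        fits[cell_id] = fit
        fdt.graph.nodes[cell_id][f"fit_{attr}_y0"] = fit.y0
        fdt.graph.nodes[cell_id][f"fit_{attr}_k"] = fit.k
        fdt.graph.nodes[cell_id][f"fit_{attr}_rmse"] = fit.rmse
        fdt.graph.nodes[cell_id][f"fit_{attr}_converged"] = fit.converged
    n_failed = sum(1 for f in fits.values() if not f.converged)
    if n_failed:
        logger.info("%d cells failed to fit the %s model", n_failed, model)
    return fits


def population_growth_summary(fits, band: str = "variance") -> PopulationGrowthSummary:
    """Summarize converged per-cell exponential fits into the average curve.

    Means and sample variances (n-1) of ``y0`` and ``k`` over converged
    fits.  The band curves are ``(y0_mean ± s) * exp((k_mean ± s) t)``
    where ``s`` is the variance (``band="variance"``, default) or the
    standard deviation (``band="sd"``).
    """
    if band not in ("variance", "sd"):
        raise ValueError(f"band must be 'variance' or 'sd', got {band!r}")
    if isinstance(fits, dict):
        fits = list(fits.values())
    ok = [f for f in fits if f.converged]
    failed = [f.cell_id for f in fits if not f.converged]
    if len(ok) < 2:
        raise ValueError(f"need >= 2 converged fits, got {len(ok)}")
    y0 = np.array([f.y0 for f in ok])
    k = np.array([f.k for f in ok])
    return PopulationGrowthSummary(
        y0_mean=float(np.mean(y0)),
        y0_var=float(np.var(y0, ddof=1)),
        k_mean=float(np.mean(k)),
        k_var=float(np.var(k, ddof=1)),
        n_cells=len(ok),
        failed_ids=failed,
        band=band,
    )


# ---------------------------------------------------------------------------
# colony counts and the Baranyi–Roberts model


def colony_counts(flt: LineageForest) -> pd.DataFrame:
    """Cell-instance counts per frame, per colony plus whole population.

    Returns a DataFrame indexed by frame (1..n_frames) with one column
    per colony label and a ``population`` column.
    """
    frames = range(1, flt.n_frames + 1)
    counts = {cid: dict.fromkeys(frames, 0) for cid in flt.colony_ids}
    for n, data in flt.graph.nodes(data=True):
        if is_synthetic(n):
            continue
        counts.setdefault(data["colony"], dict.fromkeys(frames, 0))
        counts[data["colony"]][n[1]] += 1
    df = pd.DataFrame(counts, index=list(frames)).sort_index(axis=1)
    df.index.name = "frame"
    df["population"] = df.sum(axis=1)
    return df


def baranyi_curve(t_hours, log10_N0, log10_Nmax, lam, mu_max):
    """Baranyi–Roberts log10 cell count at time ``t_hours``."""
    t = np.asarray(t_hours, dtype=float)
    # guard exp overflow: the ratio saturates, so clip exponents
    a = np.exp(np.minimum(mu_max * lam, 500.0))
    b = np.exp(np.minimum(mu_max * t, 500.0))
    num = -1.0 + a + b
    den = -1.0 + b + a * 10.0 ** (log10_Nmax - log10_N0)
    return log10_Nmax + np.log10(num / den)


def fit_baranyi(times_hours, log10_counts, colony_id=None) -> BaranyiFit:
    """Fit the Baranyi–Roberts model to a log10 cell-count series.

    Initialization: ``log10_N0`` from the first value, ``log10_Nmax``
    from the maximum, ``mu_max`` from the steepest finite slope of the
    natural-log count series, ``lam`` from the first sustained increase.
    Non-growing series (no increase in counts) and series that never
    approach a plateau (fitted Nmax well above anything observed) are
    flagged ``converged=False`` with a reason.
    """
    t = np.asarray(times_hours, dtype=float)
    y = np.asarray(log10_counts, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and counts have different shapes")
    if t.size < 5:
        raise ValueError(f"need >= 5 time points, got {t.size}")
    if np.any(10.0**y < 1 - 1e-9):
        raise ValueError("cell counts must be >= 1")

    if np.ptp(y) < 1e-12:
        return BaranyiFit(
            float(y[0]), float(y[0]), math.nan, math.nan, 0.0, False, colony_id,
            reason="no growth: counts constant",
        )

    ln10 = math.log(10.0)
    slopes = np.diff(y) / np.diff(t)
    mu0 = float(np.nanmax(slopes)) * ln10
    if mu0 <= 0:
        return BaranyiFit(
            float(y[0]), float(y[-1]), math.nan, math.nan, 0.0, False, colony_id,
            reason="no growth: counts never increase",
        )
    rising = np.nonzero(y > y[0] + 1e-9)[0]
    lam0 = float(t[rising[0]]) if rising.size else float(t[-1] / 4)

    def resid(p):
        return baranyi_curve(t, p[0], p[1], p[2], p[3]) - y

    lo = [y.min() - 2, y.min(), 0.0, 1e-6]
    hi = [y.max() + 2, y.max() + 6, float(t[-1]) * 2 + 1, 100.0]
    x0 = np.clip([float(y[0]), float(y.max()), lam0, mu0], lo, hi)
    try:
        sol = least_squares(
            resid, x0=x0, bounds=(lo, hi), max_nfev=10_000, ftol=1e-10, xtol=1e-12
        )
    except Exception:
        return BaranyiFit(
            math.nan, math.nan, math.nan, math.nan, math.nan, False, colony_id,
            reason="optimizer failure",
        )
    n0, nmax, lam, mu = sol.x
    rmse = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    if not sol.success:
        return BaranyiFit(
            float(n0), float(nmax), float(lam), float(mu), rmse, False, colony_id,
            reason="optimizer did not converge",
        )
    # a plateau never observed: Nmax is extrapolation, not estimation
    if nmax > y.max() + 0.15:
        return BaranyiFit(
            float(n0), float(nmax), float(lam), float(mu), rmse, False, colony_id,
            reason="still in exponential phase: stationary level not reached",
        )
    return BaranyiFit(float(n0), float(nmax), float(lam), float(mu), rmse, True, colony_id)


def fit_colony_baranyi(flt: LineageForest) -> dict[str, BaranyiFit]:
    """Fit the Baranyi–Roberts model to every colony's cell-count curve."""
    counts = colony_counts(flt)
    t_hours = (counts.index.to_numpy() - 1) * flt.frame_period / MIN_PER_HOUR
    fits = {}
    for colony in counts.columns:
        series = counts[colony].to_numpy(dtype=float)
        mask = series >= 1
        if mask.sum() < 5:
            fits[colony] = BaranyiFit(
                math.nan, math.nan, math.nan, math.nan, math.nan, False, colony,
                reason="fewer than 5 frames with cells",
            )
            continue
        fits[colony] = fit_baranyi(
            t_hours[mask], np.log10(series[mask]), colony_id=colony
        )
    return fits
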