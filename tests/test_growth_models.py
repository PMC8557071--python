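import math

import numpy as np
import pytest

from scmovie import (
    SimulationConfig,
    baranyi_curve,
    build_fdt,
    build_flt,
    colony_counts,
    fit_baranyi,
    fit_cell_growth,
    population_growth_summary,
    simulate_movie,
)
from scmovie.growth_models import fit_colony_baranyi, fit_forest_growth

from conftest import binary_movie, make_cell
from scmovie import CellList


class TestCellGrowth:
    def test_constant_series_exponential(self):
        fit = fit_cell_growth([0, 10, 20, 30], [2.0] * 4, model="exponential")
        assert fit.converged
        assert fit.y0 == pytest.approx(2.0)
        assert fit.k == pytest.approx(0.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_exponential_recovery(self):
        t_h = np.linspace(0, 10, 11)
        y = 2.0 * np.exp(0.05 * t_h)
        fit = fit_cell_growth(t_h * 60.0, y, model="exponential")
        assert fit.y0 == pytest.approx(2.0, rel=1e-9)
        assert fit.k == pytest.approx(0.05, rel=1e-9)
        assert fit.rmse < 1e-12

    def test_two_points_reported_not_fitted(self):
        fit = fit_cell_growth([0, 5], [1.0, 1.2], cell_id="tiny")
        assert not fit.converged
        assert fit.cell_id == "tiny"
        assert fit.n_points == 2

    def test_linear_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        t_min = np.arange(0, 60, 5, dtype=float)
        y = 1.0 + 0.3 * t_min / 60 + rng.normal(0, 0.05, t_min.size)
        fit = fit_cell_growth(t_min, y, model="linear")
        # closed-form normal equations on hours
        th = t_min / 60.0
        A = np.column_stack([np.ones_like(th), th])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.y0 == pytest.approx(beta[0], rel=1e-12)
        assert fit.k == pytest.approx(beta[1], rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="shape"):
            fit_cell_growth([0, 1, 2], [1.0, 2.0])
        with pytest.raises(ValueError, match="time"):
            fit_cell_growth([5, 5, 5], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="model"):
            fit_cell_growth([0, 1, 2], [1, 2, 3], model="cubic")

    def test_noisy_recovery_median_error_under_2pct(self):
        # one interdivision (~1 h) sampled at 1 min, as in a simple
        # single-colony movie
        rng = np.random.default_rng(42)
        errors = []
        t_min = np.arange(0, 61, 1, dtype=float)
        for _ in range(200):
            k = rng.gamma(3.026, 1 / 4.520)
            y0 = rng.uniform(1.2, 2.5)
            y = y0 * np.exp(k * t_min / 60) * rng.lognormal(0, 0.02, t_min.size)
            fit = fit_cell_growth(t_min, y)
            errors.append(abs(fit.k - k) / k)
        assert np.median(errors) < 0.02


class TestPopulationSummary:
    def test_hand_computed_variances(self):
        from scmovie import GrowthFit

        fits = [
            GrowthFit("exponential", 1.0, 0.4, 0.0, 10, True, "a"),
            GrowthFit("exponential", 3.0, 0.6, 0.0, 10, True, "b"),
            GrowthFit("exponential", math.nan, math.nan, math.nan, 2, False, "c"),
        ]
        s = population_growth_summary(fits)
        assert s.k_mean == pytest.approx(0.5)
        assert s.k_var == pytest.approx(0.02)
        assert s.y0_mean == pytest.approx(2.0)
        assert s.y0_var == pytest.approx(2.0)
        assert s.failed_ids == ["c"]
        assert s.n_cells == 2
        upper, lower = s.band_curves([0.0, 1.0])
        assert upper[0] == pytest.approx(2.0 + 2.0)
        assert lower[1] == pytest.approx((2.0 - 2.0) * math.exp((0.5 - 0.02)))

    def test_identical_fits_collapse_band(self):
        from scmovie import GrowthFit

        fits = [GrowthFit("exponential", 2.0, 0.5, 0.0, 10, True)] * 3
        s = population_growth_summary(fits)
        t = np.linspace(0, 2, 5)
        upper, lower = s.band_curves(t)
        assert upper == pytest.approx(s.mean_curve(t))
        assert lower == pytest.approx(s.mean_curve(t))

    def test_insufficient_fits(self):
        from scmovie import GrowthFit

        with pytest.raises(ValueError):
            population_growth_summary([GrowthFit("exponential", 1, 1, 0, 5, True)])


class TestColonyCounts:
    def test_single_cell(self):
        cells = CellList(frame_period=1.0, n_frames=4, cells=[make_cell("a", range(1, 5))])
        counts = colony_counts(build_flt(cells))
        assert counts["colony_1"].tolist() == [1, 1, 1, 1]
        assert counts["population"].tolist() == [1, 1, 1, 1]

    def test_one_division(self):
        cells = CellList(
            frame_period=1.0,
            n_frames=6,
            cells=[
                make_cell("m", [1, 2, 3]),
                make_cell("d1", [4, 5, 6], mother="m"),
                make_cell("d2", [4, 5, 6], mother="m"),
            ],
        )
        counts = colony_counts(build_flt(cells))
        assert counts["colony_1"].tolist() == [1, 1, 1, 2, 2, 2]

    def test_matches_brute_force_tally(self, sim_movie):
        cells, _ = sim_movie
        counts = colony_counts(build_flt(cells))
        tally = {}
        for rec in cells.cells:
            for f in rec.frames:
                tally[f] = tally.get(f, 0) + 1
        for f in range(1, cells.n_frames + 1):
            assert counts["population"].loc[f] == tally.get(f, 0)


class TestBaranyi:
    TRUE = dict(log10_N0=0.0, log10_Nmax=3.0, lam=1.0, mu_max=2.0)

    def test_limits(self):
        assert baranyi_curve(0.0, **self.TRUE) == pytest.approx(0.0, abs=1e-9)
        assert baranyi_curve(1e6, **self.TRUE) == pytest.approx(3.0, abs=1e-9)

    def test_noiseless_recovery(self):
        t = np.arange(0, 6.01, 0.1)
        y = baranyi_curve(t, **self.TRUE)
        fit = fit_baranyi(t, y)
        assert fit.converged
        assert fit.log10_Nmax == pytest.approx(3.0, rel=1e-3)
        assert fit.lam == pytest.approx(1.0, rel=1e-3)
        assert fit.mu_max == pytest.approx(2.0, rel=1e-3)
        assert abs(fit.log10_N0) < 1e-3

    def test_constant_series_fails(self):
        fit = fit_baranyi(np.linspace(0, 5, 20), np.zeros(20))
        assert not fit.converged
        assert "no growth" in fit.reason

    def test_pure_exponential_flagged(self):
        t = np.linspace(0, 5, 30)
        fit = fit_baranyi(t, 0.5 * t)
        assert not fit.converged
        assert "exponential" in fit.reason

    def test_input_errors(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_baranyi([0, 1, 2], [0, 0.5, 1])
        with pytest.raises(ValueError, match=">= 1"):
            fit_baranyi(np.linspace(0, 5, 10), np.linspace(-1, 1, 10))

    def test_per_colony_fit_flags_non_growing(self):
        # two colonies: one saturating (division disabled late), one frozen
        cells, _ = simulate_movie(
            SimulationConfig(seed=9, n_progenitors=1, n_frames=90,
                             elongation_rate_dist=1.0, division_length_dist=(10.666, 3.474))
        )
        frozen = CellList(
            frame_period=cells.frame_period,
            n_frames=cells.n_frames,
            cells=cells.cells
            + [make_cell("solo", range(1, cells.n_frames + 1), colony="colony_99")],
        )
        fits = fit_colony_baranyi(build_flt(frozen))
        assert not fits["colony_99"].converged


def test_forest_growth_stores_life_attributes(sim_forest):
    flt, fdt = sim_forest
    fdt = fdt.copy()
    fits = fit_forest_growth(flt, fdt, attr="length")
    ok = [f for f in fits.values() if f.converged]
    assert len(ok) > 10
    cid = ok[0].cell_id
    assert fdt.graph.nodes[cid]["fit_length_k"] == pytest.approx(ok[0].k)
    # short-lived cells are reported, not dropped silently
    short = [f for f in fits.values() if f.n_points < 3]
    for f in short:
        assert not f.converged
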