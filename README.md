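# scmovie

Analytics for bacterial **single-cell movies** — time-lapse microscopy videos
of growing micro-colonies that image analysis has reduced to per-frame,
per-cell measurements. Given the cell-tracking output (who is whose
daughter, and each cell's length/area/fluorescence at every frame), the
package answers the questions a microbial single-cell study asks:

- How fast does each *individual* cell grow, and how variable is the
  population? (per-cell exponential elongation fits, y = y₀·e^{kt})
- What growth kinetics does each colony follow? (Baranyi–Roberts lag /
  exponential / stationary model fitted to log₁₀ cell counts)
- Which parametric law describes a single-cell trait — interdivision time,
  division length, elongation rate? (Normal/Gamma/Lognormal maximum
  likelihood with BIC model selection and ΔBIC evidence on Jeffreys' scale)
- Do related cells inherit their division characteristics? (sibling /
  cousin / mother–daughter correlations per generation)
- Where did the tracker go wrong, and how do I fix it? (motherless-branch
  detection, RMSE and rate-of-change outliers, explicit branch surgery)

Everything is built on two tree views of the movie: the **forest of lineage
trees** (FLT — one node per cell per frame; levels are frames) and the
**forest of division trees** (FDT — one node per cell; levels are
generations). A seeded agent-based colony simulator generates realistic
movies with known ground truth, so the entire pipeline is testable without
any imaging data, and a corruption tool injects tracking errors for QC
benchmarking.

## Worked example

```python
import numpy as np
from scmovie import (
    SimulationConfig, simulate_movie, build_flt, build_fdt,
    compute_life_attributes, population_growth_summary,
    best_fit_auto, dist_mean_sd, corrupt_tracking, list_motherless,
)
from scmovie.growth_models import fit_forest_growth

# a 4-colony movie: 78 frames at 5 min, elongation rates ~ Gamma(3.026, 4.520)/h
cells, truth = simulate_movie(SimulationConfig(seed=42, n_progenitors=4, n_frames=78))
print(len(cells.cells), sum(r.lifespan for r in cells.cells))   # 522 cells, 5708 instances

flt = build_flt(cells)                       # lineage forest, levels = frames
fdt = build_fdt(flt)                         # division forest, levels = generations
compute_life_attributes(flt, fdt)            # birth/division times, min/max/mean/sd

fits = fit_forest_growth(flt, fdt, attr="length")   # per-cell y0·e^{kt}
s = population_growth_summary(fits)
print(f"k = {s.k_mean:.3f}/h (var {s.k_var:.3f}), y0 = {s.y0_mean:.3f} um (var {s.y0_var:.3f})")
# k = 0.657/h (var 0.142), y0 = 1.407 um (var 0.150)   [426 converged, 96 too short]

ks = np.array([f.k for f in fits.values() if f.converged and f.k > 0])
sel = best_fit_auto(ks)                      # MLE + BIC over Normal/Gamma/Lognormal
print(sel.best, sel.fits[sel.best].params)   # gamma (2.966, 4.511)
print(sel.delta_bic)                         # {normal: 92.7, gamma: 0.0, lognormal: 34.4}
print(dist_mean_sd("gamma", sel.fits["gamma"].params))
# {'mean': 0.657, 'sd': 0.382, 'variance': 0.146}
```

The fitted rate distribution recovers the simulator's configured
Gamma(3.026, 4.520) from the movie alone, and the ΔBIC table says the gamma
law is decisively preferred (ΔBIC > 10) over both alternatives — the same
form of evidence one would quote for a real movie.

Tracking-error QC on the same movie:

```python
bad, log = corrupt_tracking(cells, 3, seed=7)   # erase 3 division links
flt_bad = build_flt(bad)
for rep in list_motherless(flt_bad):            # 3 orphan branches found
    print(rep.root_cell_id, rep.first_frame, rep.candidates[:3])
```

Every orphan is detected, with candidate mothers ranked by the
size-halving division signature; gluing a branch back is explicit
(`add_branch(flt, branch, target)`), and repairing every cut restores a
forest identical to the uncorrupted one.

A thin CLI mirrors the library for shell use:

```sh
scmovie simulate --seed 42 --out movie.json
scmovie corrupt --in movie.json --lost 3 --seed 7 --out bad.json --log cuts.json
scmovie qc --in bad.json --out qc_report.csv
scmovie fit-dist --in movie.json --attr division_duration --group-by generation --out dist.csv
scmovie plot-forest --in movie.json --attr generation --out forest.png
```

## Layout

| module | contents |
| --- | --- |
| `scmovie.io_cell_lists` | canonical JSON cell-list schema, validation, long-format CSV adapter |
| `scmovie.lineage_forest` | FLT/FDT construction, branch surgery, cell-life tables, GraphML export |
| `scmovie.cell_attributes` | cell age, rate of change (roc), life-attribute reduction |
| `scmovie.selection` | AND-constraint subpopulation selection, OR union, mean±k·sd outliers |
| `scmovie.growth_models` | per-cell linear/exponential fits, population band, colony counts, Baranyi–Roberts |
| `scmovie.stochasticity` | Normal/Gamma/Lognormal MLE, BIC/ΔBIC selection, dominant family |
| `scmovie.family_correlations` | kin-pair enumeration and per-generation correlation/regression |
| `scmovie.error_qc` | motherless branches, RMSE outliers, roc anomalies, lost-division flags |
| `scmovie.synthetic_colony` | seeded sizer-based colony simulator + tracking-error injection |
| `scmovie.viz` | radial forest plots, scatter + regression, violin/box/pdf overlays |

`docs/methods.md` describes the models, conventions, and numerical choices
in detail.
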