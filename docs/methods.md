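# Methods

## The data model

A bacterial single-cell movie, after segmentation and tracking, reduces to a
*cell list*: one record per tracked cell carrying its colony, its mother (if
the tracker resolved the division), a contiguous 1-based frame range, and one
measurement per frame for each attribute. Frames map to time as
t = (f − 1)·Δt with Δt the frame period in minutes, so t = 0 at movie start.

Two tree views are built from the list. The **forest of lineage trees (FLT)**
has one node per *cell instance* (a cell at a frame): a synthetic master root
(level 1) holds one synthetic root per colony (level 2), and an instance at
frame f sits at level f + 2. Edges join consecutive instances of a cell and
the last instance of a mother to the first instance of each daughter. The
**forest of division trees (FDT)** collapses each lifespan to a single node;
a generation-g cell sits at level g + 3, generations counting from 0 at the
progenitors. Generation labels count cell boundaries on the path from the
progenitor; colony labels are inherited from the progenitor so they survive
colony merges. Both forests are networkx digraphs, so subpopulation
selections — which may be disconnected — remain first-class inputs to every
downstream operation.

A cell first seen after frame 1 with no resolved mother is either a cell
entering the field of view or a tracking error. Such cells, with their whole
progeny, are kept out of the main forest in a *motherless-branch store*; the
analytics only ever see divisions that were actually observed. A stored
branch can be glued back (`add_branch`) under the instance at the preceding
frame; if the attachment target belongs to a different cell the division is
recovered, if it is the same cell a split lifespan is rejoined. Generation
and colony labels downstream of the attachment are recomputed at that point
rather than stored immutably, because surgery changes them.

## Life attributes

Each FDT node carries: birth and last-observation times (minutes), the
interdivision time, min/max/mean/sd of every numeric attribute over the
lifespan, the majority value of every boolean attribute (ties reduce to
False and are flagged — conservative for contact/boundary flags), and, once
growth fitting has run, the fitted y₀, k, and RMSE. Descriptive statistics
use the sample (n − 1) standard deviation; the distribution MLEs below use
the n denominator, as maximum likelihood requires.

The interdivision time is `lifespan_frames · Δt` by default ("inclusive"):
the division falls between the last observed frame and the next, so
back-to-back generations tile the movie without gaps. The observational
convention `(lifespan_frames − 1) · Δt` is available as "exclusive"; the
data do not disambiguate which a given tracker intends.

## Growth models

**Single cell.** Bacterial length elongates exponentially over a lifespan,
y = y₀·e^{kt}. The exponential fit is nonlinear least squares initialized
from the log-linear regression; time is converted to hours internally so k
is per hour. Cells with fewer than 3 points, or failed optimizations, are
returned as non-converged with their ids — short tracks are information
about tracking quality, not noise to discard silently. The population
summary reports means and sample variances of y₀ and k over converged fits
and the band curves (ȳ₀ ± s)·e^{(k̄ ± s)t}, where s is the *variance* by
default (a deliberate, documented choice of the band formula; `band="sd"`
gives the dimensionally conventional alternative).

**Colony.** Cell counts per frame follow the three-stage Baranyi–Roberts
model in log10 space,

    y(t) = log10 Nmax + log10[ (−1 + e^{μλ} + e^{μt})
              / (−1 + e^{μt} + e^{μλ}·10^{log10 Nmax − log10 N0}) ],

with t in hours, lag λ (hours), and maximum specific growth rate μ (1/h).
As t → 0 the curve approaches log10 N0; as t → ∞ it saturates at
log10 Nmax (both limits are unit-tested). Fitting is bounded least squares
initialized from the first value, the maximum, the steepest log-slope
(converted to natural-log units), and the first sustained increase. Two
failure modes are flagged rather than reported as parameters: a flat series
("no growth" — a colony that never divides carries no kinetic information)
and a fitted log10 Nmax more than 0.15 log10 units above anything observed
("still in exponential phase" — a plateau never seen makes Nmax pure
extrapolation). The 0.15 margin is ~1.4× in count units, large enough to
tolerate noise around a genuine plateau.

## Stochasticity characterization

Normal, Gamma, and Lognormal are fitted by maximum likelihood: normal and
lognormal in closed form; gamma by Newton iteration on the shape score
equation log α − ψ(α) = log x̄ − mean(log x) (Minka-style start, relative
tolerance 1e−10), with rate β = α/x̄. The shape–rate parameterization keeps
the mean at α/β. All three families have two free parameters, so
BIC = −2·loglik + 2·ln n, and the selected family minimizes BIC. ΔBIC
against the best model follows Jeffreys' scale (> 5 strong, > 10 decisive).
Across groups (generations, colonies), the *dominant* family is the one most
often competitive (ΔBIC ≤ 5 in the most groups), ties broken toward the
smallest mean ΔBIC — the tie-break is this package's own convention.
`dist_mean_sd` returns the mean, the standard deviation, and the variance
explicitly labeled, because summary tables in the literature sometimes print
one where the other is meant. A minimum of n = 8 samples is required for a
2-parameter MLE; this floor is a stability choice, not a statistical claim.

## Kin-pair correlations

Sibling (same mother), cousin (same grandmother, different mothers),
mother–daughter, and grandmother–granddaughter pairs are enumerated
exhaustively on the FDT; sibling pairs exist from generation 1, cousins from
generation 2. Same-generation pairs are unordered, and their Pearson r and
regression are computed on the symmetrized set (each pair contributing both
orderings) so the statistics are orientation-invariant; cross-generation
pairs are ordered and the regression is descendant-on-ancestor. Groups with
fewer than 3 pairs report NaN with their count.

## Error QC

Three report-only detectors (repair is always explicit surgery):
motherless-branch listing with candidate mothers ranked by the abruptness of
their size drop at the orphan's birth frame, by their track ending exactly
there, and by centroid proximity when available (equal weights by default —
the ranking is triage, not a decision); RMSE outliers among exponential fits,
with an "auto" threshold of mean + 2·sd of all converged RMSEs standing in
for eyeballing the RMSE histogram; and normalized rate-of-change anomalies,
|Δx/x| per frame above a percent threshold. Cells ending mid-movie with
exactly one successor are additionally flagged as suspected lost divisions.
No detector has a paper-given numeric default; thresholds are explicit
configuration.

## The colony simulator

The simulator is the package's test bed and defines its study conditions.
Each cell elongates exponentially with a personal rate k drawn from a
generation-indexed Gamma (1/h) and divides on reaching a drawn target length
(a *sizer*; the trigger mechanism is configurable ground truth, not a
biological claim). Daughters receive L_div/2·(1 ± ε), ε ~ N(0, asymmetry_sd).
Lengths are sampled on the frame grid with multiplicative lognormal
measurement noise. Every cell's draws come from an RNG stream derived from
(seed, cell_id), so output is byte-identical per seed and corruption does
not perturb the simulation. Defaults emulate a multi-colony *S.* Typhimurium
movie: 12 progenitors, 78 frames at 5 min, rates Gamma(3.026, 4.520),
division lengths Gamma(10.666, 3.474) μm, birth length 1.9 μm, asymmetry sd
0.04, measurement noise 2%.

What the simulator does *not* emulate: mechanical cell–cell interaction,
spatial packing, nutrient depletion, death, or gene circuits (the optional
"expression" marker is a linear stand-in — rising with generation,
anti-correlated with division length — so expression-style analyses are
exercisable). Passing tests therefore certify the analytics on idealized
exponential sizer growth, not on real imaging artifacts.

Two regimes beyond the defaults are used deliberately:

- **Inheritance-strong** (kin-correlation checks): daughters copy the
  mother's division length and rate with multiplicative lognormal noise
  (sd 0.10) instead of drawing fresh. This reproduces the regime where
  sibling correlations reach ~0.85–0.9 and exceed cousin correlations in
  every generation. With much smaller noise the within-generation variance
  is dominated by founder differences and sibling/cousin correlations become
  statistically indistinguishable per generation.
- **Independence null**: birth length 1.0 μm with division lengths
  Gamma(100, 32.5). Under the defaults the sizer clamp (a drawn target at or
  below the inherited birth size is raised to 1.05× birth) couples siblings
  through their shared birth size and produces r ≈ 0.1 — a real property of
  sizer division, not an estimator artifact. The null configuration keeps
  the target distribution far above the birth size so the clamp never fires
  and measured sibling correlation is sampling noise (|r| < 0.05 at 10⁴
  pairs).

The corruption tool erases one daughter's mother link per sampled division
("unlink"), optionally also fusing the mother with the other daughter's
track ("merged", the over-long-trajectory signature). The log records true
links so QC recall and repair can be scored exactly.

## Numerical choices and problem sizes

Nonlinear fits use scipy least squares (LM for the unbounded exponential
fit, trf with bounds for Baranyi), max 10⁴ evaluations, cost tolerance
1e−10. Noise-recovery checks run 200 cells of one interdivision (~60 min)
sampled at 1 min — the acquisition of a simple single-colony movie — where
the per-cell rate estimator's median relative error is ~1%; at 5-min
sampling over a single lifespan the same estimator carries ~2.4% median
error, which is a property of the information in 13 points, not of the
implementation. BIC family-recovery runs 100 replicates of n = 5000 per
family. Structural invariants run over 50 seeded small movies (2
progenitors, 45 frames). The end-to-end suite runs in well under a minute
on one CPU, the acceptance script in ~20 s.

## Known limitations

- Tracks are split, never interpolated, across frame gaps; a tracker that
  genuinely skips frames will fragment.
- `merged`-mode corruption cannot be reversed from the log alone (forest
  surgery is required), and nested merged cuts can reference an absorbed
  mother.
- The candidate-mother ranking is heuristic; precision is reported, never
  asserted.
- Exponential-phase-only count series are rejected by design; fitting
  Baranyi–Roberts to them would return an unidentifiable Nmax.
- The radial tree layout recurses over the forest; movies with tens of
  thousands of frames would need an iterative layout.
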