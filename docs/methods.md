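# Methods

This note records the models implemented in `hoptrack`, the numerical and
design choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations.  Units are seconds and µm throughout
the computation; nm and ms appear only in reports.

## Trajectory simulator (`hoptrack.simulate`)

Dynamics are integrated with Gaussian substeps of variance
`2·D_micro·δt/substeps` per coordinate, and frame positions are the substep
positions at frame boundaries plus i.i.d. Gaussian localization noise
N(0, σ²) per coordinate.  Noise is added at sampling only and never feeds
back into the dynamics — localization error is a property of the measurement,
not of the motion.

* **free / directed** — cumulative sums of the substeps; directed mode adds
  `v·t`.  Substep count is irrelevant in law.
* **confined** — reflecting walls on `[0, L_x]×[0, L_y]` are applied by exact
  path folding with period 2L per axis, which is distribution-exact for any
  substep count.  The particle starts uniformly inside the box, the
  stationary distribution, so the time-averaged MSD saturates at
  `L_x²/6 + L_y²/6`.
* **hop** — a square lattice of semipermeable barriers with spacing
  `(L_x, L_y)`.  A substep that would cross a barrier line crosses with
  probability `p_hop` and is otherwise reflected about the line (the standard
  treatment of semipermeable interfaces in random-walk form); the axes are
  independent.  An invariant enforces an RMS substep length of at most
  `min(L)/10` so that multiple barrier events per substep are negligible.

**p_hop is per crossing attempt, not per unit time.**  Because the
barrier-encounter rate of a discrete walk scales with the substep length, the
emergent macroscopic coefficient depends on the substep count: halving the
substep duration multiplies encounters by √2, so `p_hop → p_hop/√2` keeps the
physical permeability fixed (verified in the test suite).  Since experiments
constrain D_MACRO/D_micro ratios rather than microscopic crossing rates, the
module provides `calibrate_p_hop`, which bisects log p_hop against simulated
ensembles (common random numbers across iterations) until the emergent
long-lag D matches a target.

Per-trajectory RNG streams are spawned from the ensemble seed with numpy's
`SeedSequence` (PCG64), so ensembles are bitwise-reproducible from the config
alone; the scheme is echoed in the output metadata.

Default regimes mirror the study conditions the package is designed around:
frame times 20 µs (ultrafast gold-probe tracking), 0.5 ms and 33 ms
(fluorescent probes); D_micro ≈ 0.2–7 µm²/s; compartments ≈ 40–250 nm;
localization σ = 19–20 nm; track lengths 15–2500 frames.  The simulator's
default D_micro of 5 µm²/s for the 20-µs regime is a choice (the microscopic
coefficient of gold-tagged lipids is not separately constrained); it is
recorded in the output metadata, and the fitted compartment size is insensitive
to ±30% variations of it (tested).

*Not emulated*: photophysics (blinking, bleaching), localization-error
correlations, gaps and mislinking, 3D motion, anisotropic or disordered
barrier lattices, inter-compartment heterogeneity.  Passing tests therefore
validate the estimators under idealized picket-fence conditions, not the
image-processing upstream of them.

## MSD estimation (`hoptrack.msd`)

The time-averaged MSD uses all overlapping windows: for a track of P
positions, lag n averages P − n displacement pairs.  Overlapping windows are
correlated; uncertainty is therefore always quantified across trajectories,
never across lags of one curve.

`MSD(0)` (the noise floor, 4σ² for 2D curves, 2σ² per axis) is the intercept
of an ordinary least-squares line through the MSD at lags 2δt, 3δt, 4δt and
is subtracted elementwise; negative corrected values are recorded, not
clipped.  `D_2-4` is the slope of that same line divided by 4 (2 for
single-axis curves); the slope is invariant under the intercept subtraction,
so the order of the two operations is immaterial.  D_2-4 ≤ 0 flags a
noise-dominated track.

`ensemble_msd` reports per-lag means and SEs across tracks and fits a
weighted least-squares line.  Its "linearity p" is defined as the chi-square
tail probability of the residuals against the per-lag SEs — an
interpretation, since several linearity statistics are in circulation.
Because residuals of an ensemble MSD are strongly correlated across lags, the
statistic is far below its nominal degrees of freedom for truly linear data,
so free-diffusion ensembles yield p close to 1 and saturating (confined)
ensembles reject the line sharply; the test suite calibrates both directions.

## Mode classification (`hoptrack.classify`)

`RD(N, n) = MSD(nδt)/(4·D_2-4·n·δt)` is computed once per track from its
leading N frames (fixed-(N, n) thresholds are only valid at fixed track
length).  The null is 10,000 noise-free simulated Brownian tracks — RD is
scale-free, so the diffusion coefficient used is immaterial (tested) — passed
through the *identical* correction pipeline as experimental curves, so the
2.5/97.5 percentile thresholds calibrate exactly the statistic being scored.
Default scales: (N=160, n=40, δt=0.5 ms) for fast fluorescence data;
n·δt ≈ 1 s for 33-ms data; (N=300, n=75, δt=20 µs) for ultrafast data; all
configurable.

Tracks are pre-filtered for mobility: immobile iff the corrected MSD at the
classification lag does not exceed k× the noise floor (k = 2 by default, a
configurable interpretation — the original immobile criterion is not fully
specified in the source literature) or D_2-4 ≤ 0.

## Hop-diffusion model and fitting (`hoptrack.hopfit`)

The confined model is the exact eigenfunction series for reflecting-wall 1D
diffusion from a uniform start, truncated adaptively to <10⁻⁶ relative error:
`MSD(t) = L²/6 − (16L²/π⁴)·Σ_{k odd} k⁻⁴ exp(−(kπ/L)²·D·t)`.

For hop diffusion we initially implemented the transient-plus-linear
composite (confined transient scaled to amplitude `(1−D_MACRO/D_micro)·L²/6`
plus `2·D_MACRO·t`), but it deviates from the hop-mode simulator by 6–17% at
mid-transient for moderate permeabilities — too coarse for quantitative
fitting.  The shipped `hop_msd_model` is instead the **exact** continuum
solution for 1D diffusion through an infinite periodic array of semipermeable
barriers: the Laplace transform of the MSD is derived in closed form by
summing barrier fluxes of the point-source Green's function (the
semipermeable-barrier jump conditions give a unit-determinant transfer matrix
whose decaying eigenvalue acts as the lattice impedance; the average over a
uniform start position is elementary) and inverted numerically on a
fixed-Talbot contour (M = 24 nodes; inversion error ~10⁻¹⁰, verified against
the confined and free limits).  The user-facing parameters (L, D_micro,
D_MACRO) map to the barrier permeability through the series-resistance
relation `1/D_MACRO = 1/D_micro + 1/(κL)`.  All hyperbolics are scaled by
`e^(−qL)`, so the expression is overflow-free.  Against the hop-mode
simulator the model agrees to within ~3% (relative) across L ∈ {40, 85, 230}
nm × p_hop ∈ {0.01, 0.05, 0.2} when the emergent D_MACRO is supplied;
residual excursions toward 5% trace to Monte-Carlo error of the
emergent-slope estimate, not to the model shape.

`fit_hop` fits each axis independently over the first 300 lags (configurable)
by weighted nonlinear least squares:

* **Weights** — per-lag SD taken as ∝ √(n/n_pairs), the leading-order scaling
  of the variance of a time-averaged MSD.  Weighting by 1/√n_pairs alone lets
  the long linear segment dominate and washes out the confinement transient
  (median size errors of tens of percent in the small-compartment regime).
* **Initialization** — D_micro from max(D_2-4, lag-1 secant): D_2-4 is biased
  far below D_micro when the compartment equilibrates within a few frames.
  D_MACRO/D_micro from the tail slope; L from the tail intercept.
* **Parameterization and bounds** — (L, D_micro, f = D_MACRO/D_micro) with
  f ∈ [10⁻⁶, 1], which enforces D_MACRO ≤ D_micro as a box constraint;
  L ∈ [2σ_loc, 10×√(max MSD)]; D_micro within ×/÷20 of its initializer.
* **Convergence flags** — fits with f ≥ 0.9 are reported "no resolvable
  compartment" (free-like), and boundary-pinned L is flagged; non-converged
  tracks carry NaNs and are excluded from size distributions.

The per-axis noise floors (2σ² each) are estimated by the same lag-2..4
intercept method before fitting.  Reported per track: L_x, L_y, the
compartment size √(L_x·L_y) (geometric mean), D_micro and D_MACRO (means of
the per-axis coefficients), and the residency time
`(compartment size)²/(4·D_MACRO)`.

Known bias: with 19-nm localization noise the per-axis noise floor (7.2×10⁻⁴
µm²) is comparable to the transient amplitude of sub-60-nm compartments
(L²/6 ≈ 5.6×10⁻⁴ µm² at 58 nm), and the intercept estimator absorbs part of
a fast transient; median recovery stays within ~10% for 2500-frame tracks
but degrades for much shorter ones (single tracks then contain only a
handful of hops).

## Transient-confinement detection (`hoptrack.confinement`)

For each sliding window the maximal displacement R from the window's first
point is measured (floored at the localization σ to keep the index finite for
pinned particles), the staying probability of a free Brownian reference
particle is evaluated with the log-linear approximation
`log₁₀ψ = 0.2048 − 2.5117·D_ref·t/R²`, and the index is the positive part of
`−log₁₀ψ − 1`.  Maximal supra-threshold runs lasting at least a minimum
duration become confinement segments.

Defaults (window 16 frames, threshold 2.0, minimum duration 4 ms at
δt = 0.5 ms) were calibrated on the simulator: free-diffusion ensembles at a
matched D_ref give a per-track false-positive segment rate ≲1% (bound ≤5% in
the tests), while 20-ms traps in 85-nm zones are detected with ≈90%
sensitivity and detection power increases monotonically with trap duration.
Only this escape-probability detector is implemented; entrapment detectors
that model immobilization photophysics are out of scope.

## Pipeline and statistics (`hoptrack.pipeline`, `hoptrack.io`, `hoptrack.cli`)

Trajectories travel as CSV (`track_id,frame,t_s,x_um,y_um`; 0-based
consecutive frames, uniform δt, no gaps) with a JSON sidecar echoing the
generating config; malformed files are rejected with line-numbered errors.
Group summaries report median and mean ± SE of D_2-4 over mobile tracks, the
simple-Brownian fraction over classified tracks, and hop-fit medians
(compartment size, D_MACRO, residency time) over converged fits; every
summary number is recomputable from the stage CSVs.  Group comparisons use
the two-sided tie-corrected Mann–Whitney U test, reported per comparison
without multiple-testing adjustment (matching standard practice for these
tables); null p-values are verified uniform.  The full bundle is a pure
function of (inputs, config, seed).  Unknown configuration keys abort before
execution.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale, chosen so each
statistical assertion has a comfortable margin at 3-SE tolerances: RD-null
calibration uses the full 10,000 + 10,000 tracks; free-diffusion D recovery
300 tracks × 160 frames; compartment-size recovery 100 tracks of 2500 frames
(script) or 1000 frames (test suite) at 20 µs; model-vs-simulator grids use
384–512 tracks per point.  Calibration of p_hop uses 96-track ensembles of
800 frames per bisection step.

## Limitations

* The picket-fence simulator is the package's ground truth; agreement with it
  does not certify behavior on real image-derived tracks with gaps,
  mislinking or non-Gaussian localization errors.
* The hop model is one-dimensional per axis and assumes equally spaced,
  equally permeable barriers; disordered meshes broaden the fitted size
  distribution in ways the model does not capture.
* RD classification uses a single (N, n) scale per run; molecules switching
  modes within a track are out of scope (no per-segment classification).
* D_2-4 on 33-ms data reports an *effective* macroscopic coefficient; the
  package does not attempt to deconvolve intra-compartment motion at that
  resolution.
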