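# hoptrack

Single-particle-tracking analysis for diffusion in compartmentalized cell
membranes: time-averaged MSD with localization-noise correction, statistical
diffusion-mode classification against a Monte Carlo null, hop-diffusion
fitting of membrane-compartment size and residency time, transient-confinement
detection, and a picket-fence trajectory simulator that makes every stage
verifiable at desk scale.

## The scientific problem

The plasma membrane is partitioned by the actin-based membrane skeleton
("fence") and its anchored transmembrane proteins ("pickets") into
compartments tens to hundreds of nanometers across.  Lipids and proteins
diffuse rapidly *within* a compartment (D_micro) but only occasionally hop
across a boundary, so their long-term diffusion coefficient (D_MACRO) is much
smaller.  At video-rate time resolution this hop diffusion is invisible and
trajectories look like simple Brownian motion with an effective coefficient;
only microsecond-scale tracking resolves the compartments.  `hoptrack`
implements the trajectory-analysis toolchain used to quantify this picture
from 2D single-molecule tracks.

For a track of P positions sampled at frame time δt, the time-averaged MSD at
lag n uses all P − n overlapping displacement pairs:

    MSD(nδt) = ⟨ [x(jδt+nδt) − x(jδt)]² + [y(jδt+nδt) − y(jδt)]² ⟩_j

Localization noise adds a constant offset MSD(0) = 4σ², estimated as the
intercept of a line through MSD(2δt..4δt) and subtracted.  The slope of that
same line gives the short-term coefficient D_2-4 = slope/4.  Each mobile
track is scored by the relative deviation

    RD(N, n) = MSD(nδt) / (4 · D_2-4 · n · δt)

which is ≈1 for simple Brownian motion.  Thresholds RD_min / RD_MAX are the
2.5th / 97.5th percentiles of RD over 10,000 simulated Brownian tracks of the
same (N, n, δt), so 95% of ideal Brownian tracks classify as simple; tracks
below RD_min are *suppressed* (confined/hop), above RD_MAX *directed*.

Per-axis MSD curves of ultrafast tracks are fitted with the exact MSD of 1D
diffusion through an infinite array of semipermeable barriers (spacing L,
permeability κ, with D_MACRO = D_micro·κL/(κL + D_micro)), yielding the
compartment size √(L_x·L_y), D_micro and D_MACRO, and the mean residency time
per compartment

    τ = (compartment size)² / (4 · D_MACRO).

A sliding-window escape-probability index (the Simson-type detector) flags
transient confinement zones in otherwise free trajectories.

## Worked example

Simulate a "blebbed membrane" condition (free diffusion, D = 6.4 µm²/s) and
an "intact membrane" condition (hop diffusion over 300-nm compartments with a
0.5% crossing probability), classify both at the fast-fluorescence scale
(N = 160 frames, n = 40, δt = 0.5 ms), and compare:

```sh
hoptrack report --config pipeline.yaml --seed 1 --out run
```

with `pipeline.yaml`:

```yaml
groups:
  blebbed: {mode: free, D_micro: 6.4, delta_t: 5.0e-4, n_frames: 160,
            substeps: 1, loc_sigma: 0.02, n_traj: 60}
  intact:  {mode: hop, D_micro: 5.0, compartment: [0.3, 0.3], p_hop: 0.005,
            delta_t: 5.0e-4, n_frames: 160, substeps: 16, loc_sigma: 0.02,
            n_traj: 60}
analysis: {N: 160, n: 40, delta_t: 5.0e-4, null_sims: 10000}
comparisons: [[intact, blebbed]]
```

`run/summary.json` then contains (abridged):

```json
"blebbed": {"fraction_simple": 0.983333, "D24_mean_um2_s": 6.55636,
            "D24_median_um2_s": 6.49042, "D24_se_um2_s": 0.174115},
"intact":  {"fraction_simple": 0.206897, "D24_mean_um2_s": 1.8192},
"comparisons": {"intact_vs_blebbed": 7.69221e-21}
```

Reading: the free ensemble is recovered almost entirely as simple Brownian
(98%) with mean D_2-4 ≈ 6.56 ± 0.17 µm²/s, consistent with the generating
6.4 µm²/s; the hop ensemble is mostly classified suppressed (only 21%
simple), its apparent short-term coefficient is pulled far below D_micro by
the barriers, and the Mann–Whitney test separates the two conditions at
p ≈ 8×10⁻²¹.  Alongside the summary the bundle holds per-track MSD,
classification and (when enabled) hop-fit and confinement CSVs, the RD-null
thresholds, and a log with versions and seeds.

The same stages are available as a library (`simulate_ensemble`,
`compute_msd`, `build_rd_null`, `classify_tracks`, `fit_hop`,
`confinement_index`, ...) and as `hoptrack simulate` / `analyze` / `report`.

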