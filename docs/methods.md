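# Methods

This note documents the models and numerical procedures implemented in
`spherokin`, the assumptions behind them, and what the synthetic data used in
the test suite does and does not establish about real microscopy data.

## Quantification pipeline

### Projected-area segmentation (`spherokin.imaging`)

Each frame of a single-channel nuclear-fluorescence stack is processed
independently:

1. **Background subtraction.** The estimated mean background intensity is
   subtracted and the result clipped at zero. Default estimator: the global
   frame mean, which approximates the background mean while the background
   dominates the field of view; a border-band mean (band width 5% of the
   short image side) is available for frames where the object covers much of
   the field.
2. **Gaussian blur.** The frame is convolved with a Gaussian of radius
   `blur_radius_px` (default 45 px; sigma = radius/3, reflecting the common
   three-sigma support convention). The blur merges the individual nuclei
   into one connected aggregate region — it is the step that makes the
   projected *aggregate* area, not the summed nuclear area, the measured
   quantity. At 10x sampling, radii of 35–60 px are appropriate.
3. **Binarisation.** Otsu's automatic threshold on the blurred frame. The
   method is pluggable; Otsu is the default because it needs no per-dataset
   tuning and is offset-invariant in combination with step 1.
4. **Hole filling**, then optional **small-object removal**
   (`min_object_px`).
5. **Area.** Foreground pixel count × `pixel_size_um`². The pixel size is
   user input; when unknown, areas are in px² (normalisation cancels units).

**Empty-frame guard.** Otsu always produces a threshold, even on an
object-free frame, where it would split the residual noise ripple and report
roughly half the frame as foreground. A frame is therefore declared empty
unless the threshold exceeds the blurred frame's median by `min_snr`
(default 5) robust standard deviations (MAD × 1.4826). Empty frames are
flagged *missing*, not recorded as zero area, so the gap-repair rule below
applies to them.

Accuracy contract, verified on rendered fixtures with exact ground-truth
masks: measured area within 10% of truth across blur radii 35–60 px at the
default rendering contrast (signal 200, background 20, noise sd 3). In
practice the bias is a small dilation (+1–4% for an object filling ~20% of
the field) growing with blur radius relative to object size.

### Trajectory repair and normalisation (`spherokin.dynamics`)

Wells lose frames when the spheroid drifts out of the field or segmentation
finds nothing. Gaps of at most 3 consecutive missing frames are filled by a
local polynomial (default cubic) fitted through up to 4 non-missing frames
on each side; gaps of 4 or more disqualify the well with an explicit
rejection status. Boundary gaps have support on one side only, so they are
extrapolations; these are kept linear — a cubic through exactly four noisy
flanking points interpolates the noise and can ring violently. Interior fits
are least-squares over up to 8 points, centred in time for conditioning.
Interpolation is exact (zero residual) when the underlying data are
polynomial of degree ≤ the fit degree.

The normalised area is NA(t) = A(t)/A(0); frame 0 must be present (it is
never dropped by the synthetic generator either). Cohorts are summarised per
frame as mean ± SEM (sd/√n, ddof = 1); a single-replicate frame reports
SEM 0 with a warning rather than NaN.

### Shrinkage rate and phase detection

The shrinkage rate is the backward difference
`rate[i] = NA[i] − NA[i+1]`, i.e. ΔNA/Δt with Δt expressed in frame units
(per 30-min interval). The sign convention makes contraction positive and
growth negative. This unit matters: the canonical aggregation→compaction
threshold 0.008 is only meaningful on the 30-min grid, so `shrinkage_rate`
keeps the per-interval scale and stores the grid spacing alongside.

Phase detection scans for the earliest run of at least
ceil(persistence/interval) = 3 consecutive intervals with rate strictly
below the threshold (0.008 for compaction, 0 for growth; both sustained
≥ 1.5 h by default). The reported transition time is the **left edge of the
first qualifying interval** — equivalently the right-edge timestamp of the
last above-threshold interval; on a trajectory whose rate drops below
threshold after 37 fast intervals the transition is reported at 18.5 h.
Detection operates by default on the cohort mean curve (per-well annotation
is available by applying it to a single trajectory). If the rate goes
straight from fast decay to negative, both transitions are reported at the
same time; the annotation allows that degenerate equality.

### Condition-vs-control testing

Per tested time point, a two-sided Wilcoxon rank-sum test compares the NA
values of the two cohorts; the exact null distribution is used when
min(n, m) ≤ 25 and the pooled sample is tie-free (exactness verified against
full enumeration in the tests), otherwise the normal approximation with tie
correction. All-tied degenerate samples give p = 1 with a warning. The Holm
step-down correction is applied across the tested time points of one
condition-vs-control contrast (e.g. 6, 12, 24, 36, 48 h, 7 d), and stars
follow p < 0.05 (*), < 0.01 (**), < 0.001 (***), on the adjusted values.

## Agent-based model (`spherokin.abm`)

### Mechanics

50 cells (default) are hard spheres of radius 10 µm in a concave well. Per
time step (dt = 1 min):

1. **Brownian motion.** Each connected cluster (single cells included)
   receives an isotropic Gaussian displacement with diffusion coefficient
   D·m^(−1/3), where D = kT/(6πηr) is the Stokes–Einstein value
   (≈ 1.36 µm²/min at 310 K, η = 1 mPa·s, r = 10 µm) and m the cluster
   size; members translate rigidly (no rotational diffusion).
2. **Sedimentation.** Clusters fall at the Stokes terminal velocity
   v·m^(2/3) with v = 2Δρgr²/(9η); the excess density Δρ (mg/ml ≡ kg/m³) is
   the model's *buoyancy* parameter (≈ 13 µm/min per mg/ml at these
   defaults). The m^(2/3) scaling is buoyant force ∝ m over drag ∝ m^(1/3).
3. **Bond springs.** Each bonded pair relaxes toward centre distance 2r by
   an overdamped spring step (gain 0.2 per step, split symmetrically).
4. **Excluded volume.** Overlapping pairs are pushed apart symmetrically to
   contact distance (one sweep per step).
5. **Walls and floor.** The floor is a spherical cap of curvature radius
   20 mm; the side wall a cylinder of radius 400 µm. Violations are resolved
   by one Newton projection along the local surface normal. On the curved
   floor this projection has an inward horizontal component, so a
   sedimenting cell slides downhill — the centre-ward funnelling by which a
   non-adhesive concave well collects cells.
6. **Binding/unbinding.** Every unbound pair within 1.05 × 2r binds with
   probability `p_bind`; every bond existing before this sub-step breaks
   with probability `p_unbind`. Bonds have unlimited valence and events are
   independent Bernoulli draws per pair, so the evaluation order is
   immaterial and the draws are vectorised. Probabilities are per step at
   dt = 1 min; changing dt rescales them as 1 − (1 − p)^(dt′/dt).

Cell number is conserved; there is no division, death, volume change or
active motility in the model. The readout is the area of the convex hull of
the cell **centres** projected to the x-y plane (no inflation by the cell
radius — normalisation cancels most of the offset), divided by its frame-0
value, recorded every 30 simulated minutes (97 frames ≙ 48 h).

### Geometry and time scales

Cells start uniformly dispersed (non-overlapping, dart-throwing placement)
within 330 µm of the axis, up to 120 µm above the floor. Vertical settling
completes within minutes; the slow process is the downhill drift along the
gently curved floor, with time constant ≈ R_floor/v. The 20 mm curvature
radius — a shallow cast-agarose concavity, nearly flat near its centre —
puts that constant at roughly 3/6/12 h for excess densities 4/2/1 mg/ml,
matching the hours-scale aggregation phases observed across cell lines;
strongly curved floors collapse the hull within an hour, which no cell line
shows. Against this drift, diffusion maintains a spread of
σ ≈ √(D·R/v) ≈ 20 µm for unbound cells, which is what gives the binding
parameters their leverage on the late curve: strongly bonded piles are
compacted by the springs, fragile ones (high `p_unbind`) stay measurably
looser, and binding *en route* creates clusters that funnel faster
(v ∝ m^(2/3)), steepening the mid-curve.

Degenerate hull projections (fewer than 3 distinct non-collinear points)
yield area 0 with a warning; a degenerate frame 0 is an error. Hull areas
are verified in the tests against an O(n³) edge-enumeration oracle.

## Parameter estimation (`spherokin.fitting`)

With the buoyancy fixed beforehand (see below), the binding probability is
scanned over [0.05, 1.0] and the unbinding probability over [0.01, 0.2] —
by default 10 × 10 evenly spaced values, the only factorisation consistent
with 25 replicates per combination and 2500 runs in total. Every individual
run is scored against the observed NA series by the least-squares Akaike
information criterion

    AIC = n ln(RSS/n) + 2k,  RSS = Σ_t (NA_sim(t) − NA_obs(t))²,  k = 2,

with n the number of compared frames (simulations are linearly resampled
onto the observation times when the grids differ; observed frames beyond
the simulated horizon are dropped with a warning; RSS = 0 maps to
AIC = −∞ so a perfect fit sorts first). The buoyancy is excluded from k
because it is fixed before the scan. At fixed k and n the AIC ranking
equals the RSS ranking — asserted in the tests.

The estimate is the mean ± sd (ddof = 1) of the parameter values of the 25
lowest-AIC runs **pooled across the whole grid** (not per-cell averaging):
because single stochastic runs are scored, the ensemble typically spans
neighbouring grid cells, and its spread is the reported uncertainty. Run
seeds derive from (base_seed, combo_index, rep_index) through a SplitMix-
style seed sequence, so any single run is reproducible in isolation.
Simulation failures are excluded with a count; above 10% the scan aborts.

`fit_buoyancy` fixes the buoyancy first: one (typically reduced) scan per
candidate excess density, choosing the candidate whose best ensemble has the
lowest mean AIC, ties broken toward the smaller value.

The statsmodels-style surface wraps this engine:
`SpheroidFormationModel(observed, …).fit()` returns `SpheroidFitResults`
with `params`, `bse`, the full score table, `summary()` and an overlay
`plot()`.

## Synthetic data (`spherokin.synthetic`)

The generator defines the conditions under which everything above is
tested.

* **Trajectories** are piecewise-linear in NA: decrement
  `decay_rate_fast` per 30-min frame during aggregation, `decay_rate_slow`
  during compaction, and an optional linear increase `growth_rate` from a
  growth-onset frame; 97 frames ≙ 48 h. Linearity is deliberate — the phase
  detector's outputs are then exactly computable, and the calibration
  constants can be recovered by bisection. Gaussian noise (sd `noise_sd`)
  and a sinusoidal fluctuation (amplitude `fluctuation_amplitude`, period
  6 h, random phase per well) are added from frame 1 on; frame 0 is the
  exact anchor 1.0. The random phase reflects that well-to-well area
  fluctuations are asynchronous; with a common phase they would survive
  cohort averaging and masquerade as growth. Ready-made presets emulate the
  three characterised mammary lines: aggregation completing at 18.5 h with
  steady compaction (HC11-like), at 12 h with growth from 24 h (4T1-like),
  and slow aggregation completing at 29.5 h (T47D-like); noise sd 0.01 and
  fluctuation amplitude 0.015 (zero for the T47D-like preset, which shows
  none).
* **Cohorts** draw independent replicates via per-replicate seed streams
  spawned from (seed, replicate); condition effects scale the decay/growth
  rates and fluctuation amplitude multiplicatively, emulating drug-like
  perturbations. Frames other than frame 0 drop out independently with a
  configurable rate (missing, not deleted, so the repair rule is
  exercised).
* **Image stacks** render agent x-y positions as hard disks (radius
  `nucleus_radius_px`, signal 200) on a noisy background (level 20, sd 3),
  with the exact union-of-disks mask returned as ground truth; a
  Gaussian-spot option exists but the disk default keeps ground truth
  exact. Out-of-bounds centres raise an error naming the frame.

**What passing tests show — and not.** Synthetic stacks contain no PSF,
bleaching, illumination gradients, debris or transmitted-light structure,
and synthetic trajectories have stationary Gaussian noise; segmentation
accuracy and phase-detection results on them bound algorithmic error only.
On real data the blur radius, background mode and `min_object_px` need
per-setup adjustment, and the 0.008 threshold is an empirical convention
tied to the 30-min grid, treated here as a tunable with that default.

## Numerical and testing choices

* Determinism: every stochastic component takes an integer seed through
  NumPy `SeedSequence`; identical seeds give bit-identical trajectories,
  stacks, traces and scan ensembles. Trace CSVs round-trip losslessly
  (17-significant-digit output, correctly rounded parse).
* Problem sizes in the test suite are scaled to keep the full run at
  minutes, as the package's own test-design choice: the scan-structure test
  runs the full 2500-run protocol with 10 agents and 20 frames; parameter
  recovery uses a 5 × 5 grid × 10 replicates with 10 agents against a
  5-run mean observation, recovering grid-interior truth within one grid
  step; trend tests compare medians across ≥ 9 seeds at 24 h horizons.
* Known limitations: no rotational diffusion or cluster-shape hydrodynamics
  in the ABM; single-sweep overlap resolution can leave transient small
  overlaps in dense piles; the hull of centres underestimates the visual
  aggregate area by roughly one cell radius of margin (cancelled by
  normalisation except at extreme compaction); Otsu binarisation assumes a
  roughly bimodal blurred histogram and can dilate faint objects.
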