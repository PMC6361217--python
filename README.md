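# spherokin

Quantification and modelling of **spheroid formation kinetics** from
time-lapse fluorescence microscopy.

When single cells are seeded in a non-adhesive, concave well (liquid-overlay
culture), they aggregate into a spheroid in three successive phases —
**aggregation** (fast contraction of the occupied area), **compaction**
(slow contraction) and, for proliferative lines, **growth** (late
re-expansion). The standard readout is the *projected area* A(t) occupied by
the cells, normalised to its value at seeding, NA(t) = A(t)/A(0), sampled
every 30 min over 48 h.

`spherokin` implements the full analysis chain for labs running such assays:

* **Segmentation** (`spherokin.imaging`) — background subtraction, heavy
  Gaussian blur (radius 35–60 px at 10x), Otsu binarisation, hole filling
  and pixel counting turn each frame of a nuclear-fluorescence stack into a
  projected area; empty frames are flagged missing.
* **Dynamics** (`spherokin.dynamics`) — polynomial repair of short
  missing-frame gaps (wells with ≥ 4 consecutive missing frames are
  rejected), normalisation, cohort mean ± SEM, the shrinkage rate
  ΔNA/Δt, and phase detection: aggregation ends when the shrinkage rate
  stays below 0.008 per 30-min interval for ≥ 1.5 h, growth starts when it
  stays below 0 for ≥ 1.5 h. Conditions are compared against control with
  Wilcoxon rank-sum tests, Holm-corrected across time points.
* **Agent-based model** (`spherokin.abm`) — 50 Brownian hard-sphere cells
  sediment in a concave well (Stokes–Einstein diffusion, Stokes terminal
  velocity with excess density Δρ as the *buoyancy* parameter), bind on
  contact with probability `p_bind` per pair per minute and unbind with
  probability `p_unbind` per bond per minute; the model's NA is the convex
  hull of the projected cell centres, normalised to frame 0.
* **Inference** (`spherokin.fitting`) — a 10 × 10 grid scan over
  p_bind ∈ [0.05, 1.0] × p_unbind ∈ [0.01, 0.2] with 25 simulations per
  combination (2500 runs), each run scored against the observation by
  AIC = n·ln(RSS/n) + 2k; the 25 best runs form the ensemble whose
  parameter mean ± sd is the estimate. Buoyancy is fixed beforehand by a
  coarse candidate scan.
* **Synthetic data** (`spherokin.synthetic`) — three-phase piecewise-linear
  trajectory presets (including cell-line-like shapes), replicate cohorts
  with drug-like effects and frame drop-out, and rendered nuclei stacks
  with exact ground-truth masks, so the whole pipeline runs and is tested
  without any external data.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Generate a 4T1-like synthetic cohort (fast aggregation, growth from 24 h),
repair drop-out, summarise and detect phases:

```python
import numpy as np
from spherokin import (CELL_LINE_PRESETS, make_cohort, interpolate_missing,
                       normalize, cohort_summary, shrinkage_rate, detect_phases)

cohort = make_cohort(CELL_LINE_PRESETS["4T1"], n_replicates=40, seed=1,
                     missing_frame_rate=0.02)
normalized = [normalize(interpolate_missing(t)) for t in cohort]
summary = cohort_summary(normalized)
print(summary.iloc[[0, 12, 24, 48, 96]].to_string(index=False))

rates = shrinkage_rate(summary["mean_na"].to_numpy(),
                       times_h=summary["time_h"].to_numpy())
phases = detect_phases(rates)
print("aggregation ends:", phases.aggregation_end_h, "h;",
      "growth starts:", phases.growth_start_h, "h")
```

```
 time_h  mean_na   sem_na  n
    0.0 1.000000 0.000000 40
    6.0 0.606107 0.002068 40
   12.0 0.207452 0.002535 40
   24.0 0.157470 0.002482 40
   48.0 0.349654 0.002025 40
aggregation ends: 12.0 h; growth starts: 24.0 h
```

The cohort mean contracts to ~21% of the seeded area within 12 h
(aggregation), keeps compacting until 24 h, then re-expands (growth) — and
the detector reads off exactly the transition times the preset encodes.

Fit the agent-based model to an observed NA curve (here a reduced scan —
5 × 5 grid, 10 replicates, 10 agents — against a synthetic observation
generated at p_bind = 0.525, p_unbind = 0.105):

```python
from spherokin import SimulationConfig, ScanConfig, SpheroidFormationModel, run

obs = np.mean([run(SimulationConfig(n_cells=10, p_bind=0.525, p_unbind=0.105,
                                    seed=900 + s)).na for s in range(5)], axis=0)
scan = ScanConfig(bind_grid=np.linspace(0.05, 1.0, 5),
                  unbind_grid=np.linspace(0.01, 0.2, 5),
                  reps_per_combo=10, best_k=25, base_seed=7)
model = SpheroidFormationModel(obs, sim_config=SimulationConfig(n_cells=10),
                               scan_config=scan)
print(model.fit().summary())
```

```
Spheroid formation model — grid-scan fit
========================================================
observed frames:        97
agents per simulation:  10
buoyancy (fixed):       2 mg/ml
grid:                   5 x 5, 10 reps (250 runs)
best ensemble size:     25
excluded failures:      0
--------------------------------------------------------
parameter         mean        sd
p_bind          0.7150    0.2827
p_unbind        0.1069    0.0678
--------------------------------------------------------
best AIC: -868.641
```

Both generating parameters are recovered within one grid step (0.24 for
p_bind, 0.048 for p_unbind); the ensemble sd reflects how flat the fit
landscape is in each direction — binding saturates above ~0.5, so its
ensemble spreads wider than the unbinding one.

A thin CLI mirrors the stages:

```bash
spherokin synth    --preset 4T1 --replicates 40 --seed 1 --out cohort.csv
spherokin segment  --input stack.tiff --blur-radius 45 --pixel-size 1.29 --out traj.csv
spherokin analyze  --trajectories cohort.csv --out results/4t1
spherokin simulate --p-bind 0.5 --p-unbind 0.05 --buoyancy 2 --seed 7 --out trace/
spherokin fit      --observed results/4t1_summary.csv --buoyancy 2 --out fit
```

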