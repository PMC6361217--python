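"""Synthetic inputs for the whole pipeline.

Spheroid formation in non-adhesive (liquid-overlay) wells shows a
characteristic three-phase normalised-area curve: a fast decay while single
cells aggregate, a slower decay while the aggregate compacts, and — in
fast-growing lines — a late increase once proliferation dominates. The
generator here produces

* parametric normalised-area trajectories with exactly that piecewise-linear
  structure plus Gaussian noise and optional sinusoidal fluctuations
  (fragile-contact lines show strong area fluctuations),
* cohorts of replicate wells with condition effects (scaled decay/growth
  rates, extra fluctuation) and random frame drop-out, and
* rendered time-lapse image stacks of bright nuclei on a dim noisy
  background, with exact ground-truth foreground masks for testing the
  segmentation stage.

Piecewise-LINEAR segments are used deliberately: they make the phase
detector's breakpoints analytically computable, so detector behaviour can be
verified exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging import ImageStack
from .trajectories import AreaTrajectory

__all__ = [
    "TrajectoryPreset",
    "CohortEffect",
    "SceneConfig",
    "make_trajectory",
    "noiseless_curve",
    "make_cohort",
    "render_stack",
    "load_preset",
    "save_preset",
    "CELL_LINE_PRESETS",
]

#: Clip floor keeping synthetic areas strictly positive after noise.
_AREA_FLOOR = 1e-3

#: Period of the optional sinusoidal fluctuation, in frames (6 h at 30 min).
_FLUCTUATION_PERIOD_FRAMES = 12


@dataclass
class TrajectoryPreset:
    """Parametric description of one three-phase normalised-area curve.

    The noiseless curve starts at ``baseline`` (1.0, the t = 0 h anchor),
    decreases by ``decay_rate_fast`` per frame until ``transition_frame_1``
    (aggregation), then by ``decay_rate_slow`` per frame (compaction), and —
    if ``growth_onset_frame`` is set — increases by ``growth_rate`` per frame
    afterwards. Rates are per 30-min interval, matching the shrinkage-rate
    convention of the analysis stage.
    """

    decay_rate_fast: float
    transition_frame_1: int
    decay_rate_slow: float = 0.0
    growth_onset_frame: int | None = None
    growth_rate: float = 0.0
    baseline: float = 1.0
    noise_sd: float = 0.0
    fluctuation_amplitude: float = 0.0
    n_frames: int = 97
    interval_minutes: float = 30.0

    def __post_init__(self) -> None:
        if not (self.decay_rate_fast > self.decay_rate_slow >= 0):
            raise ValueError("need decay_rate_fast > decay_rate_slow >= 0")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.noise_sd < 0 or self.fluctuation_amplitude < 0:
            raise ValueError("noise_sd and fluctuation_amplitude must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 <= self.transition_frame_1 <= self.n_frames:
            raise ValueError("transition_frame_1 must lie within the trajectory")
        if self.growth_onset_frame is not None:
            if not self.transition_frame_1 < self.growth_onset_frame <= self.n_frames:
                raise ValueError(
                    "growth_onset_frame must satisfy "
                    "transition_frame_1 < growth_onset_frame <= n_frames"
                )


@dataclass
class CohortEffect:
    """Multiplicative condition effect applied to a preset.

    Emulates drug-like perturbations: slowed aggregation or compaction
    (decay scales < 1), suppressed growth, and contact-fragility
    fluctuations (fluctuation_scale > 1 or an added amplitude).
    """

    decay_fast_scale: float = 1.0
    decay_slow_scale: float = 1.0
    growth_scale: float = 1.0
    fluctuation_scale: float = 1.0
    extra_fluctuation: float = 0.0

    def apply(self, preset: TrajectoryPreset) -> TrajectoryPreset:
        slow = preset.decay_rate_slow * self.decay_slow_scale
        fast = max(preset.decay_rate_fast * self.decay_fast_scale, slow * (1 + 1e-9))
        if fast <= slow:  # both zero-ish; keep the invariant fast > slow
            fast = slow + 1e-12
        return replace(
            preset,
            decay_rate_fast=fast,
            decay_rate_slow=slow,
            growth_rate=preset.growth_rate * self.growth_scale,
            fluctuation_amplitude=(
                preset.fluctuation_amplitude * self.fluctuation_scale
                + self.extra_fluctuation
            ),
        )


#: Ready-made presets shaped like the three mammary cell lines the assay
#: characterised: an 18.5 h aggregation phase then steady compaction
#: (HC11-like), a 12 h aggregation phase with growth from 24 h (4T1-like),
#: and slow aggregation completing only after 29.5 h (T47D-like).
CELL_LINE_PRESETS: dict[str, TrajectoryPreset] = {
    "HC11": TrajectoryPreset(
        decay_rate_fast=0.020, transition_frame_1=37, decay_rate_slow=0.003,
        noise_sd=0.01, fluctuation_amplitude=0.015,
    ),
    "4T1": TrajectoryPreset(
        decay_rate_fast=0.033, transition_frame_1=24, decay_rate_slow=0.002,
        growth_onset_frame=48, growth_rate=0.004,
        noise_sd=0.01, fluctuation_amplitude=0.015,
    ),
    "T47D": TrajectoryPreset(
        decay_rate_fast=0.012, transition_frame_1=59, decay_rate_slow=0.001,
        noise_sd=0.01, fluctuation_amplitude=0.0,
    ),
}


def noiseless_curve(preset: TrajectoryPreset) -> np.ndarray:
    """Evaluate the piecewise-linear curve without noise or fluctuation."""
    n = preset.n_frames
    increments = np.empty(max(n - 1, 0))
    for j in range(1, n):
        if j <= preset.transition_frame_1:
            increments[j - 1] = -preset.decay_rate_fast
        elif preset.growth_onset_frame is None or j <= preset.growth_onset_frame:
            increments[j - 1] = -preset.decay_rate_slow
        else:
            increments[j - 1] = preset.growth_rate
    values = preset.baseline + np.concatenate([[0.0], np.cumsum(increments)])
    return values


def make_trajectory(preset: TrajectoryPreset, seed: int) -> AreaTrajectory:
    """Draw one noisy trajectory from a preset.

    Frame 0 equals the baseline exactly (it is the normalisation anchor);
    Gaussian noise of sd ``noise_sd`` and a sinusoidal fluctuation of
    amplitude ``fluctuation_amplitude`` (period 6 h) are added from frame 1
    onward. Values are clipped to a small positive floor so areas stay
    positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = noiseless_curve(preset).copy()
    n = preset.n_frames
    if n > 1:
        j = np.arange(1, n)
        # fluctuations are asynchronous between wells: a random phase per
        # trajectory, so they visibly perturb single wells but average out
        # of cohort means
        phase = rng.uniform(0.0, 2.0 * np.pi)
        values[1:] += preset.fluctuation_amplitude * np.sin(
            2.0 * np.pi * j / _FLUCTUATION_PERIOD_FRAMES + phase
        )
        values[1:] += rng.normal(0.0, preset.noise_sd, size=n - 1)
    values = np.maximum(values, _AREA_FLOOR)
    times_h = np.arange(n) * preset.interval_minutes / 60.0
    return AreaTrajectory(
        well_id=f"synthetic-{seed}",
        times_h=times_h,
        areas=values,
        missing=np.zeros(n, dtype=bool),
        interval_minutes=preset.interval_minutes,
    )


def make_cohort(
    preset: TrajectoryPreset,
    n_replicates: int,
    seed: int,
    effect: CohortEffect | None = None,
    missing_frame_rate: float = 0.0,
) -> list[AreaTrajectory]:
    """Generate a cohort of replicate wells with drop-out.

    Each replicate uses an independent RNG stream derived deterministically
    from ``(seed, replicate_index)``, so cohorts are reproducible
    element-wise. Every frame except frame 0 (the normalisation anchor,
    always acquired) is independently marked missing with probability
    ``missing_frame_rate``; missing areas are set to NaN but kept in place
    so the interpolation rule can be exercised.
    """
    if not 0 <= missing_frame_rate < 1:
        raise ValueError("missing_frame_rate must be in [0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if effect is not None:
        preset = effect.apply(preset)

    cohort = []
    for r in range(n_replicates):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(r,))
        traj_seed, drop_seed = child.generate_state(2) % (2**31)
        traj = make_trajectory(preset, int(traj_seed))
        traj.well_id = f"well-{seed}-{r:03d}"
        if missing_frame_rate > 0:
            drop_rng = np.random.default_rng(int(drop_seed))
            drop = drop_rng.random(preset.n_frames) < missing_frame_rate
            drop[0] = False
            traj.areas[drop] = np.nan
            traj.missing = drop
        cohort.append(traj)
    return cohort


@dataclass
class SceneConfig:
    """Rendering parameters for synthetic nuclear-fluorescence frames."""

    nucleus_radius_px: float = 5.0
    image_shape: tuple[int, int] = (256, 256)
    background_level: float = 20.0
    background_noise_sd: float = 3.0
    signal_level: float = 200.0
    pixel_size_um: float = 1.29
    interval_minutes: float = 30.0
    spot_style: str = "disk"  # "disk" (exact ground truth) or "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_px < 1:
            raise ValueError("nucleus_radius_px must be >= 1")
        if self.signal_level <= self.background_level:
            raise ValueError("signal_level must exceed background_level")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")


def _rasterize_disk(mask: np.ndarray, cy: float, cx: float, radius: float) -> None:
    """Set mask pixels whose centre lies within ``radius`` of (cy, cx)."""
    h, w = mask.shape
    y0 = max(int(np.floor(cy - radius)), 0)
    y1 = min(int(np.ceil(cy + radius)) + 1, h)
    x0 = max(int(np.floor(cx - radius)), 0)
    x1 = min(int(np.ceil(cx + radius)) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def render_stack(
    positions_um: np.ndarray,
    scene: SceneConfig,
    well_id: str = "synthetic",
) -> tuple[ImageStack, np.ndarray]:
    """Render agent x-y positions into a fluorescence-like image stack.

    Parameters
    ----------
    positions_um : array (n_frames, n_agents, >=2)
        Per-frame agent coordinates in µm, with the well centre at the
        origin; only x and y are used. A :class:`~spherokin.abm.SimulationTrace`
        can be passed via its ``positions`` attribute.
    scene : SceneConfig
        Intensity, geometry and noise settings.

    Returns
    -------
    (ImageStack, ground_truth_masks)
        The rendered stack and the exact per-frame boolean foreground masks
        (union of nucleus disks), for testing segmentation accuracy.
    """
    positions_um = np.asarray(positions_um, dtype=float)
    if positions_um.ndim == 2:  # single frame convenience
        positions_um = positions_um[None]
    n_frames, n_agents = positions_um.shape[0], positions_um.shape[1]
    h, w = scene.image_shape
    rng = np.random.default_rng(np.random.SeedSequence(scene.seed))

    frames = np.empty((n_frames, h, w), dtype=float)
    masks = np.zeros((n_frames, h, w), dtype=bool)
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    for f in range(n_frames):
        mask = masks[f]
        spots = np.zeros((h, w))
        for a in range(n_agents):
            x_um, y_um = positions_um[f, a, 0], positions_um[f, a, 1]
            cx = cx0 + x_um / scene.pixel_size_um
            cy = cy0 + y_um / scene.pixel_size_um
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValueError(
                    f"agent {a} out of image bounds on frame {f}: "
                    f"pixel position ({cx:.1f}, {cy:.1f})"
                )
            if scene.spot_style == "disk":
                _rasterize_disk(mask, cy, cx, scene.nucleus_radius_px)
            else:
                yy, xx = np.mgrid[0:h, 0:w]
                r2 = (yy - cy) ** 2 + (xx - cx) ** 2
                spots += np.exp(-r2 / (2.0 * (scene.nucleus_radius_px / 2.0) ** 2))
                mask |= r2 <= scene.nucleus_radius_px**2
        frame = np.full((h, w), scene.background_level, dtype=float)
        if scene.spot_style == "disk":
            frame[mask] = scene.signal_level
        else:
            frame += (scene.signal_level - scene.background_level) * np.minimum(spots, 1.0)
        if scene.background_noise_sd > 0:
            frame += rng.normal(0.0, scene.background_noise_sd, size=(h, w))
        frames[f] = frame

    stack = ImageStack(
        frames=frames,
        pixel_size_um=scene.pixel_size_um,
        interval_minutes=scene.interval_minutes,
        well_id=well_id,
    )
    return stack, masks


def save_preset(preset: TrajectoryPreset, path: str | Path) -> None:
    """Write a preset as a plain-text key-value (JSON/YAML-compatible) file."""
    Path(path).write_text(json.dumps(asdict(preset), indent=2) + "\n")


def load_preset(path: str | Path) -> TrajectoryPreset:
    """Load a preset from a JSON or YAML key-value file."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        data = yaml.safe_load(text)
    return TrajectoryPreset(**data)
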