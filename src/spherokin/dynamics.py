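"""Normalised-area dynamics: interpolation, cohort statistics, phase
detection and condition-vs-control testing.

The analysis follows the standard quantification of spheroid-formation
assays on a 30-min frame grid:

* wells with short runs of missing frames (a spheroid drifting out of the
  field) are repaired by local polynomial interpolation; wells with four or
  more consecutive missing frames are rejected;
* areas are normalised to the 0 h frame (NA), cohorts summarised as
  mean ± SEM per time point;
* the shrinkage rate ΔNA/Δt (per 30-min interval, positive while the area
  contracts) delimits the three formation phases: aggregation ends when the
  rate stays below 0.008 for at least 1.5 h, growth starts when it stays
  below zero for at least 1.5 h;
* conditions are compared against control per time point with a two-sided
  Wilcoxon rank-sum test, Holm-corrected across the tested time points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .trajectories import AreaTrajectory, NormalizedTrajectory

__all__ = [
    "TrajectoryRejected",
    "ShrinkageSeries",
    "PhaseAnnotation",
    "ComparisonResult",
    "interpolate_missing",
    "normalize",
    "cohort_summary",
    "shrinkage_rate",
    "detect_phases",
    "rank_sum_test",
    "holm_adjust",
    "significance_stars",
    "compare_conditions",
]

#: Default aggregation->compaction shrinkage-rate threshold (per 30-min
#: interval) and the minimum time the rate must stay below it.
DEFAULT_THRESHOLD = 0.008
DEFAULT_PERSISTENCE_H = 1.5

#: Largest sample size for which the rank-sum null is enumerated exactly.
EXACT_RANKSUM_CUTOFF = 25


class TrajectoryRejected(ValueError):
    """A well was disqualified (too many consecutive missing frames)."""

    def __init__(self, well_id: str, gap_start: int, gap_length: int):
        self.well_id = well_id
        self.gap_start = gap_start
        self.gap_length = gap_length
        super().__init__(
            f"well {well_id!r} rejected: {gap_length} consecutive missing "
            f"frames starting at frame {gap_start}"
        )


def _missing_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of True values."""
    runs = []
    i = 0
    n = len(missing)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def interpolate_missing(
    traj: AreaTrajectory,
    max_gap: int = 3,
    degree: int = 3,
    flank: int = 4,
) -> AreaTrajectory:
    """Fill short gaps by local polynomial fits; reject long gaps.

    Gaps of at most ``max_gap`` consecutive missing frames are filled by a
    polynomial (default cubic, clipped to the available points) fitted
    through up to ``flank`` non-missing frames on each side of the gap.
    A gap of ``max_gap + 1`` or more frames raises
    :class:`TrajectoryRejected` — the well is disqualified, not silently
    dropped. Interpolated frames are flagged.
    """
    if traj.missing[0]:
        raise ValueError("frame 0 is missing; the normalisation anchor is required")
    if not traj.missing.any():
        return traj.copy()

    out = traj.copy()
    for start, length in _missing_runs(traj.missing):
        if length > max_gap:
            raise TrajectoryRejected(traj.well_id, start, length)
        left = [i for i in range(start - 1, -1, -1) if not traj.missing[i]][:flank]
        right_stop = start + length
        right = [
            i for i in range(right_stop, traj.n_frames) if not traj.missing[i]
        ][:flank]
        support = np.array(sorted(left + right))
        if len(support) < 2:
            raise TrajectoryRejected(traj.well_id, start, length)
        if not left or not right:
            # boundary gap: only one-sided support exists, so this is an
            # extrapolation — keep it linear to avoid polynomial ringing
            deg = 1
        else:
            deg = min(degree, len(support) - 1)
        x = traj.times_h[support]
        x0 = x.mean()  # centre for conditioning
        coeffs = np.polyfit(x - x0, traj.areas[support], deg)
        gap = np.arange(start, start + length)
        out.areas[gap] = np.polyval(coeffs, traj.times_h[gap] - x0)
        out.missing[gap] = False
        out.interpolated[gap] = True
    # filled values stay strictly positive so normalisation remains valid
    out.areas[out.interpolated] = np.maximum(out.areas[out.interpolated], 1e-6)
    return out


def normalize(traj: AreaTrajectory) -> NormalizedTrajectory:
    """Divide a trajectory by its frame-0 area (NA definition)."""
    if traj.missing[0] or not np.isfinite(traj.areas[0]):
        raise ValueError("frame 0 is missing; cannot normalise")
    a0 = traj.areas[0]
    if a0 <= 0:
        raise ValueError("area at time 0 h must be positive")
    na = traj.areas / a0
    na = np.where(traj.missing, np.nan, na)
    return NormalizedTrajectory(
        well_id=traj.well_id,
        times_h=traj.times_h,
        na=na,
        interpolated=traj.interpolated.copy(),
        interval_minutes=traj.interval_minutes,
    )


def cohort_summary(trajs: Sequence[NormalizedTrajectory]) -> pd.DataFrame:
    """Per-frame mean and SEM of a cohort sharing one time grid.

    Returns a DataFrame with columns ``time_h, mean_na, sem_na, n``. With a
    single valid replicate the SEM is undefined and reported as 0 with a
    warning.
    """
    if len(trajs) == 0:
        raise ValueError("cohort is empty")
    grid = trajs[0].times_h
    for t in trajs[1:]:
        if len(t.times_h) != len(grid) or not np.allclose(t.times_h, grid):
            raise ValueError("all trajectories must share one time grid")
    values = np.vstack([t.na for t in trajs])
    n_valid = np.sum(np.isfinite(values), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
    sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), 0.0)
    if np.any(n_valid <= 1):
        warnings.warn(
            "SEM undefined for frames with a single valid replicate; reported as 0",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame({"time_h": grid, "mean_na": mean, "sem_na": sem, "n": n_valid})


@dataclass
class ShrinkageSeries:
    """Per-interval shrinkage rate ΔNA/Δt.

    ``rates[i] = na[i] - na[i+1]`` (unitless per interval): positive while
    the projected area contracts, negative during growth.  ``times_h[i]`` is
    the right edge of interval i (the time of frame i + 1).
    """

    times_h: np.ndarray
    rates: np.ndarray
    interval_minutes: float = 30.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.times_h) != len(self.rates):
            raise ValueError("times_h and rates must share one length")


def shrinkage_rate(
    na: np.ndarray | NormalizedTrajectory | pd.Series,
    interval_minutes: float = 30.0,
    times_h: np.ndarray | None = None,
) -> ShrinkageSeries:
    """Linear shrinkage-rate approximation ΔNA/Δt on the frame grid.

    Δt is expressed in frame units, so the rate is "per 30-min interval" —
    the scale on which the 0.008 phase threshold is defined.
    """
    if isinstance(na, NormalizedTrajectory):
        times_h = na.times_h
        interval_minutes = na.interval_minutes
        na = na.na
    na = np.asarray(na, dtype=float)
    if len(na) < 2:
        raise ValueError("need at least two frames to compute a shrinkage rate")
    if times_h is None:
        times_h = np.arange(len(na)) * interval_minutes / 60.0
    rates = na[:-1] - na[1:]
    return ShrinkageSeries(
        times_h=np.asarray(times_h, dtype=float)[1:],
        rates=rates,
        interval_minutes=interval_minutes,
    )


@dataclass
class PhaseAnnotation:
    """Boundaries of the aggregation / compaction / growth phases, hours.

    Either boundary is None when the corresponding criterion never holds
    within the observed window.
    """

    aggregation_end_h: float | None
    growth_start_h: float | None
    threshold: float = DEFAULT_THRESHOLD
    persistence_h: float = DEFAULT_PERSISTENCE_H

    def __post_init__(self) -> None:
        if (
            self.aggregation_end_h is not None
            and self.growth_start_h is not None
            and self.aggregation_end_h > self.growth_start_h
        ):
            raise ValueError("aggregation must end no later than growth starts")


def _first_run_start(qualify: np.ndarray, run_len: int) -> int | None:
    """Index of the first of ``run_len`` consecutive True values, or None."""
    count = 0
    for i, q in enumerate(qualify):
        count = count + 1 if q else 0
        if count >= run_len:
            return i - run_len + 1
    return None


def detect_phases(
    rates: ShrinkageSeries,
    threshold: float = DEFAULT_THRESHOLD,
    persistence_h: float = DEFAULT_PERSISTENCE_H,
) -> PhaseAnnotation:
    """Locate the aggregation→compaction and compaction→growth transitions.

    The aggregation phase ends at the start of the earliest run of
    consecutive intervals whose shrinkage rate is strictly below
    ``threshold`` and whose duration is at least ``persistence_h`` (3
    intervals at the default 1.5 h on a 30-min grid); growth starts at the
    earliest such run with rates below zero. The reported time is the left
    edge of the first qualifying interval.
    """
    if len(rates.times_h) > 1:
        steps = np.diff(rates.times_h)
        if not np.allclose(steps, steps[0]):
            raise ValueError("phase detection requires a uniform time grid")
    interval_h = rates.interval_minutes / 60.0
    run_len = max(1, math.ceil(persistence_h / interval_h - 1e-9))

    agg_idx = _first_run_start(rates.rates < threshold, run_len)
    growth_idx = _first_run_start(rates.rates < 0.0, run_len)
    # left edge of interval i = right-edge timestamp minus one interval
    agg_h = None if agg_idx is None else float(rates.times_h[agg_idx] - interval_h)
    growth_h = None if growth_idx is None else float(rates.times_h[growth_idx] - interval_h)
    return PhaseAnnotation(
        aggregation_end_h=agg_h,
        growth_start_h=growth_h,
        threshold=threshold,
        persistence_h=persistence_h,
    )


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Uses the exact null distribution when min(n, m) <= 25 and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie correction. Returns (rank-sum statistic W of sample a, p-value).
    Degenerate all-tied samples give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two members")
    pooled = np.concatenate([a, b])
    w_stat = float(stats.rankdata(pooled)[: len(a)].sum())
    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied; p-value set to 1", UserWarning,
                      stacklevel=2)
        return w_stat, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = min(len(a), len(b)) <= EXACT_RANKSUM_CUTOFF
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return w_stat, float(res.pvalue)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def significance_stars(p_adjusted: float) -> str:
    """Star code for an adjusted p-value: ns / * / ** / ***."""
    if p_adjusted < 0.001:
        return "***"
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    time_h: float
    statistic: float
    p_raw: float
    p_adjusted: float
    stars: str


def compare_conditions(
    cohort_a: Sequence[NormalizedTrajectory],
    cohort_b: Sequence[NormalizedTrajectory],
    times_h: Sequence[float],
) -> list[ComparisonResult]:
    """Condition-vs-control tests at selected time points, Holm-corrected.

    For each requested time point the NA values of both cohorts at the
    nearest frame are compared with a two-sided rank-sum test; the Holm
    family is the set of tested time points of this one contrast.
    """
    raw = []
    stats_w = []
    for t in times_h:
        samples = []
        for cohort in (cohort_a, cohort_b):
            idx = int(np.argmin(np.abs(cohort[0].times_h - t)))
            vals = np.array([c.na[idx] for c in cohort])
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2:
                raise ValueError(
                    f"need >= 2 valid replicates per cohort at t = {t} h"
                )
            samples.append(vals)
        w, p = rank_sum_test(samples[0], samples[1])
        stats_w.append(w)
        raw.append(p)
    adjusted = holm_adjust(raw)
    return [
        ComparisonResult(
            time_h=float(t),
            statistic=stats_w[i],
            p_raw=float(raw[i]),
            p_adjusted=float(adjusted[i]),
            stars=significance_stars(float(adjusted[i])),
        )
        for i, t in enumerate(times_h)
    ]


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "time_h": [r.time_h for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "stars": [r.stars for r in results],
        }
    )
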