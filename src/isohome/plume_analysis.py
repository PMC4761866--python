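"""Plume-isoline intersection statistics.

Decides whether a plume snapshot (the set of living odorant particles)
comes within a buffer distance of a drifted intensity isoline, and
aggregates intersection frequencies over snapshots, years, and odorant
durations with binomial confidence intervals.  The intersection frequency
is the quantity that measures how often a "magnetic highway" still leads to
detectable odor after the field has drifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._geodesy import points_to_polyline_min_km
from .errors import ValidationError
from .isoline import IsolinePolyline
from .particle_tracking import PlumeSnapshot, TrajectorySet

#: default intersection buffer, ~ one 0.08° ocean-model grid cell
DEFAULT_BUFFER_KM = 10.0


@dataclass
class IntersectionResult:
    """Proportion of snapshots whose plume touches the isoline, with a 95%
    Wilson score interval on the snapshot counts."""

    n_snapshots: int
    n_intersecting: int
    proportion: float
    ci_low: float
    ci_high: float
    duration_days: float | None = None
    year: int | None = None
    cue: str | None = None
    delta_years: float | None = None

    def __post_init__(self):
        if self.n_intersecting > self.n_snapshots:
            raise ValidationError("n_intersecting cannot exceed n_snapshots")
        if not (self.ci_low <= self.proportion <= self.ci_high):
            raise ValidationError("CI must bracket the proportion")

    def to_dict(self) -> dict:
        return {"cue": self.cue, "duration_days": self.duration_days,
                "year": self.year, "delta_years": self.delta_years,
                "n": self.n_snapshots, "k": self.n_intersecting,
                "proportion": self.proportion,
                "ci_low": self.ci_low, "ci_high": self.ci_high}


def min_distance_to_isoline_km(snapshot: PlumeSnapshot,
                               isoline: IsolinePolyline) -> float:
    """Smallest particle-to-isoline great-circle distance (inf if empty)."""
    if not isoline.segments or isoline.n_vertices == 0:
        raise ValidationError("isoline is empty")
    if snapshot.n_particles == 0:
        return np.inf
    best = np.inf
    for seg in isoline.segments:
        if seg.shape[0] == 0:
            continue
        d = points_to_polyline_min_km(snapshot.positions[:, 0],
                                      snapshot.positions[:, 1], seg)
        best = min(best, float(d.min()))
    return best


def plume_intersects(snapshot: PlumeSnapshot, isoline: IsolinePolyline,
                     buffer_km: float = DEFAULT_BUFFER_KM) -> bool:
    """True iff any living particle lies within ``buffer_km`` of the isoline.

    An empty snapshot never intersects.  Monotone in the buffer by
    construction.
    """
    if buffer_km < 0:
        raise ValidationError("buffer_km must be >= 0")
    return min_distance_to_isoline_km(snapshot, isoline) <= buffer_km


def snapshot_times(season_start_h: float, season_end_h: float,
                   k: int) -> np.ndarray:
    """``k`` evenly spaced instants across the season window.

    Endpoints are included for k >= 2; k = 1 degenerates to the midpoint.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if season_end_h <= season_start_h:
        raise ValidationError("season_end_h must exceed season_start_h")
    if k == 1:
        return np.array([0.5 * (season_start_h + season_end_h)])
    return np.linspace(season_start_h, season_end_h, k)


def wilson_interval(k: int, n: int, alpha: float = 0.05):
    """95% (by default) Wilson score interval for a binomial proportion.

    Endpoints are clamped to [0, 1] and to bracket k/n (guards against
    ~1e-16 floating-point overshoot at the boundaries).
    """
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    p = k / n
    return float(min(max(lo, 0.0), p)), float(max(min(hi, 1.0), p))


def intersection_rate(snapshots: list[PlumeSnapshot], isoline: IsolinePolyline,
                      buffer_km: float = DEFAULT_BUFFER_KM,
                      **labels) -> IntersectionResult:
    """Fraction of snapshots intersecting the isoline, with a Wilson 95% CI."""
    if len(snapshots) < 1:
        raise ValidationError("need at least one snapshot")
    flags = [plume_intersects(s, isoline, buffer_km) for s in snapshots]
    return intersection_rate_from_flags(flags, **labels)


def intersection_rate_from_flags(flags, **labels) -> IntersectionResult:
    n = len(flags)
    k = int(np.sum(flags))
    lo, hi = wilson_interval(k, n)
    return IntersectionResult(n_snapshots=n, n_intersecting=k,
                              proportion=k / n, ci_low=lo, ci_high=hi,
                              **labels)


def duration_sensitivity(trajectories_by_year: dict[int, TrajectorySet],
                         isoline_by_year: dict[int, IsolinePolyline],
                         lifetimes_days=(15.0, 30.0, 45.0),
                         snapshots_per_year: int = 10,
                         buffer_km: float = DEFAULT_BUFFER_KM,
                         cue: str = "waterborne",
                         delta_years: float | None = None) -> pd.DataFrame:
    """Intersection rates per (odorant duration, year) plus per-duration means.

    Each year's trajectory set must have been simulated at the *longest*
    lifetime; shorter durations reuse the same trajectories with a stricter
    age cut, so the alive-set is exactly nested across durations and the
    intersection rate is monotone non-decreasing in duration by construction.
    """
    lifetimes_days = sorted(lifetimes_days)
    rows = []
    per_duration_flags = {d: [] for d in lifetimes_days}
    for year, traj in sorted(trajectories_by_year.items()):
        iso = isoline_by_year[year]
        season_len = traj.times_h[-1] - traj.lifetime_h
        times = snapshot_times(0.0, float(season_len), snapshots_per_year)
        # snapshots late in the season are taken when the plume is mature;
        # clip to the simulated span for safety
        times = np.clip(times, traj.times_h[0], traj.times_h[-1])
        for d in lifetimes_days:
            if d * 24.0 > traj.lifetime_h + 1e-9:
                raise ValidationError(
                    f"lifetime {d} d exceeds simulated {traj.lifetime_h / 24} d")
            flags = [plume_intersects(traj.snapshot(t, lifetime_h=d * 24.0),
                                      iso, buffer_km) for t in times]
            per_duration_flags[d].extend(flags)
            rows.append(intersection_rate_from_flags(
                flags, duration_days=d, year=year, cue=cue,
                delta_years=delta_years).to_dict())
    for d in lifetimes_days:
        rows.append(intersection_rate_from_flags(
            per_duration_flags[d], duration_days=d, year=None, cue=cue,
            delta_years=delta_years).to_dict())
    return pd.DataFrame(rows)


def results_to_csv(df: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
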