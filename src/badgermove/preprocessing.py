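"""Cleaning and regularisation of raw GPS fix tables.

The cleaning pipeline runs in a fixed order:

    quality -> speed -> jump -> snap -> split -> shift -> interpolate

1. drop fixes with fewer than 4 satellites or dilution of precision > 4
   (fixes lacking both quality fields pass);
2. drop fixes implying travel faster than 26.2 m/min, the fastest speed
   recorded for badgers;
3. drop lone spikes: single fixes whose out-and-back excursion exceeds
   1500 m over two consecutive steps while the neighbours nearly coincide;
4. snap recorded times to the collar's programmed fix grid, discarding
   fixes displaced by more than a tolerance (collars can log late when
   satellite acquisition is slow);
5. split each animal's series into monitoring periods at large gaps
   (collar battery loss can leave days or months without data);
6. shift coordinates per site to a (0, 0) base;
7. linearly interpolate within nights to an exactly uniform step.

Every stage logs the number of records removed so the reduction
bookkeeping of a study can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .synthetic import ObservationSchedule

FIX_COLUMNS = ["animal_id", "group_id", "sex", "site", "timestamp",
               "x_m", "y_m", "n_sats", "dop"]


@dataclass
class Track:
    """Time-sorted fixes of one animal within one monitoring period."""

    period_id: str
    animal_id: str
    fixes: pd.DataFrame  # columns FIX_COLUMNS + interpolated

    def __post_init__(self):
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("track timestamps must be increasing")

    def __len__(self):
        return len(self.fixes)


@dataclass
class RegularTrack:
    """A within-night segment resampled to uniform spacing ``dt`` minutes.

    Original fixes are preserved exactly; inserted ones carry
    ``interpolated = True``.  The first and last fixes are always original.
    """

    period_id: str
    animal_id: str
    dt: float
    fixes: pd.DataFrame

    @property
    def positions(self) -> np.ndarray:
        return self.fixes[["x_m", "y_m"]].to_numpy(dtype=float)


@dataclass
class AuditLog:
    """Per-stage record-count bookkeeping, serialisable as JSON lines."""

    entries: list = dc_field(default_factory=list)

    def record(self, stage: str, n_before: int, n_after: int, reason: str = ""):
        self.entries.append({
            "stage": stage,
            "n_before": int(n_before),
            "n_after": int(n_after),
            "removed": int(n_before - n_after),
            "reason": reason,
        })

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(e) for e in self.entries)

    @property
    def total_reduction(self) -> float:
        """Overall fraction of raw records removed across logged stages."""
        if not self.entries:
            return 0.0
        n0 = self.entries[0]["n_before"]
        n1 = self.entries[-1]["n_after"]
        return 1.0 - n1 / n0 if n0 else 0.0


def filter_quality(fixes: pd.DataFrame, min_sats: int = 4,
                   max_dop: float = 4.0) -> pd.DataFrame:
    """Drop low-quality fixes: fewer than ``min_sats`` satellites or
    dilution of precision above ``max_dop``.  Fixes with neither field
    recorded pass unfiltered."""
    if fixes.empty:
        return fixes.copy()
    sats = fixes.get("n_sats")
    dop = fixes.get("dop")
    keep = pd.Series(True, index=fixes.index)
    if sats is not None:
        keep &= sats.isna() | (sats >= min_sats)
    if dop is not None:
        keep &= dop.isna() | (dop <= max_dop)
    return fixes[keep].copy()


def _speeds(df: pd.DataFrame) -> np.ndarray:
    dt = df["timestamp"].diff().dt.total_seconds().to_numpy() / 60.0
    dx = df["x_m"].diff().to_numpy()
    dy = df["y_m"].diff().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.hypot(dx, dy) / dt


def filter_speed(track: pd.DataFrame, max_speed: float = 26.2) -> pd.DataFrame:
    """Remove fixes implying implausible speed.

    Scans consecutive surviving pairs; when Euclidean distance / elapsed
    minutes exceeds ``max_speed`` the *later* fix is dropped and scanning
    resumes from the surviving predecessor.  Idempotent.
    """
    if len(track) < 2:
        return track.copy()
    df = track.sort_values("timestamp")
    t = df["timestamp"].astype("int64").to_numpy() / 60e9  # minutes
    x = df["x_m"].to_numpy(dtype=float)
    y = df["y_m"].to_numpy(dtype=float)
    keep = np.ones(len(df), dtype=bool)
    prev = 0
    for i in range(1, len(df)):
        dt = t[i] - t[prev]
        if dt <= 0:
            keep[i] = False
            continue
        speed = np.hypot(x[i] - x[prev], y[i] - y[prev]) / dt
        if speed > max_speed:
            keep[i] = False
        else:
            prev = i
    return df[keep].copy()


def filter_jump(track: pd.DataFrame, max_two_step: float = 1500.0) -> pd.DataFrame:
    """Remove lone spikes: a single fix B in a triple A-B-C where the
    out-and-back path |AB| + |BC| exceeds ``max_two_step`` metres while A
    and C nearly coincide (|AC| small relative to the excursion) is
    biologically unrealistic and dropped.  Idempotent.
    """
    if len(track) < 3:
        return track.copy()
    df = track.sort_values("timestamp")
    x = df["x_m"].to_numpy(dtype=float)
    y = df["y_m"].to_numpy(dtype=float)
    keep = np.ones(len(df), dtype=bool)
    idx = np.arange(len(df))
    changed = True
    while changed:
        changed = False
        live = idx[keep]
        for a, b, c in zip(live[:-2], live[1:-1], live[2:]):
            out = np.hypot(x[b] - x[a], y[b] - y[a])
            back = np.hypot(x[c] - x[b], y[c] - y[b])
            base = np.hypot(x[c] - x[a], y[c] - y[a])
            if out + back > max_two_step and base < 0.25 * (out + back):
                keep[b] = False
                changed = True
                break
    return df[keep].copy()


def shift_origin(fixes: pd.DataFrame) -> pd.DataFrame:
    """Translate coordinates to a (0, 0) base, per site.

    Subtracts the per-site minimum x and y so every coordinate is
    non-negative; pairwise distances within a site are unchanged.
    """
    if fixes.empty:
        raise ValueError("cannot shift an empty fix table")
    out = fixes.copy()
    site_col = out["site"] if "site" in out else pd.Series("_", index=out.index)
    for _, ix in out.groupby(site_col).groups.items():
        out.loc[ix, "x_m"] -= out.loc[ix, "x_m"].min()
        out.loc[ix, "y_m"] -= out.loc[ix, "y_m"].min()
    return out


def snap_times(track: pd.DataFrame, schedule: ObservationSchedule,
               max_displacement: float = 3.0) -> pd.DataFrame:
    """Snap recorded timestamps to the nearest programmed fix time.

    Fixes whose displacement exceeds ``max_displacement`` minutes are
    discarded (slow satellite acquisition makes their true location time
    too uncertain to use).  When several fixes snap to the same slot only
    the first is kept; exact midpoints round down.
    """
    if track.empty:
        return track.copy()
    from .synthetic import STUDY_EPOCH
    df = track.sort_values("timestamp").copy()
    minutes = (df["timestamp"] - STUDY_EPOCH).dt.total_seconds().to_numpy() / 60.0
    start_min = schedule._minutes(schedule.window_start)
    days = np.unique(np.concatenate([
        np.floor(minutes / 1440.0).astype(int) - 1,
        np.floor(minutes / 1440.0).astype(int),
        np.floor(minutes / 1440.0).astype(int) + 1,
    ]))
    grid = np.unique(np.concatenate([
        schedule.night_times(d * 1440.0 + start_min) for d in days
    ]))
    pos = np.searchsorted(grid, minutes)
    snapped = np.empty_like(minutes)
    for i, (m, p) in enumerate(zip(minutes, pos)):
        lo = grid[max(p - 1, 0)]
        hi = grid[min(p, len(grid) - 1)]
        # ties round down (earlier slot)
        snapped[i] = lo if (m - lo) <= (hi - m) else hi
    displacement = np.abs(minutes - snapped)
    df["timestamp"] = STUDY_EPOCH + pd.to_timedelta(snapped, unit="min")
    df = df[displacement <= max_displacement + 1e-9]
    df = df.drop_duplicates(subset=["animal_id", "timestamp"], keep="first")
    return df.sort_values("timestamp")


def split_periods(fixes: pd.DataFrame, max_gap: float = 7 * 1440.0) -> list[Track]:
    """Split each animal's fixes into monitoring periods at gaps larger
    than ``max_gap`` minutes (default 7 days), assigning fresh period ids."""
    tracks: list[Track] = []
    for animal, df in fixes.groupby("animal_id", sort=True):
        df = df.sort_values("timestamp").reset_index(drop=True)
        gaps = df["timestamp"].diff().dt.total_seconds().to_numpy() / 60.0
        breaks = np.flatnonzero(gaps > max_gap)
        bounds = np.concatenate([[0], breaks, [len(df)]])
        for p, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            seg = df.iloc[int(a):int(b)].reset_index(drop=True)
            if seg.empty:
                continue
            tracks.append(Track(f"{animal}P{p + 1}", str(animal), seg))
    return tracks


def _night_index(minutes: np.ndarray, schedule: ObservationSchedule) -> np.ndarray:
    """Which nightly window each epoch-minute belongs to.

    For a window crossing midnight (e.g. 20:00-04:00), the small hours of
    day d belong to the night that opened on day d - 1.
    """
    start = schedule._minutes(schedule.window_start)
    end = schedule._minutes(schedule.window_end)
    day = np.floor(minutes / 1440.0).astype(int)
    mod = minutes % 1440.0
    if end <= start:  # crosses midnight
        return np.where(mod >= start - 1e-9, day, day - 1)
    return day


def night_segments(track: Track, schedule: ObservationSchedule,
                   min_fixes: int = 2) -> list[pd.DataFrame]:
    """Partition a track into per-night runs of fixes.

    Fixes are grouped by the nightly window they fall in, so the daytime
    gap (when badgers are typically inactive underground) never appears
    inside a segment.
    """
    if len(track) == 0:
        return []
    from .synthetic import STUDY_EPOCH
    df = track.fixes
    minutes = (df["timestamp"] - STUDY_EPOCH).dt.total_seconds().to_numpy() / 60.0
    nights = _night_index(minutes, schedule)
    breaks = np.flatnonzero(np.diff(nights) != 0) + 1
    bounds = np.concatenate([[0], breaks, [len(df)]])
    return [
        df.iloc[int(a):int(b)].reset_index(drop=True)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b - a >= min_fixes
    ]


def interpolate_uniform(track: Track, dt: float,
                        half_native: float | None = None) -> RegularTrack:
    """Resample one within-night segment to exactly uniform spacing.

    Linear interpolation between consecutive fixes; originals preserved
    bit-exactly and inserted fixes flagged ``interpolated``.  Each
    inter-fix interval must be an integer multiple of ``dt``.  The one
    exception is half-interval mode (``half_native`` = the nominal fix
    interval, used for 35-min collars resampled at 17.5 min): every
    interval then receives exactly one midpoint, so the odd 30-minute
    midnight-boundary interval yields two 15-minute halves rather than an
    error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    df = track.fixes.sort_values("timestamp").reset_index(drop=True)
    if "interpolated" not in df:
        df = df.assign(interpolated=False)
    if len(df) < 2:
        return RegularTrack(track.period_id, track.animal_id, dt, df)
    t = df["timestamp"].astype("int64").to_numpy() / 60e9
    rows = [df.iloc[[0]]]
    for i in range(len(df) - 1):
        gap = t[i + 1] - t[i]
        if half_native is not None and abs(2 * dt - half_native) < 1e-9:
            # one midpoint per native interval; multi-interval gaps get
            # proportionally more so spacing stays ~dt, and the odd
            # 30-minute midnight interval is simply halved
            ratio = gap / half_native
            n_sub = 2 * int(round(ratio)) if abs(ratio - round(ratio)) < 1e-6 else 2
            n_sub = max(n_sub, 2)
        else:
            n_sub = gap / dt
            if abs(n_sub - round(n_sub)) > 1e-6:
                raise ValueError(
                    f"interval of {gap:g} min between "
                    f"{df['timestamp'].iloc[i]} and {df['timestamp'].iloc[i + 1]} "
                    f"is not a multiple of dt={dt:g}"
                )
            n_sub = int(round(n_sub))
        for j in range(1, n_sub):
            frac = j / n_sub
            mid = df.iloc[[i]].copy()
            mid["timestamp"] = (df["timestamp"].iloc[i]
                                + pd.to_timedelta(frac * gap, unit="min"))
            mid["x_m"] = (1 - frac) * df["x_m"].iloc[i] + frac * df["x_m"].iloc[i + 1]
            mid["y_m"] = (1 - frac) * df["y_m"].iloc[i] + frac * df["y_m"].iloc[i + 1]
            mid["n_sats"] = np.nan
            mid["dop"] = np.nan
            mid["interpolated"] = True
            rows.append(mid)
        rows.append(df.iloc[[i + 1]])
    out = pd.concat(rows, ignore_index=True)
    return RegularTrack(track.period_id, track.animal_id, dt, out)


def regularise(track: Track, schedule: ObservationSchedule, dt: float,
               min_fixes: int = 2) -> list[RegularTrack]:
    """Split a monitoring period into nights and resample each at ``dt``.

    Interpolation never crosses the daytime gap.  If ``2 * dt`` equals the
    schedule's nominal interval, half-interval mode is used (one midpoint
    per native interval).
    """
    half = schedule.fix_interval if abs(2 * dt - schedule.fix_interval) < 1e-9 else None
    out = []
    for k, seg in enumerate(night_segments(track, schedule, min_fixes)):
        sub = Track(f"{track.period_id}N{k + 1}", track.animal_id, seg)
        out.append(interpolate_uniform(sub, dt, half_native=half))
    return out


def clean_fixes(
    fixes: pd.DataFrame,
    schedule: ObservationSchedule,
    *,
    min_sats: int = 4,
    max_dop: float = 4.0,
    max_speed: float = 26.2,
    max_two_step: float = 1500.0,
    snap_tolerance: float = 3.0,
    max_gap: float = 7 * 1440.0,
    exclude_animals: tuple[str, ...] = (),
    shift: bool = True,
    log: AuditLog | None = None,
) -> tuple[list[Track], AuditLog]:
    """Run the full cleaning pipeline on a raw fix table.

    Returns per-monitoring-period :class:`Track` objects with coordinates
    shifted to a per-site (0, 0) base, plus the audit log.  Animals listed
    in ``exclude_animals`` are removed up front (the analogue of manually
    excluding individuals isolated from the rest of a study population).
    """
    log = log if log is not None else AuditLog()
    df = fixes.copy()
    n0 = len(df)
    if exclude_animals:
        df = df[~df["animal_id"].isin(exclude_animals)]
    log.record("exclude_animals", n0, len(df), "manually excluded individuals")

    n = len(df)
    df = filter_quality(df, min_sats=min_sats, max_dop=max_dop)
    log.record("quality", n, len(df), f"n_sats < {min_sats} or dop > {max_dop}")

    n = len(df)
    parts = [filter_speed(g, max_speed=max_speed)
             for _, g in df.groupby("animal_id", sort=True)]
    df = pd.concat(parts, ignore_index=True) if parts else df.iloc[:0]
    log.record("speed", n, len(df), f"implied speed > {max_speed} m/min")

    n = len(df)
    parts = [filter_jump(g, max_two_step=max_two_step)
             for _, g in df.groupby("animal_id", sort=True)]
    df = pd.concat(parts, ignore_index=True) if parts else df.iloc[:0]
    log.record("jump", n, len(df), f"lone spike > {max_two_step} m over two steps")

    n = len(df)
    parts = [snap_times(g, schedule, max_displacement=snap_tolerance)
             for _, g in df.groupby("animal_id", sort=True)]
    df = pd.concat(parts, ignore_index=True) if parts else df.iloc[:0]
    log.record("snap", n, len(df), f"snap displacement > {snap_tolerance} min")

    if df.empty:
        return [], log
    if shift:
        df = shift_origin(df)
    log.record("shift", len(df), len(df),
               "translated to (0,0) base per site" if shift
               else "skipped (already in a common frame)")

    tracks = split_periods(df, max_gap=max_gap)
    log.record("split", len(df), sum(len(t) for t in tracks),
               f"monitoring periods at gaps > {max_gap:g} min: {len(tracks)}")
    return tracks, log
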