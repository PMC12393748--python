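"""Isotropic diffusion estimation from cleaned tracks.

For a process dX = b dt + c dW with isotropic diffusion, the
Kramers–Moyal (conditional second moment) formula gives, from m fixes
(x_i, y_i) at times t_i,

    c^2 ~= 1 / (2 (m - 1)) * sum_i (1 / dt_i) [(x_{i+1} - x_i)^2
                                               + (y_{i+1} - y_i)^2],

with dt_i = t_{i+1} - t_i in minutes, so c carries units m * min^-1/2.
Unequal dt_i are supported.  Pairs spanning the overnight daytime gap are
excluded (animals are inactive underground, so those displacements do not
reflect the movement process); each surviving within-night consecutive
pair contributes.

Estimates are aggregated per animal and calendar month — the
observational unit of the downstream mixed model — and months supported
by ten or fewer fixes are dropped as too sparse for a stable estimate.
Because c is positive and multiplicative effects act on its log, log c is
expected to be approximately normal; a Shapiro–Wilk check is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import Track, night_segments
from .synthetic import ObservationSchedule

#: Months with this many fixes or fewer yield no estimate.
MIN_FIXES_EXCLUSIVE = 10


@dataclass
class DiffusionEstimate:
    animal_id: str
    site: str
    sex: str
    month: int
    capture_year: int
    c: float
    n_pairs: int

    def __post_init__(self):
        if self.c < 0 or self.n_pairs < 1:
            raise ValueError("c must be >= 0 and n_pairs >= 1")


def _pairs_from_frame(df: pd.DataFrame):
    t = df["timestamp"].astype("int64").to_numpy() / 60e9  # minutes
    x = df[["x_m", "y_m"]].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-increasing timestamps in track")
    sq = np.sum(np.diff(x, axis=0) ** 2, axis=1)
    return dt, sq


def estimate_c(track) -> tuple[float, int]:
    """Diffusion constant from one track's consecutive displacement pairs.

    Accepts a :class:`Track` or a fix DataFrame whose pairs are already
    within-night.  Returns ``(c, n_pairs)``; raises on fewer than two
    fixes or non-positive time steps.
    """
    df = track.fixes if isinstance(track, Track) else track
    if len(df) < 2:
        raise ValueError("need at least two fixes to estimate diffusion")
    dt, sq = _pairs_from_frame(df.sort_values("timestamp"))
    c2 = np.sum(sq / dt) / (2.0 * len(dt))
    return float(np.sqrt(c2)), len(dt)


def _pooled_c(dts: np.ndarray, sqs: np.ndarray) -> float:
    return float(np.sqrt(np.sum(sqs / dts) / (2.0 * len(dts))))


def monthly_estimates(
    tracks: list[Track],
    covariates: pd.DataFrame,
    schedule: ObservationSchedule | None = None,
    min_fixes: int = MIN_FIXES_EXCLUSIVE + 1,
) -> list[DiffusionEstimate]:
    """One diffusion estimate per (animal, calendar month).

    ``covariates`` must cover every animal with columns
    ``animal_id, site, sex, capture_year``.  If a ``schedule`` is given,
    displacement pairs are restricted to within-night consecutive fixes;
    otherwise all consecutive pairs in each track are used (appropriate
    when tracks are already night segments).  A pair spanning two months
    is assigned to the month of its earlier fix.  Animal-months with
    fewer than ``min_fixes`` underlying fixes are dropped.
    """
    cov = covariates.set_index("animal_id")
    missing = {t.animal_id for t in tracks} - set(cov.index)
    if missing:
        raise KeyError(f"covariates missing for animals: {sorted(missing)}")

    # accumulate per (animal, month): fix count and pair displacements
    acc: dict[tuple[str, int], dict] = {}
    for track in tracks:
        segments = (night_segments(track, schedule, min_fixes=1)
                    if schedule is not None else [track.fixes])
        for seg in segments:
            seg = seg.sort_values("timestamp")
            months = seg["timestamp"].dt.month.to_numpy()
            for mth in np.unique(months):
                key = (track.animal_id, int(mth))
                a = acc.setdefault(key, {"n_fixes": 0, "dts": [], "sqs": []})
                a["n_fixes"] += int(np.sum(months == mth))
            if len(seg) < 2:
                continue
            dt, sq = _pairs_from_frame(seg)
            pair_month = months[:-1]  # earlier fix decides the month
            for mth in np.unique(pair_month):
                sel = pair_month == mth
                a = acc[(track.animal_id, int(mth))]
                a["dts"].append(dt[sel])
                a["sqs"].append(sq[sel])

    out = []
    for (animal, mth), a in sorted(acc.items()):
        if a["n_fixes"] < min_fixes or not a["dts"]:
            continue
        dts = np.concatenate(a["dts"])
        sqs = np.concatenate(a["sqs"])
        row = cov.loc[animal]
        out.append(DiffusionEstimate(
            animal_id=animal,
            site=str(row["site"]),
            sex=str(row["sex"]),
            month=mth,
            capture_year=int(row.get("capture_year", 1)),
            c=_pooled_c(dts, sqs),
            n_pairs=len(dts),
        ))
    return out


def estimates_frame(estimates: list[DiffusionEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates], columns=[
        "animal_id", "site", "sex", "month", "capture_year", "c", "n_pairs",
    ])


def lognormality_check(estimates, alpha: float = 0.05):
    """Shapiro–Wilk test of normality applied to log(c).

    Returns ``(statistic, p_value, passed)`` with ``passed = p > alpha``
    (no evidence against log-normality of the diffusion constants).
    """
    estimates = list(estimates)
    if estimates and isinstance(estimates[0], DiffusionEstimate):
        c = np.asarray([e.c for e in estimates], dtype=float)
    else:
        c = np.asarray(estimates, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least three estimates for a Shapiro-Wilk test")
    if np.any(c <= 0):
        raise ValueError("log-normality check undefined for c <= 0")
    stat, p = stats.shapiro(np.log(c))
    return float(stat), float(p), bool(p > alpha)
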