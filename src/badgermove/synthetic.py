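"""Synthetic badger telemetry with known ground truth.

Movement follows a two-dimensional SDE

    dX_t = b(X_t) dt + c dW_t,

with isotropic diffusion (sigma = c * I, c in m * min^-1/2) and a drift b
derived from a multi-well potential: each social group is anchored to one
well (its main sett area), so trajectories are metastable — long residence
near the home well with rare excursions.  A GPS observation layer turns the
continuous paths into nightly fix tables with the defects real collars
produce: timing jitter, dropout, gross outliers and poor-quality fixes.

Time is measured in minutes throughout; coordinates in metres.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from datetime import time as dtime

import numpy as np
import pandas as pd

STUDY_EPOCH = pd.Timestamp("2021-01-01 00:00")

#: Log-scale calendar-month diffusion multipliers, January = reference.
#: February is elevated (early-spring activity peak); late-year months are
#: depressed relative to January.
DEFAULT_MONTH_EFFECTS = (
    0.0, 0.106, 0.050, 0.036, 0.006, -0.106,
    -0.069, -0.116, -0.236, -0.370, -0.442, -0.290,
)

#: Log-scale female-vs-male diffusion contrast.
DEFAULT_SEX_EFFECT = -0.152

#: Between-animal log-scale random-intercept SD (variance 0.229).
DEFAULT_INDIVIDUAL_SD = 0.4786


class SdeBlowupError(RuntimeError):
    """Raised when an Euler–Maruyama step produces a non-finite position."""


@dataclass(frozen=True)
class PotentialField:
    """Sum of inverted Gaussian wells.

    U(x) = -sum_k depth_k * exp(-|x - centre_k|^2 / (2 * width_k^2))

    The drift is b(x) = -grad U(x): smooth, bounded, and attracting toward
    the nearest well.  Depths are energies (min^-1 m^2 scale), widths metres.
    """

    centres: np.ndarray  # (K, 2) m
    depths: np.ndarray   # (K,)
    widths: np.ndarray   # (K,) m

    def __post_init__(self):
        centres = np.atleast_2d(np.asarray(self.centres, dtype=float))
        depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if centres.shape != (len(depths), 2) or len(depths) != len(widths):
            raise ValueError("centres, depths, widths must have matching lengths")
        if len(depths) < 1:
            raise ValueError("at least one well required")
        if np.any(depths < 0) or np.any(widths <= 0):
            raise ValueError("depths must be >= 0 and widths > 0")
        object.__setattr__(self, "centres", centres)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "widths", widths)

    @property
    def is_flat(self) -> bool:
        return bool(np.all(self.depths == 0.0))

    def potential(self, x) -> float:
        x = np.asarray(x, dtype=float)
        d2 = np.sum((x - self.centres) ** 2, axis=1)
        return float(-np.sum(self.depths * np.exp(-d2 / (2.0 * self.widths**2))))

    def drift_at(self, x) -> np.ndarray:
        """Drift b(x) = -grad U(x); a total, bounded function of the plane."""
        x = np.asarray(x, dtype=float)
        diff = x - self.centres                      # (K, 2)
        d2 = np.sum(diff**2, axis=1)
        w2 = self.widths**2
        weight = self.depths * np.exp(-d2 / (2.0 * w2)) / w2   # (K,)
        return -(weight[:, None] * diff).sum(axis=0)


def drift_at(field: PotentialField, x) -> np.ndarray:
    return field.drift_at(x)


@dataclass
class TrueTrajectory:
    """Uniformly sampled latent path of one animal.

    ``times`` are minutes since :data:`STUDY_EPOCH`, strictly increasing at
    a constant step ``dt``; ``positions`` are metres.
    """

    individual_id: str
    group_id: str
    sex: str
    times: np.ndarray      # (n,) minutes since STUDY_EPOCH
    positions: np.ndarray  # (n, 2) m

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("trajectory times must be uniformly spaced")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            return np.nan
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class ObservationSchedule:
    """Nightly GPS duty cycle of a collar.

    The collar attempts a fix every ``fix_interval`` minutes inside the
    nightly window.  Scheduling is anchored at the window start until
    midnight and re-anchored at 00:00 after it (collars run on a
    midnight-to-midnight internal cycle), so a 20:00–04:00 window at 35 min
    yields fixes ... 23:30, 00:00, 00:35 ... with a single 30-minute
    interval at the boundary.
    """

    window_start: dtime = dtime(20, 0)
    window_end: dtime = dtime(4, 0)
    fix_interval: float = 20.0
    jitter_max: float = 0.0
    dropout_prob: float = 0.0
    outlier_prob: float = 0.0
    outlier_scale: float = 2000.0
    bad_quality_prob: float = 0.0

    def __post_init__(self):
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        if not 0 <= self.jitter_max < self.fix_interval / 2:
            raise ValueError("jitter_max must satisfy 0 <= jitter < interval/2")
        for p in (self.dropout_prob, self.outlier_prob, self.bad_quality_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def _minutes(self, t: dtime) -> float:
        return t.hour * 60 + t.minute + t.second / 60.0

    def night_times(self, night_start_minute: float) -> np.ndarray:
        """Scheduled fix times (minutes since epoch) for the night whose
        evening window opens ``night_start_minute`` after the epoch.

        ``night_start_minute`` must be the epoch-minute of ``window_start``
        on some calendar day.
        """
        start = self._minutes(self.window_start)
        end = self._minutes(self.window_end)
        out = []
        if end <= start:  # window crosses midnight
            to_midnight = 1440.0 - start
            t = 0.0
            while t < to_midnight:
                out.append(night_start_minute + t)
                t += self.fix_interval
            # re-anchor at midnight
            t = 0.0
            while t <= end + 1e-9:
                out.append(night_start_minute + to_midnight + t)
                t += self.fix_interval
        else:
            t = 0.0
            while t <= end - start + 1e-9:
                out.append(night_start_minute + t)
                t += self.fix_interval
        return np.asarray(out)

    def in_window(self, minute_of_day: float) -> bool:
        start = self._minutes(self.window_start)
        end = self._minutes(self.window_end)
        m = minute_of_day % 1440.0
        if end <= start:
            return m >= start - 1e-9 or m <= end + 1e-9
        return start - 1e-9 <= m <= end + 1e-9


def simulate_sde(
    field: PotentialField,
    c: float,
    x0,
    dt: float,
    n_steps: int,
    seed,
    t0: float = 0.0,
    individual_id: str = "sim",
    group_id: str = "g0",
    sex: str = "male",
) -> TrueTrajectory:
    """Euler–Maruyama integration of the movement SDE.

    X_{k+1} = X_k + b(X_k) dt + c sqrt(dt) Z_k, Z_k ~ N(0, I_2).

    Deterministic for a fixed ``seed`` (any value acceptable to
    ``numpy.random.default_rng``).  Raises :class:`SdeBlowupError` if the
    drift drives the position non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if c < 0:
        raise ValueError("c must be non-negative")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    times = t0 + dt * np.arange(n_steps + 1)

    if field.is_flat:
        # pure Brownian motion: vectorised exact update
        steps = c * np.sqrt(dt) * rng.standard_normal((n_steps, 2))
        positions = np.vstack([x0, x0 + np.cumsum(steps, axis=0)])
        return TrueTrajectory(individual_id, group_id, sex, times, positions)

    noise = c * np.sqrt(dt) * rng.standard_normal((n_steps, 2))
    positions = np.empty((n_steps + 1, 2))
    positions[0] = x0
    x = x0
    for k in range(n_steps):
        x = x + field.drift_at(x) * dt + noise[k]
        if not np.all(np.isfinite(x)):
            raise SdeBlowupError(
                f"non-finite position at step {k + 1} (t={times[k + 1]:.1f} min); "
                "reduce dt or the well depths"
            )
        positions[k + 1] = x
    return TrueTrajectory(individual_id, group_id, sex, times, positions)


def simulate_ou_1d(theta: float, sigma: float, x0: float, dt: float,
                   n_steps: int, seed) -> np.ndarray:
    """Exact sampling of the 1-D Ornstein–Uhlenbeck process
    dX = -theta X dt + sigma dW at step ``dt``.

    The OU process is the standard calibration benchmark here: its Koopman
    operator at lag tau has eigenvalues exp(-k theta tau), k = 0, 1, 2, ...
    """
    if theta <= 0 or sigma < 0 or dt <= 0:
        raise ValueError("need theta > 0, sigma >= 0, dt > 0")
    rng = np.random.default_rng(seed)
    a = np.exp(-theta * dt)
    s = sigma * np.sqrt((1.0 - a * a) / (2.0 * theta))
    x = np.empty(n_steps + 1)
    x[0] = x0
    z = rng.standard_normal(n_steps)
    for k in range(n_steps):
        x[k + 1] = a * x[k] + s * z[k]
    return x


def _individual_rng(seed: int, individual_id: str) -> np.random.Generator:
    """One independent stream per animal: removing or adding an individual
    never perturbs the others' trajectories."""
    return np.random.default_rng([int(seed), zlib.crc32(individual_id.encode())])


def observe(traj: TrueTrajectory, sched: ObservationSchedule, seed,
            site: str = "S1") -> pd.DataFrame:
    """Sample a trajectory through the GPS observation model.

    Keeps scheduled fix times falling inside the nightly window and the
    trajectory's time span; jitters the recorded time by U(0, jitter_max)
    minutes (collars log late, never early) and reads the position at the
    trajectory sample nearest the jittered time; then applies dropout,
    gross outliers (uniform in a ring 2000–5000 m out so the speed and jump
    filters can catch them), and occasional poor-quality fixes
    (n_sats = 3 or dop > 4).
    """
    if len(traj.times) < 2:
        return _empty_fix_frame()
    dt = traj.dt
    if abs(sched.fix_interval / dt - round(sched.fix_interval / dt)) > 1e-9:
        raise ValueError("trajectory dt must divide the fix interval")
    rng = np.random.default_rng(seed)
    t_lo, t_hi = traj.times[0], traj.times[-1]

    start_min = sched._minutes(sched.window_start)
    first_day = int(np.floor(t_lo / 1440.0)) - 1
    last_day = int(np.ceil(t_hi / 1440.0)) + 1
    sched_times = np.concatenate([
        sched.night_times(day * 1440.0 + start_min)
        for day in range(first_day, last_day + 1)
    ])
    sched_times = sched_times[(sched_times >= t_lo) & (sched_times <= t_hi)]

    n = len(sched_times)
    if n == 0:
        return _empty_fix_frame()
    keep = rng.random(n) >= sched.dropout_prob
    jitter = (rng.uniform(0.0, sched.jitter_max, n) if sched.jitter_max > 0
              else np.zeros(n))
    t_rec = sched_times + jitter
    idx = np.clip(np.round((t_rec - t_lo) / dt).astype(int), 0, len(traj.times) - 1)
    pos = traj.positions[idx].copy()

    is_outlier = rng.random(n) < sched.outlier_prob
    r = rng.uniform(sched.outlier_scale, 2.5 * sched.outlier_scale, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    pos[is_outlier] += np.column_stack([r * np.cos(phi),
                                        r * np.sin(phi)])[is_outlier]

    n_sats = rng.integers(4, 13, n)
    dop = rng.uniform(0.8, 3.5, n)
    is_bad = rng.random(n) < sched.bad_quality_prob
    bad_kind = rng.random(n) < 0.5
    bad_dop_hi = rng.uniform(4.5, 9.0, n)
    few_sats = is_bad & bad_kind
    n_sats[few_sats] = 3
    dop[is_bad & ~bad_kind] = bad_dop_hi[is_bad & ~bad_kind]

    out = pd.DataFrame({
        "animal_id": traj.individual_id,
        "group_id": traj.group_id,
        "sex": traj.sex,
        "site": site,
        "timestamp": STUDY_EPOCH + pd.to_timedelta(t_rec, unit="min"),
        "x_m": pos[:, 0],
        "y_m": pos[:, 1],
        "n_sats": n_sats,
        "dop": dop,
    })
    return out[keep].reset_index(drop=True)


def _empty_fix_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "animal_id", "group_id", "sex", "site", "timestamp",
        "x_m", "y_m", "n_sats", "dop",
    ])


def default_field(n_groups: int, well_spacing: float = 1200.0,
                  well_depth: float = 450.0, well_width: float = 150.0) -> PotentialField:
    """One well per social group on a near-square lattice."""
    ncol = int(np.ceil(np.sqrt(n_groups)))
    centres = np.array([
        [well_spacing * (g % ncol), well_spacing * (g // ncol)]
        for g in range(n_groups)
    ], dtype=float)
    return PotentialField(
        centres=centres,
        depths=np.full(n_groups, well_depth),
        widths=np.full(n_groups, well_width),
    )


def generate_study(
    n_groups: int,
    badgers_per_group: int,
    months: int,
    sex_effect: float = DEFAULT_SEX_EFFECT,
    month_effects=DEFAULT_MONTH_EFFECTS,
    base_c: float = float(np.exp(3.397)),
    removal_schedule=None,
    seed: int = 0,
    *,
    n_sites: int = 1,
    individual_sd: float = DEFAULT_INDIVIDUAL_SD,
    schedule: ObservationSchedule | None = None,
    field: PotentialField | None = None,
    sim_dt: float = 5.0,
    start_month: int = 1,
    return_trajectories: bool = False,
):
    """Simulate a multi-group GPS collaring study.

    Each group owns one potential well; each animal's per-month diffusion is

        c_im = base_c * exp(sex_effect * 1[female] + month_effect[m] + b_i),

    with b_i ~ N(0, individual_sd^2) an animal-level random intercept.
    Months are true calendar months starting at ``start_month`` of the
    study epoch year; the SDE runs continuously (day and night) and the
    collar samples only the nightly window.
    ``removal_schedule`` — a list of ``(individual_id, timestamp)`` pairs —
    truncates trajectories at the given time, emulating culling-like
    removal of animals mid-study.

    Returns ``(fix_table, truth_table)`` DataFrames; the truth table has
    one row per animal-month with the realised c and well centre.
    """
    if n_groups < 1 or badgers_per_group < 1 or months < 1:
        raise ValueError("counts must be >= 1")
    month_effects = np.asarray(month_effects, dtype=float)
    if month_effects.shape != (12,):
        raise ValueError("month_effects must have 12 entries")
    if schedule is None:
        schedule = ObservationSchedule()
    if field is None:
        field = default_field(n_groups)
    if field.centres.shape[0] < n_groups:
        raise ValueError("field must provide at least one well per group")
    removals = {}
    if removal_schedule:
        for ind, when in removal_schedule:
            when = pd.Timestamp(when)
            t_min = (when - STUDY_EPOCH).total_seconds() / 60.0
            removals[ind] = min(removals.get(ind, np.inf), t_min)

    groups_per_site = int(np.ceil(n_groups / n_sites))
    # calendar month boundaries, in minutes since the study epoch
    month_starts = [
        STUDY_EPOCH + pd.DateOffset(months=start_month - 1 + m)
        for m in range(months + 1)
    ]
    month_t0 = [(ts - STUDY_EPOCH).total_seconds() / 60.0 for ts in month_starts]
    month_steps = [
        int(round((month_t0[m + 1] - month_t0[m]) / sim_dt)) for m in range(months)
    ]

    fix_frames, truth_rows, trajectories = [], [], []
    for g in range(n_groups):
        group_id = f"G{g + 1}"
        site = f"S{g // groups_per_site + 1}"
        centre = field.centres[g]
        for k in range(badgers_per_group):
            ind = f"{group_id}B{k + 1}"
            sex = "female" if k % 2 == 1 else "male"
            rng = _individual_rng(seed, ind)
            b_i = rng.normal(0.0, individual_sd)
            x = centre + rng.normal(0.0, 20.0, size=2)
            t_cut = removals.get(ind, np.inf)

            month_trajs = []
            for m in range(months):
                cal_month = month_starts[m].month
                c_im = base_c * np.exp(
                    (sex_effect if sex == "female" else 0.0)
                    + month_effects[cal_month - 1] + b_i
                )
                t0 = month_t0[m]
                if t0 >= t_cut:
                    break
                sub_seed = rng.integers(0, 2**31)
                traj = simulate_sde(
                    field, c_im, x, sim_dt, month_steps[m], sub_seed,
                    t0=t0, individual_id=ind, group_id=group_id, sex=sex,
                )
                x = traj.positions[-1]
                if traj.times[-1] > t_cut:
                    keep = traj.times <= t_cut
                    traj = replace(traj, times=traj.times[keep],
                                   positions=traj.positions[keep])
                month_trajs.append(traj)
                truth_rows.append({
                    "animal_id": ind, "group_id": group_id, "site": site,
                    "sex": sex, "month": cal_month, "c_true": c_im,
                    "well_x": centre[0], "well_y": centre[1],
                })
            if not month_trajs:
                continue
            full = TrueTrajectory(
                ind, group_id, sex,
                np.concatenate([t.times[:-1] for t in month_trajs[:-1]]
                               + [month_trajs[-1].times]),
                np.concatenate([t.positions[:-1] for t in month_trajs[:-1]]
                               + [month_trajs[-1].positions]),
            )
            trajectories.append(full)
            obs_seed = _individual_rng(seed + 1, ind).integers(0, 2**31)
            fix_frames.append(observe(full, schedule, obs_seed, site=site))

    fixes = (pd.concat(fix_frames, ignore_index=True)
             if fix_frames else _empty_fix_frame())
    truth = pd.DataFrame(truth_rows)
    if return_trajectories:
        return fixes, truth, trajectories
    return fixes, truth
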