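import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import badgermove as bm

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from badgermove.synthetic import STUDY_EPOCH, ObservationSchedule, default_field


def frame_from_trajectory(traj):
    """Fix-table view of a latent trajectory (no observation noise)."""
    return pd.DataFrame({
        "animal_id": traj.individual_id,
        "group_id": traj.group_id,
        "sex": traj.sex,
        "site": "S1",
        "timestamp": STUDY_EPOCH + pd.to_timedelta(traj.times, unit="min"),
        "x_m": traj.positions[:, 0],
        "y_m": traj.positions[:, 1],
        "n_sats": 8,
        "dop": 1.5,
    })


def fix_table(times_min, xy, animal="A1", **overrides):
    """Minimal raw fix table from explicit times (minutes) and coordinates."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    df = pd.DataFrame({
        "animal_id": animal,
        "group_id": overrides.get("group_id", "G1"),
        "sex": overrides.get("sex", "male"),
        "site": overrides.get("site", "S1"),
        "timestamp": STUDY_EPOCH + pd.to_timedelta(np.asarray(times_min, dtype=float), unit="min"),
        "x_m": xy[:, 0],
        "y_m": xy[:, 1],
        "n_sats": overrides.get("n_sats", 8),
        "dop": overrides.get("dop", 1.5),
    })
    return df


@pytest.fixture(scope="session")
def quiet_schedule():
    """Noise-free 20-minute nightly schedule."""
    return ObservationSchedule(fix_interval=20.0)


@pytest.fixture(scope="session")
def four_well_study():
    """Small four-group study with strong metastability, shared across tests."""
    field = default_field(4, well_spacing=1200, well_depth=1500, well_width=150)
    sched = ObservationSchedule(fix_interval=20.0, jitter_max=1.0,
                                dropout_prob=0.05, outlier_prob=0.01,
                                bad_quality_prob=0.02)
    fixes, truth, trajectories = bm.generate_study(
        4, 3, 2, base_c=8.0, seed=7, n_sites=1, individual_sd=0.2,
        schedule=sched, field=field, return_trajectories=True)
    return {"fixes": fixes, "truth": truth, "trajectories": trajectories,
            "schedule": sched, "field": field}


@pytest.fixture(scope="session")
def four_well_clean(four_well_study):
    # cleaned without the origin shift so coordinates stay in the
    # generator's frame and the well centres remain ground truth
    tracks, audit = bm.clean_fixes(four_well_study["fixes"],
                                   four_well_study["schedule"], shift=False)
    return {"tracks": tracks, "audit": audit, **four_well_study}
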