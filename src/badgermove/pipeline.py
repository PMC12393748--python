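"""End-to-end orchestration: simulate -> clean -> diffusion -> glmm ->
koopman -> report.

Every stage is a pure function of (inputs, config, seed); a run writes
each intermediate artifact to the output directory and a manifest
recording seeds, per-stage record counts, timings and artifact
checksums, so identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from datetime import time as dtime
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffusion as diff
from . import koopman as koop
from . import mixed_model as mm
from . import preprocessing as prep
from . import territory
from .synthetic import ObservationSchedule, generate_study


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    # simulation (used when input_csv is None)
    input_csv: str | None = None
    n_groups: int = 4
    badgers_per_group: int = 3
    months: int = 2
    base_c: float = 8.0
    individual_sd: float = 0.2
    n_sites: int = 2
    well_depth: float = 1500.0
    well_width: float = 150.0
    well_spacing: float = 1200.0
    # observation schedule
    window_start: str = "20:00"
    window_end: str = "04:00"
    fix_interval: float = 20.0
    jitter_max: float = 1.0
    dropout_prob: float = 0.05
    outlier_prob: float = 0.01
    bad_quality_prob: float = 0.02
    # cleaning thresholds
    min_sats: int = 4
    max_dop: float = 4.0
    max_speed: float = 26.2
    max_two_step: float = 1500.0
    snap_tolerance: float = 3.0
    max_gap_days: float = 7.0
    exclude_animals: tuple = ()
    # regularisation / EDMD
    interp_dt: float = 20.0
    grid_edge: float = 100.0
    min_box_count: int = 5
    delta: float = 0.05
    n_max: int = 20
    kmeans_restarts: int = 10
    # subsetting for the report
    subset_cols: tuple = ()
    # misc
    seed: int = 0
    out_dir: str = "runs/default"

    def __post_init__(self):
        positive = {
            "fix_interval": self.fix_interval, "max_speed": self.max_speed,
            "max_dop": self.max_dop, "max_two_step": self.max_two_step,
            "snap_tolerance": self.snap_tolerance, "max_gap_days": self.max_gap_days,
            "interp_dt": self.interp_dt, "grid_edge": self.grid_edge,
            "delta": self.delta,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive (got {val})")
        if self.min_sats < 0 or self.n_max < 1 or self.kmeans_restarts < 1:
            raise ValueError("min_sats >= 0, n_max >= 1, kmeans_restarts >= 1")
        ratio = self.fix_interval / self.interp_dt
        if abs(ratio - round(ratio)) > 1e-9 and abs(2 * self.interp_dt - self.fix_interval) > 1e-9:
            raise ValueError("interp_dt must divide the fix interval (or be "
                             "exactly half of it)")

    # --- serialisation -------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["exclude_animals"] = list(self.exclude_animals)
        d["subset_cols"] = list(self.subset_cols)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["exclude_animals"] = tuple(d.get("exclude_animals", ()))
        d["subset_cols"] = tuple(d.get("subset_cols", ()))
        return cls(**d)

    def schedule(self) -> ObservationSchedule:
        hs, ms = map(int, self.window_start.split(":"))
        he, me = map(int, self.window_end.split(":"))
        return ObservationSchedule(
            window_start=dtime(hs, ms), window_end=dtime(he, me),
            fix_interval=self.fix_interval, jitter_max=self.jitter_max,
            dropout_prob=self.dropout_prob, outlier_prob=self.outlier_prob,
            bad_quality_prob=self.bad_quality_prob,
        )


@dataclass
class RunManifest:
    config: RunConfig
    stages: list = dc_field(default_factory=list)

    def record(self, stage: str, n_records: int, seconds: float, artifacts: dict):
        self.stages.append({
            "stage": stage,
            "n_records": int(n_records),
            "seconds": round(seconds, 3),
            "artifacts": artifacts,
        })

    def to_json(self) -> str:
        return json.dumps({
            "config": json.loads(self.config.to_json()),
            "stages": self.stages,
        }, indent=2, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, index=False)
    return {path.name: _checksum(path)}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in fixed order, writing artifacts and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched = config.schedule()
    manifest = RunManifest(config)
    (out / "config.json").write_text(config.to_json())

    # 1. simulate / load ------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.input_csv is not None:
            fixes = pd.read_csv(config.input_csv, parse_dates=["timestamp"])
            truth = None
        else:
            from .synthetic import default_field
            field = default_field(config.n_groups, config.well_spacing,
                                  config.well_depth, config.well_width)
            fixes, truth = generate_study(
                n_groups=config.n_groups,
                badgers_per_group=config.badgers_per_group,
                months=config.months,
                base_c=config.base_c,
                seed=config.seed,
                n_sites=config.n_sites,
                individual_sd=config.individual_sd,
                schedule=sched,
                field=field,
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    arts = _write_csv(fixes, out / "fixes_raw.csv")
    if truth is not None:
        arts.update(_write_csv(truth, out / "truth.csv"))
    manifest.record("simulate", len(fixes), time.perf_counter() - t0, arts)

    # 2. clean ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        tracks, audit = prep.clean_fixes(
            fixes, sched,
            min_sats=config.min_sats, max_dop=config.max_dop,
            max_speed=config.max_speed, max_two_step=config.max_two_step,
            snap_tolerance=config.snap_tolerance,
            max_gap=config.max_gap_days * 1440.0,
            exclude_animals=config.exclude_animals,
        )
        clean = pd.concat([t.fixes.assign(period_id=t.period_id) for t in tracks],
                          ignore_index=True) if tracks else fixes.iloc[:0]
    except Exception as e:  # noqa: BLE001
        raise StageError("clean", e) from e
    arts = _write_csv(clean, out / "fixes_clean.csv")
    (out / "audit.jsonl").write_text(audit.to_jsonl())
    arts["audit.jsonl"] = _checksum(out / "audit.jsonl")
    manifest.record("clean", len(clean), time.perf_counter() - t0, arts)

    # 3. diffusion ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        covariates = (clean[["animal_id", "site", "sex"]]
                      .drop_duplicates("animal_id").assign(capture_year=1))
        estimates = diff.monthly_estimates(tracks, covariates, schedule=sched)
        est_df = diff.estimates_frame(estimates)
    except Exception as e:  # noqa: BLE001
        raise StageError("diffusion", e) from e
    arts = _write_csv(est_df, out / "diffusion.csv")
    manifest.record("diffusion", len(est_df), time.perf_counter() - t0, arts)

    # 4. glmm -----------------------------------------------------------
    t0 = time.perf_counter()
    glmm_art = {}
    try:
        if est_df.empty or est_df["animal_id"].nunique() < 3:
            fit = None
        else:
            fit = mm.fit_glmm(estimates, mm.ModelSpec(include_year_slopes=False))
            glmm_art.update(_write_csv(fit.coefficients, out / "glmm_coefficients.csv"))
            (out / "glmm_fit.json").write_text(json.dumps({
                "model": fit.spec.label(),
                "aic": fit.aic, "bic": fit.bic,
                "residual_sd": fit.residual_sd,
                "random_sd": fit.random_sd,
                "converged": fit.converged,
                "singular": fit.singular,
                "warnings": fit.warnings,
            }, indent=2))
            glmm_art["glmm_fit.json"] = _checksum(out / "glmm_fit.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("glmm", e) from e
    manifest.record("glmm", 0 if fit is None else fit.n_obs,
                    time.perf_counter() - t0, glmm_art)

    # 5 & 6. koopman + report, per site ---------------------------------
    # Each site is shifted to its own (0, 0) base, so the slow-scale
    # analysis (grid, Koopman matrix, partition, hulls) runs per site.
    t0 = time.perf_counter()
    triplets, eigen_rows, part_rows = [], [], []
    summaries, labelled_frames = [], []
    overlay_clusters, overlay_groups = [], []
    n_pairs_total = 0
    for site in sorted(clean["site"].unique()):
        site_tracks = [t for t in tracks if t.fixes["site"].iloc[0] == site]
        site_clean = clean[clean["site"] == site]
        try:
            regular: list[prep.RegularTrack] = []
            for track in site_tracks:
                regular.extend(prep.regularise(track, sched, config.interp_dt))
            pairs = koop.build_pairs(regular)
            grid = koop.build_grid(pairs.all_points, target_edge=config.grid_edge)
            pairs = koop.filter_sparse_pairs(pairs, grid,
                                             min_count=config.min_box_count)
            kmat = koop.prune_spurious_absorbing(
                koop.estimate_koopman(pairs, grid))
            spectral = koop.spectral_decompose(kmat)
            n_meta = koop.spectral_gap(
                spectral.eigenvalues, delta=config.delta,
                n_max=min(config.n_max, kmat.n_states - 1))
            partition = koop.cluster_metastable(
                spectral, n_meta, seed=config.seed,
                n_init=config.kmeans_restarts)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"koopman[{site}]", e) from e
        n_pairs_total += len(pairs)
        jj, ii = np.nonzero(kmat.K)
        triplets.append(pd.DataFrame({
            "site": site, "from_box": kmat.box_indices[jj],
            "to_box": kmat.box_indices[ii], "prob": kmat.K[jj, ii]}))
        eigen_rows.append(pd.DataFrame({
            "site": site, "re": spectral.eigenvalues.real,
            "im": spectral.eigenvalues.imag}))
        part_rows.append(pd.DataFrame({
            "site": site, "box_ix": partition.box_indices % grid.nx,
            "box_iy": partition.box_indices // grid.nx,
            "cluster": partition.box_labels}))
        try:
            summary = territory.summarise_partition(
                partition, site_clean.reset_index(drop=True),
                subset_cols=tuple(config.subset_cols))
        except Exception as e:  # noqa: BLE001
            raise StageError(f"report[{site}]", e) from e
        tab = summary["table"].copy()
        tab.insert(0, "site", site)
        summaries.append(tab)
        lab = site_clean.reset_index(drop=True).copy()
        lab["cluster"] = summary["cluster_labels"]
        labelled_frames.append(lab)
        overlay_clusters.extend(summary["cluster_hulls"]["Total"])
        overlay_groups.extend(summary["group_hulls"]["Total"])

    arts = _write_csv(pd.concat(triplets, ignore_index=True),
                      out / "koopman_triplets.csv")
    arts.update(_write_csv(pd.concat(eigen_rows, ignore_index=True),
                           out / "eigenvalues.csv"))
    arts.update(_write_csv(pd.concat(part_rows, ignore_index=True),
                           out / "partition.csv"))
    manifest.record("koopman", n_pairs_total, time.perf_counter() - t0, arts)

    t0 = time.perf_counter()
    summary_table = pd.concat(summaries, ignore_index=True)
    labelled = pd.concat(labelled_frames, ignore_index=True)
    territory.export_overlay(overlay_clusters, overlay_groups,
                             out / "hull_overlay.geojson")
    arts = _write_csv(summary_table, out / "territory_summary.csv")
    arts.update(_write_csv(labelled, out / "fixes_labelled.csv"))
    arts["hull_overlay.geojson"] = _checksum(out / "hull_overlay.geojson")
    manifest.record("report", len(summary_table), time.perf_counter() - t0, arts)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
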