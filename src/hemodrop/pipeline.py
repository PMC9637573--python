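"""Orchestration: run the full study analysis and emit the report bundle.

The pipeline composes the stages — study generation (or file input), droplet
geometry, thermography reduction, Marangoni analysis, deposit texture and the
statistical layer — into one run driven by a validated configuration. Each
drop is processed in isolation: a failure is logged and flagged without
killing the study (real focus-variation scans can have cracked/no-data
regions). All randomness flows from the single configured seed, recorded in
the run manifest together with a hash of the configuration, which suffices to
reproduce a synthetic run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from . import geometry, marangoni, stats, synthetic, thermography, topography
from .properties import BloodProperties, LogFitModel
from .topography import TextureReport

log = logging.getLogger("hemodrop")

__all__ = ["RunConfig", "ReportBundle", "validate_config", "run_pipeline"]


class PropertiesBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lambda_: float = 0.52
    rho: float = 1.04873
    cp: float = 3617.0
    ht: float = 35.0
    sigma_a: float = -11.5
    sigma_b: float = 88.0

    def to_props(self) -> BloodProperties:
        return BloodProperties(
            lambda_=self.lambda_, rho=self.rho, cp=self.cp, ht=self.ht,
            sigma_fit=LogFitModel(a=self.sigma_a, b=self.sigma_b),
        )


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["synthetic", "files"] = "synthetic"
    seed: int = 0
    out_dir: str = "hemodrop_out"
    # synthetic design
    temperatures: list[float] = [23.0, 37.0, 60.0, 90.0]
    replicates: int = 18
    base_volume_ul: float = 11.0
    # analysis options
    properties: PropertiesBlock = PropertiesBlock()
    alpha_mode: Literal["si", "paper_numeric"] = "si"
    ring_width_px: float = 2.0
    late_window_s: float = 100.0
    thermal_noise_degC: float | None = None
    write_audits: bool = True
    # files mode
    droplet_csvs: list[str] = []
    heightmap_tiffs: list[str] = []
    log_level: str = "INFO"

    @field_validator("replicates")
    @classmethod
    def _positive_reps(cls, v: int) -> int:
        if v < 1:
            raise ValueError("replicates must be >= 1")
        return v

    @field_validator("temperatures")
    @classmethod
    def _temps(cls, v: list[float]) -> list[float]:
        if len(v) < 1:
            raise ValueError("need at least one temperature")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    """Everything a run produces, in memory and on disk.

    drops: one row per drop (geometry, Marangoni and texture descriptors);
    significance: the per-parameter ANOVA/Tukey table (None when the stats
    stage was skipped); regressions: per-parameter T and (T, V) fits;
    manifest: config hash, seed and record count.
    """

    drops: pd.DataFrame
    significance: pd.DataFrame | None
    regressions: dict
    manifest: dict
    out_dir: Path
    failures: list[str] = field(default_factory=list)


def validate_config(path: str | Path) -> RunConfig | list[str]:
    """Load and validate a YAML config; returns the config or all error strings."""
    path = Path(path)
    if not path.exists():
        return [f"{path}: no such file"]
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        return [f"{path}: invalid YAML: {exc}"]
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        return [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]


def _analyze_drop_synthetic(record, config: RunConfig, props: BloodProperties) -> dict:
    cfg = synthetic.default_scenario(record.Ts)
    if config.thermal_noise_degC is not None:
        from dataclasses import replace
        cfg = replace(cfg, thermal_noise_degC=config.thermal_noise_degC)
    row: dict = {
        "record_id": record.record_id,
        "Ts": record.Ts,
        "V0_ul": record.V0_ul,
        "replicate": record.replicate,
    }
    series = synthetic.generate_droplet_series(record, cfg)
    fit = geometry.volume_shrinkage_slope(series)
    row["shrink_slope_ul_s"] = fit.slope
    row["shrink_r2"] = fit.r2
    row["dome_onset_s"] = geometry.detect_dome_formation(series)
    row["D_mm"] = 2.0 * series.base_radius_mm

    t_grid = synthetic.thermal_time_grid(record, cfg)
    ma_t = synthetic.ma_target_function(cfg)(t_grid)
    R_m = series.base_radius_mm * 1e-3
    dT = synthetic.invert_marangoni_to_deltaT(
        ma_t, R_m, props, record.Ts + cfg.T_center_offset_degC,
        alpha_mode=config.alpha_mode,
    )
    frames = synthetic.generate_thermal_frames(record, dT, t_grid, cfg)
    ecs = thermography.edge_center_series(frames, ring_width=config.ring_width_px)
    traj = marangoni.marangoni_series(ecs, R_m, props, alpha_mode=config.alpha_mode)
    row["Ma_final"] = float(traj.Ma[-1])
    try:
        bp = marangoni.detect_breakpoint(traj)
    except ValueError:
        bp = None
    row["ma_breakpoint_s"] = bp
    if bp is not None and bp + config.late_window_s <= traj.t[-1]:
        rates = marangoni.two_segment_rates(traj, bp, window=config.late_window_s)
        row["ma_early_rate"] = rates.early_rate
        row["ma_late_rate"] = rates.late_rate
        row["ma_rate_ratio"] = rates.ratio
    row["regime"] = marangoni.classify_regime(series, traj)

    deposit = synthetic.generate_deposit(record, cfg)
    report = topography.full_report(deposit)
    row.update({k: getattr(report, k) for k in TextureReport.PARAMETERS})
    row["texture_flags"] = ";".join(report.flags)
    return row


def _analyze_drop_files(drop_csv: str | None, hmap_tiff: str | None, idx: int) -> dict:
    row: dict = {"record_id": f"file_{idx:03d}", "Ts": np.nan, "V0_ul": np.nan,
                 "replicate": idx}
    if drop_csv:
        series = geometry.DropletTimeSeries.from_csv(drop_csv)
        fit = geometry.volume_shrinkage_slope(series)
        row["shrink_slope_ul_s"] = fit.slope
        row["shrink_r2"] = fit.r2
        row["dome_onset_s"] = geometry.detect_dome_formation(series)
        row["D_mm"] = 2.0 * series.base_radius_mm
    if hmap_tiff:
        hmap = topography.HeightMap.load(hmap_tiff)
        report = topography.full_report(hmap)
        row.update({k: getattr(report, k) for k in TextureReport.PARAMETERS})
        row["texture_flags"] = ";".join(report.flags)
    return row


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Synthetic mode generates the study from the configured design and seed;
    files mode reads droplet CSVs and height-map TIFFs. Per-drop failures are
    collected in ``failures`` instead of aborting the run. The statistics
    stage runs when every temperature group has at least two drops with
    texture parameters; otherwise it is skipped with a warning.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    props = config.properties.to_props()
    rows: list[dict] = []
    failures: list[str] = []

    if config.mode == "synthetic":
        design = synthetic.StudyDesign(
            temperatures=tuple(config.temperatures),
            replicates=config.replicates,
            base_volume_ul=config.base_volume_ul,
            master_seed=config.seed,
        )
        records = synthetic.generate_study(design)
        for record in records:
            try:
                rows.append(_analyze_drop_synthetic(record, config, props))
            except Exception as exc:  # noqa: BLE001 - per-drop isolation
                log.exception("drop %s failed", record.record_id)
                failures.append(f"{record.record_id}: {exc}")
    else:
        n = max(len(config.droplet_csvs), len(config.heightmap_tiffs))
        for i in range(n):
            csv = config.droplet_csvs[i] if i < len(config.droplet_csvs) else None
            tif = config.heightmap_tiffs[i] if i < len(config.heightmap_tiffs) else None
            try:
                rows.append(_analyze_drop_files(csv, tif, i))
            except Exception as exc:  # noqa: BLE001
                log.exception("input %d failed", i)
                failures.append(f"input_{i}: {exc}")

    drops = pd.DataFrame(rows)
    drops.to_csv(out / "drops.csv", index=False)
    if config.write_audits and rows:
        audits = out / "audits"
        audits.mkdir(exist_ok=True)
        for row in rows:
            (audits / f"{row['record_id']}.json").write_text(
                json.dumps({k: (v if not isinstance(v, float) or np.isfinite(v)
                                else None) for k, v in row.items()}, default=str)
            )

    significance = None
    regressions: dict = {}
    params = [p for p in TextureReport.PARAMETERS if p in drops.columns]
    groups_ok = (
        not drops.empty
        and params
        and drops["Ts"].notna().all()
        and drops["Ts"].nunique() >= 2
        and (drops.groupby("Ts").size() >= 2).all()
    )
    if groups_ok:
        significance, tukeys = stats.significance_table(drops, params)
        significance.to_csv(out / "significance.csv", index=False)
        for param in params:
            slope, intercept, r2_t = stats.regress_vs_temperature(
                drops[param], drops["Ts"])
            entry = {"slope_T": slope, "intercept_T": intercept, "r2_T": r2_t}
            try:
                coef, r2_tv = stats.regress_plane_TV(
                    drops[param], drops["Ts"], drops["V0_ul"])
                entry.update({"coef_TV": list(coef), "r2_TV": r2_tv})
            except ValueError:
                pass
            regressions[param] = entry
        (out / "stats.json").write_text(json.dumps(
            {
                "anova": significance.drop(
                    columns=[c for c in significance.columns if c.startswith("sig_")]
                ).to_dict(orient="records"),
                "regressions": regressions,
            },
            indent=2,
        ))
    else:
        log.warning("statistics stage skipped: fewer than 2 drops per group")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "n_drops": len(rows),
        "n_failures": len(failures),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ReportBundle(drops=drops, significance=significance,
                        regressions=regressions, manifest=manifest,
                        out_dir=out, failures=failures)
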