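"""Orchestration: tie simulate -> analyze -> calibrate -> QC -> hits together.

Two entry points cover the common uses: :func:`run_pipeline` drives a full
screen from files on disk (TIFF manifest + platemap + config) and writes
CSV/PNG artifacts plus a run log, and :func:`screen_records` runs the same
analysis on in-memory wells (as produced by :func:`wellsim.generate_plate`),
which is what the tests and worked examples use.

Calibration is two-pass: control wells are analyzed once with a provisional
zero threshold to collect per-cell ROI statistics, thresholds are derived
from the negative controls, then every well is analyzed with the calibrated
values.  Per-field failures (unreadable TIFF, missing file) degrade
gracefully: the field is treated like an autofocus rejection and the well
is analyzed from its remaining fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import imgcore, platescreen
from .imgcore import AnalysisConfig, FieldImage, InputError
from .platescreen import (
    ROLE_EDGE,
    CalibrationResult,
    PlateSpec,
    WellRecord,
    calibrate_from_controls,
    call_hits,
    choose_hit_threshold,
    control_separation,
    heatmap_matrix,
    qc_nuclei_counts,
    records_to_frame,
    save_heatmap,
)

logger = logging.getLogger("hciscreen")


@dataclass
class ScreenConfig:
    """Plate-level screening settings."""

    k_sigma: float = 5.0
    limit_rule: str | tuple[str, float] = ("sigma", 10.0)
    qc_deviation_fraction: float = 0.5
    hit_threshold_pct: float | None = None  # None -> derive from controls
    exclude_flagged: bool = True
    fixed_threshold: float | None = None  # explicit values skip calibration
    response_limit: float | None = None
    pool: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        d = dict(d)
        lr = d.get("limit_rule", ("sigma", 10.0))
        if isinstance(lr, list):
            lr = (lr[0], float(lr[1]))
        return cls(
            k_sigma=float(d.get("k_sigma", 5.0)),
            limit_rule=lr,
            qc_deviation_fraction=float(d.get("qc_deviation_fraction", 0.5)),
            hit_threshold_pct=d.get("hit_threshold_pct"),
            exclude_flagged=bool(d.get("exclude_flagged", True)),
            fixed_threshold=d.get("fixed_threshold"),
            response_limit=d.get("response_limit"),
            pool=dict(d.get("pool", {})),
        )


@dataclass
class RunConfig:
    """Paths and settings of one reproducible pipeline run."""

    manifest: Path
    platemap: Path
    out_dir: Path
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed: int = 0
    log_level: str = "INFO"
    write_per_cell: bool = False


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON config file as a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def config_hash(analysis: AnalysisConfig, screen: ScreenConfig, seed: int) -> str:
    doc = {
        "analysis": analysis.to_dict(),
        "screen": {
            "k_sigma": screen.k_sigma,
            "limit_rule": list(screen.limit_rule)
            if isinstance(screen.limit_rule, tuple)
            else screen.limit_rule,
            "qc_deviation_fraction": screen.qc_deviation_fraction,
            "hit_threshold_pct": screen.hit_threshold_pct,
            "exclude_flagged": screen.exclude_flagged,
            "fixed_threshold": screen.fixed_threshold,
            "response_limit": screen.response_limit,
            "pool": screen.pool,
        },
        "seed": seed,
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------


def read_platemap(path: str | Path) -> list[WellRecord]:
    """Read a platemap CSV (plate, well, role, clone_id) into records."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"plate", "well", "role"}
    if df.empty or not required <= set(df.columns):
        raise InputError(f"platemap must be a nonempty CSV with columns {sorted(required)}")
    return [
        WellRecord(
            plate_id=row["plate"],
            well_id=row["well"],
            role=row["role"],
            clone_id=row.get("clone_id", ""),
        )
        for _, row in df.iterrows()
    ]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plate", "well", "field", "channel", "path"}
    if not required <= set(df.columns):
        raise InputError(f"manifest must have columns {sorted(required)}")
    return df


def load_well_fields(
    manifest: pd.DataFrame, plate: str, well: str, base_dir: Path
) -> list[FieldImage]:
    """Load one well's fields from TIFFs listed in the manifest.

    A field missing either channel, or whose TIFF cannot be read, is logged
    and skipped (treated like a rejected field).
    """
    sel = manifest[(manifest["plate"] == plate) & (manifest["well"] == well)]
    fields = []
    for fi, grp in sel.groupby("field"):
        chans = {}
        ok = True
        for ch in (1, 2):
            row = grp[grp["channel"] == ch]
            if row.empty:
                logger.warning("%s %s field %s: channel %d missing", plate, well, fi, ch)
                ok = False
                break
            p = base_dir / str(row.iloc[0]["path"])
            try:
                chans[ch] = tifffile.imread(p)
            except (OSError, ValueError) as exc:
                logger.warning("%s %s field %s ch%d unreadable (%s); field rejected",
                               plate, well, fi, ch, exc)
                ok = False
                break
        if ok:
            fields.append(
                FieldImage(ch1=chans[1], ch2=chans[2], well_id=well, field_index=int(fi))
            )
    return fields


# ---------------------------------------------------------------------------
# screening on in-memory records
# ---------------------------------------------------------------------------


def _analyze(records, fields_by_well, config: AnalysisConfig) -> None:
    for rec in records:
        if rec.role == ROLE_EDGE:
            continue
        fields = fields_by_well.get((rec.plate_id, rec.well_id), [])
        if not fields:
            rec.features = None
            rec.qc_flags.add("no_analyzable_fields")
            continue
        features, measurements = imgcore.analyze_well(fields, config)
        rec.features = features
        rec.measurements = measurements


def screen_records(
    records: Sequence[WellRecord],
    fields_by_well: Mapping[tuple[str, str], list[FieldImage]],
    analysis: AnalysisConfig,
    screen: ScreenConfig | None = None,
) -> tuple[list[WellRecord], CalibrationResult, pd.DataFrame, float]:
    """Calibrate on controls, analyze all wells, QC and call hits.

    Returns (records with features, calibration, hit table, hit threshold).
    """
    screen = screen or ScreenConfig()
    records = list(records)

    if screen.fixed_threshold is not None and screen.response_limit is not None:
        calib = CalibrationResult(
            fixed_threshold=float(screen.fixed_threshold),
            response_limit=float(screen.response_limit),
            neg_stats=(float("nan"), float("nan")),
        )
    else:
        controls = [r for r in records if r.role == platescreen.ROLE_NEG]
        _analyze(controls, fields_by_well, analysis.with_thresholds(0.0, 0.0))
        calib = calibrate_from_controls(
            controls, k_sigma=screen.k_sigma, limit_rule=screen.limit_rule
        )

    cfg = analysis.with_thresholds(calib.fixed_threshold, calib.response_limit)
    _analyze(records, fields_by_well, cfg)
    calib.separation = control_separation(records)

    for plate_id in sorted({r.plate_id for r in records}):
        plate_recs = [r for r in records if r.plate_id == plate_id]
        try:
            qc_nuclei_counts(plate_recs, screen.qc_deviation_fraction)
        except InputError:
            logger.warning("plate %s: too few analyzable wells for nuclei QC", plate_id)

    hit_thr = (
        screen.hit_threshold_pct
        if screen.hit_threshold_pct is not None
        else choose_hit_threshold(records)
    )
    hits = call_hits(records, hit_threshold_pct=hit_thr, exclude_flagged=screen.exclude_flagged)
    if screen.pool:
        hits = platescreen.annotate_pool(hits, screen.pool)
    return records, calib, hits, float(hit_thr)


# ---------------------------------------------------------------------------
# full pipeline from files
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute a full screen run from files and write its artifacts.

    Writes per-well features CSV, hit table CSV, per-plate heatmap PNGs, an
    optional per-cell CSV, and a run log recording the config hash, seed and
    every resolved threshold.  Re-running with identical inputs yields
    byte-identical CSV outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    for p in (config.manifest, config.platemap):
        if not Path(p).exists():
            raise InputError(f"required input does not exist: {p}")

    records = read_platemap(config.platemap)
    manifest = read_manifest(config.manifest)
    base_dir = Path(config.manifest).parent

    fields_by_well = {
        (r.plate_id, r.well_id): load_well_fields(manifest, r.plate_id, r.well_id, base_dir)
        for r in records
        if r.role != ROLE_EDGE
    }

    records, calib, hits, hit_thr = screen_records(
        records, fields_by_well, config.analysis, config.screen
    )

    artifacts: dict[str, Path] = {}
    features_csv = out_dir / "well_features.csv"
    records_to_frame(records).to_csv(features_csv, index=False, float_format="%.6g")
    artifacts["well_features"] = features_csv

    hits_csv = out_dir / "hits.csv"
    hits.to_csv(hits_csv, index=False, float_format="%.6g")
    artifacts["hits"] = hits_csv

    if config.write_per_cell:
        rows = []
        for r in records:
            for m in r.measurements or []:
                rows.append(
                    {
                        "plate": r.plate_id,
                        "well": r.well_id,
                        "field": m.field_index,
                        "label": m.label,
                        "centroid_row": m.centroid_rc[0],
                        "centroid_col": m.centroid_rc[1],
                        "area_px": m.area_px,
                        "roi_area_px": m.roi_area_px,
                        "target_area_px": m.target_area_px,
                        "target_avg_intensity": m.target_avg_intensity,
                        "responder": m.responder,
                    }
                )
        cells_csv = out_dir / "cell_measurements.csv"
        pd.DataFrame(rows).to_csv(cells_csv, index=False, float_format="%.6g")
        artifacts["cell_measurements"] = cells_csv

    for plate_id in sorted({r.plate_id for r in records}):
        plate_recs = [r for r in records if r.plate_id == plate_id]
        for feat in ("nuclei_per_field_avg", "pct_cells_high"):
            mat = heatmap_matrix(plate_recs, feat)
            png = out_dir / f"{plate_id}_{feat}.png"
            save_heatmap(mat, str(png), title=f"{plate_id} {feat}")
            artifacts[f"heatmap_{plate_id}_{feat}"] = png

    log_path = out_dir / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"config_hash: {config_hash(config.analysis, config.screen, config.seed)}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"fixed_threshold: {calib.fixed_threshold:.6g}\n")
        fh.write(f"response_limit: {calib.response_limit:.6g}\n")
        fh.write(f"hit_threshold_pct: {hit_thr:.6g}\n")
        fh.write(f"qc_deviation_fraction: {config.screen.qc_deviation_fraction:.6g}\n")
        fh.write(f"focus_relative_cutoff: {config.analysis.focus.relative_cutoff:.6g}\n")
        if calib.separation is not None:
            fh.write(f"control_separation_d: {calib.separation:.6g}\n")
    artifacts["run_log"] = log_path
    return artifacts
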