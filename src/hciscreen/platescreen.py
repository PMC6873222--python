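"""384-well plate logic: layout, clone assignment, calibration, QC, hits.

A standard 384-well plate has 16 rows (A-P) and 24 columns (1-24).  Border
wells are excluded from analysis because of plate edge effects, and two
interior columns (2 and 13 by default) are reserved for negative and
positive control transfections, leaving 280 sample wells per plate.
Negative controls calibrate the ligand-channel fixed threshold and the
cellular response limit; positive controls verify that bound and unbound
populations separate.  Sample wells passing QC are rank-ordered by
``pct_cells_high`` into a hit table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imgcore import CellMeasurement, InputError, ParameterError, WellFeatures, pooled_roi_pixel_stats

ROW_LABELS = "ABCDEFGHIJKLMNOP"

ROLE_SAMPLE = "sample"
ROLE_NEG = "negative_control"
ROLE_POS = "positive_control"
ROLE_EDGE = "edge_excluded"


class LayoutError(ValueError):
    """The plate layout is inconsistent (e.g. control column on the edge)."""


class CalibrationError(ValueError):
    """Controls are insufficient for threshold calibration."""


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> well id like ``"B03"``."""
    return f"{ROW_LABELS[row]}{col + 1:02d}"


def parse_well(well_id: str) -> tuple[int, int]:
    """Well id like ``"B03"`` -> 0-based (row, col)."""
    return ROW_LABELS.index(well_id[0].upper()), int(well_id[1:]) - 1


@dataclass
class PlateSpec:
    """Geometry and role structure of a screening plate.

    ``control_columns`` are 1-based column numbers; within each control
    column the interior rows are split between negative (top half) and
    positive (bottom half) controls by default.
    """

    n_rows: int = 16
    n_cols: int = 24
    control_columns: tuple[int, ...] = (2, 13)
    fields_per_well: int = 4
    neg_fraction_per_column: float = 0.5

    @property
    def interior_wells(self) -> int:
        return (self.n_rows - 2) * (self.n_cols - 2)

    @property
    def n_control_wells(self) -> int:
        return len(self.control_columns) * (self.n_rows - 2)

    @property
    def sample_capacity(self) -> int:
        return self.interior_wells - self.n_control_wells


@dataclass
class WellRecord:
    """One well of a screening plate with its role and results."""

    plate_id: str
    well_id: str
    role: str
    clone_id: str = ""
    features: WellFeatures | None = None
    qc_flags: set[str] = field(default_factory=set)
    measurements: list[CellMeasurement] | None = None

    def __post_init__(self) -> None:
        if self.role == ROLE_EDGE and self.clone_id:
            raise LayoutError(f"edge-excluded well {self.well_id} cannot carry a clone")
        if self.clone_id and self.role != ROLE_SAMPLE:
            raise LayoutError(f"clone in non-sample well {self.well_id} ({self.role})")


@dataclass
class CalibrationResult:
    """Thresholds derived from control wells.

    ``neg_stats`` are the pooled (mean, sd) of ROI pixel intensities across
    negative-control cells; ``separation`` is the standardized distance
    (Cohen's d) between positive- and negative-control ``pct_cells_high``
    distributions when positive controls are available.
    """

    fixed_threshold: float
    response_limit: float
    neg_stats: tuple[float, float]
    separation: float | None = None


# ---------------------------------------------------------------------------
# layout and assignment
# ---------------------------------------------------------------------------


def build_layout(spec: PlateSpec | None = None) -> dict[str, str]:
    """Assign every well of the plate exactly one role.

    Border wells (rows A/P, columns 1/24) are ``edge_excluded``; interior
    wells in the control columns split into negative/positive controls; all
    other interior wells are samples.
    """
    spec = spec or PlateSpec()
    for col in spec.control_columns:
        if col <= 1 or col >= spec.n_cols:
            raise LayoutError(f"control column {col} lies on the excluded edge")
    roles: dict[str, str] = {}
    n_interior_rows = spec.n_rows - 2
    n_neg = int(round(spec.neg_fraction_per_column * n_interior_rows))
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            wid = well_name(r, c)
            if r in (0, spec.n_rows - 1) or c in (0, spec.n_cols - 1):
                roles[wid] = ROLE_EDGE
            elif (c + 1) in spec.control_columns:
                roles[wid] = ROLE_NEG if (r - 1) < n_neg else ROLE_POS
            else:
                roles[wid] = ROLE_SAMPLE
    return roles


def sample_wells(spec: PlateSpec | None = None) -> list[str]:
    """Sample wells of one plate in column-major fill order."""
    spec = spec or PlateSpec()
    wells = []
    for c in range(1, spec.n_cols - 1):
        if (c + 1) in spec.control_columns:
            continue
        for r in range(1, spec.n_rows - 1):
            wells.append(well_name(r, c))
    return wells


def plates_needed(n_clones: int, spec: PlateSpec | None = None) -> int:
    """Number of plates required to array ``n_clones`` clones."""
    spec = spec or PlateSpec()
    if n_clones <= 0:
        raise InputError("need at least one clone")
    return math.ceil(n_clones / spec.sample_capacity)


def assign_clones(
    clone_ids: Sequence[str], spec: PlateSpec | None = None
) -> list[dict[str, WellRecord]]:
    """Array clones onto plates, column-major within the sample region.

    Returns one ``{well_id: WellRecord}`` dict per plate, including edge and
    control records; clones never land in edge or control wells.
    """
    spec = spec or PlateSpec()
    if not clone_ids:
        raise InputError("clone list is empty")
    roles = build_layout(spec)
    order = sample_wells(spec)
    n_plates = plates_needed(len(clone_ids), spec)
    plates: list[dict[str, WellRecord]] = []
    it = iter(clone_ids)
    exhausted = False
    for p in range(n_plates):
        plate_id = f"plate{p + 1}"
        records: dict[str, WellRecord] = {
            wid: WellRecord(plate_id=plate_id, well_id=wid, role=role)
            for wid, role in roles.items()
        }
        if not exhausted:
            for wid in order:
                try:
                    records[wid].clone_id = next(it)
                except StopIteration:
                    exhausted = True
                    break
        plates.append(records)
    return plates


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def threshold_from_intensities(values: Sequence[float], k_sigma: float) -> float:
    """mean + k_sigma * SD (population SD) of an intensity sample."""
    v = np.asarray(values, dtype=np.float64)
    return float(v.mean() + k_sigma * v.std())


def calibrate_from_controls(
    records: Iterable[WellRecord],
    k_sigma: float = 5.0,
    limit_rule: str | tuple[str, float] = ("sigma", 10.0),
    min_neg_cells: int = 50,
) -> CalibrationResult:
    """Derive the fixed threshold and response limit from control wells.

    The fixed threshold is ``mean + k_sigma * SD`` of the ROI pixel
    intensities pooled over all negative-control cells (per-cell moments are
    combined exactly, no pixels stored).  The response limit follows
    ``limit_rule``:

    - ``("sigma", m)`` (default, m = 10): ``mean + m * SD`` — stringent, so
      isolated noise pixels that sneak past the fixed threshold do not flag
      a cell as a responder;
    - ``"equal"``: equal to the fixed threshold;
    - ``("scale", c)``: ``c``-times the fixed threshold.

    The response limit is never below the fixed threshold.
    """
    neg = [r for r in records if r.role == ROLE_NEG and r.measurements]
    neg_cells = [m for r in neg for m in r.measurements]
    if not neg or len(neg_cells) < min_neg_cells:
        raise CalibrationError(
            f"need >= 1 negative-control well with >= {min_neg_cells} cells "
            f"(got {len(neg)} wells, {len(neg_cells)} cells)"
        )
    mean, sd, _ = pooled_roi_pixel_stats(neg_cells)
    fixed = mean + k_sigma * sd
    if limit_rule == "equal":
        limit = fixed
    elif isinstance(limit_rule, tuple) and limit_rule[0] == "sigma":
        limit = mean + float(limit_rule[1]) * sd
    elif isinstance(limit_rule, tuple) and limit_rule[0] == "scale":
        limit = float(limit_rule[1]) * fixed
    else:
        raise ParameterError(f"unknown limit_rule {limit_rule!r}")
    limit = max(limit, fixed)
    return CalibrationResult(
        fixed_threshold=float(fixed),
        response_limit=float(limit),
        neg_stats=(float(mean), float(sd)),
    )


def control_separation(records: Iterable[WellRecord]) -> float | None:
    """Cohen's d between positive- and negative-control pct_cells_high."""
    neg, pos = [], []
    for r in records:
        if r.features is None or r.features.pct_cells_high is None:
            continue
        if r.role == ROLE_NEG:
            neg.append(r.features.pct_cells_high)
        elif r.role == ROLE_POS:
            pos.append(r.features.pct_cells_high)
    if not neg or not pos:
        return None
    neg_a, pos_a = np.asarray(neg), np.asarray(pos)
    pooled_sd = float(np.sqrt((neg_a.var() + pos_a.var()) / 2.0))
    return float((pos_a.mean() - neg_a.mean()) / max(pooled_sd, 1e-12))


def choose_hit_threshold(
    records: Iterable[WellRecord], fallback_pct: float = 10.0
) -> float:
    """Pick a pct_cells_high hit threshold separating the controls.

    Midpoint between the highest negative and lowest positive control when
    they separate cleanly; otherwise the fixed fallback.
    """
    neg, pos = [], []
    for r in records:
        if r.features is None or r.features.pct_cells_high is None:
            continue
        if r.role == ROLE_NEG:
            neg.append(r.features.pct_cells_high)
        elif r.role == ROLE_POS:
            pos.append(r.features.pct_cells_high)
    if neg and pos and min(pos) > max(neg):
        return (max(neg) + min(pos)) / 2.0
    return fallback_pct


# ---------------------------------------------------------------------------
# QC, hit calling, heatmaps
# ---------------------------------------------------------------------------


def qc_nuclei_counts(
    records: Iterable[WellRecord], deviation_fraction: float = 0.5
) -> list[WellRecord]:
    """Flag wells whose nuclei count deviates far below the plate median.

    The median of ``nuclei_per_field_avg`` is computed over analyzable wells
    only (edge wells and null features ignored); wells below
    ``deviation_fraction`` times the median get the ``"low_cells"`` flag,
    and wells with no analyzable fields get ``"no_analyzable_fields"``.
    """
    recs = list(records)
    analyzable = [
        r
        for r in recs
        if r.role != ROLE_EDGE
        and r.features is not None
        and r.features.nuclei_per_field_avg is not None
    ]
    if len(analyzable) < 10:
        raise InputError("nuclei-count QC requires >= 10 analyzable wells")
    med = float(np.median([r.features.nuclei_per_field_avg for r in analyzable]))
    for r in recs:
        if r.role == ROLE_EDGE:
            continue
        if r.features is None or "no_analyzable_fields" in (r.features.flags or set()):
            r.qc_flags.add("no_analyzable_fields")
            continue
        if r.features.nuclei_per_field_avg < deviation_fraction * med:
            r.qc_flags.add("low_cells")
    return recs


def call_hits(
    records: Iterable[WellRecord],
    hit_threshold_pct: float = 10.0,
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Rank sample wells by pct_cells_high into a hit table.

    Only sample wells at or above the threshold (and, optionally, free of QC
    flags) are included; ties break by (plate_id, well_id).  Columns:
    rank, plate_id, well_id, clone_id, pct_cells_high, nuclei_per_field_avg,
    qc_flags.
    """
    rows = []
    for r in records:
        if r.role != ROLE_SAMPLE:
            continue
        if r.features is None or r.features.pct_cells_high is None:
            continue
        if exclude_flagged and r.qc_flags:
            continue
        if r.features.pct_cells_high >= hit_threshold_pct:
            rows.append(
                {
                    "plate_id": r.plate_id,
                    "well_id": r.well_id,
                    "clone_id": r.clone_id,
                    "pct_cells_high": r.features.pct_cells_high,
                    "nuclei_per_field_avg": r.features.nuclei_per_field_avg,
                    "qc_flags": ";".join(sorted(r.qc_flags)),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "well_id",
            "clone_id",
            "pct_cells_high",
            "nuclei_per_field_avg",
            "qc_flags",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            by=["pct_cells_high", "plate_id", "well_id"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def heatmap_matrix(
    records: Iterable[WellRecord],
    feature: str,
    spec: PlateSpec | None = None,
) -> pd.DataFrame:
    """Lay one plate's feature out as a row A-P x column 1-24 matrix.

    Excluded or unanalyzed wells are NaN (the heatmap's "NA" convention).
    """
    spec = spec or PlateSpec()
    if feature not in ("nuclei_per_field_avg", "pct_cells_high"):
        raise ParameterError(f"unknown heatmap feature {feature!r}")
    mat = np.full((spec.n_rows, spec.n_cols), np.nan)
    for r in records:
        row, col = parse_well(r.well_id)
        if r.role == ROLE_EDGE or r.features is None:
            continue
        val = getattr(r.features, feature)
        if val is not None:
            mat[row, col] = val
    return pd.DataFrame(
        mat,
        index=list(ROW_LABELS[: spec.n_rows]),
        columns=range(1, spec.n_cols + 1),
    )


def save_heatmap(matrix: pd.DataFrame, path: str, title: str = "") -> None:
    """Render a plate heatmap to a PNG file (NaN wells drawn blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="viridis", aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), labels=[str(c) for c in matrix.columns], fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), labels=list(matrix.index), fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def annotate_pool(
    hits: pd.DataFrame,
    pool_membership: Mapping[str, str],
    pool_id: str | None = None,
) -> pd.DataFrame:
    """Attach probe-deconvolution notes to a hit table.

    Each hit receives the candidate probe set of the screen's pool; with
    more than one candidate the hit ``needs_deconvolution`` (retest with
    individual probes) — no inference about which probe bound is made.
    """
    if not pool_membership:
        raise InputError("pool membership map is empty")
    candidates = sorted(
        p for p, g in pool_membership.items() if pool_id is None or g == pool_id
    )
    out = hits.copy()
    out["candidate_probes"] = ";".join(candidates)
    out["needs_deconvolution"] = len(candidates) > 1
    return out


def records_to_frame(records: Iterable[WellRecord]) -> pd.DataFrame:
    """Flatten well records to a per-well features table."""
    rows = []
    for r in records:
        f = r.features
        rows.append(
            {
                "plate_id": r.plate_id,
                "well_id": r.well_id,
                "role": r.role,
                "clone_id": r.clone_id,
                "fields_accepted": f.fields_accepted if f else None,
                "nuclei_per_field_avg": f.nuclei_per_field_avg if f else None,
                "n_cells": f.n_cells if f else None,
                "pct_cells_high": f.pct_cells_high if f else None,
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
        )
    return pd.DataFrame(rows)
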