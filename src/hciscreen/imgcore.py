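"""Per-field and per-well image analysis for a two-channel binding assay.

The workflow mirrors a standard high-content "cell health"-style pipeline:
both channels are background-corrected, nuclei in the Hoechst channel (Ch1)
are segmented as primary objects, each nucleus is dilated into a circular
region of interest (ROI) approximating the whole-cell footprint, and the
ligand channel (Ch2) is measured inside the ROI.  A *fixed threshold* keeps
only high-intensity Ch2 pixels for the target identification mask; the mean
of those pixels is the cell's *target average intensity* (defined as 0 when
no pixel passes).  Cells whose target average intensity is at or above a
*response limit* are classified as responders ("high"), and the well-level
readout is the percentage of responders, ``pct_cells_high``.

All thresholds use inclusive (``>=``) comparison.  Coordinates are 0-based
``(row, col)``, row-major; intensities are treated as unitless counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk
from skimage.segmentation import clear_border, watershed


class ParameterError(ValueError):
    """A configuration or parameter value is invalid."""


class InputError(ValueError):
    """An input raster or collection is empty or malformed."""


class MeasurementError(ValueError):
    """A per-cell measurement cannot be carried out (e.g. empty ROI)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FieldImage:
    """One imaged field of a well: two co-registered intensity rasters.

    Parameters
    ----------
    ch1 : ndarray
        Nuclei (Hoechst) channel, 2-D.
    ch2 : ndarray
        Ligand (Alexa488-like) channel, same shape as ``ch1``.
    well_id : str
        Plate coordinate, e.g. ``"B03"``.
    field_index : int
        0-based index of the field within the well.
    """

    ch1: np.ndarray
    ch2: np.ndarray
    well_id: str = ""
    field_index: int = 0

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1)
        self.ch2 = np.asarray(self.ch2)
        if self.ch1.ndim != 2 or self.ch2.ndim != 2:
            raise InputError("channel rasters must be 2-D")
        if self.ch1.shape != self.ch2.shape:
            raise InputError(
                f"channel shapes differ: {self.ch1.shape} vs {self.ch2.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.ch1.shape


@dataclass
class NucleusObject:
    """A segmented primary object (nucleus).

    ``pixels`` is an ``(n, 2)`` integer array of ``(row, col)`` coordinates;
    pixel sets of distinct labels are disjoint by construction.
    """

    label: int
    pixels: np.ndarray
    centroid_rc: tuple[float, float]
    area_px: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class CellMeasurement:
    """Per-cell Ch2 target statistics.

    ``target_avg_intensity`` follows the "-ve = 0" convention: it is the mean
    of the ROI pixels at or above the fixed threshold, and exactly 0 when no
    pixel passes.  ``roi_avg_intensity``/``roi_sd_intensity`` are moments of
    *all* ROI pixels (threshold-independent), retained so that control-based
    calibration can pool pixel statistics without storing pixels.
    """

    label: int
    roi_area_px: int
    target_area_px: int
    target_avg_intensity: float
    roi_avg_intensity: float = 0.0
    roi_sd_intensity: float = 0.0
    responder: bool = False
    field_index: int = 0
    centroid_rc: tuple[float, float] = (float("nan"), float("nan"))
    area_px: int = 0


@dataclass
class WellFeatures:
    """Population statistics for one well.

    When no field survives focus QC the numeric features are ``None`` (never
    fabricated) and the ``"no_analyzable_fields"`` flag is set; a well whose
    accepted fields contain no cells reports ``pct_cells_high = 0`` with the
    ``"no_cells"`` flag.
    """

    fields_accepted: int
    nuclei_per_field_avg: float | None
    n_cells: int
    pct_cells_high: float | None
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class PreprocessParams:
    """Background-removal settings.

    method : {"opening", "median"}
        Background estimator: grey opening with a square window (separable,
        fast at any size) or a median filter.  The window must be much larger
        than a nucleus diameter so foreground objects do not survive into the
        background estimate.
    kernel_px : int
        Side of the estimator window in pixels.
    smooth_sigma : float
        Gaussian sigma applied to the background estimate so the subtracted
        surface varies smoothly; 0 disables.
    """

    method: str = "opening"
    kernel_px: int = 64
    smooth_sigma: float = 8.0


@dataclass
class SegParams:
    """Nuclei-segmentation settings.

    A Gaussian-smoothed Ch1 raster is thresholded (Otsu by default, or a
    fixed value), holes are filled, objects below ``min_area_px`` are
    dropped, and touching nuclei are optionally split with a
    distance-transform watershed seeded at local maxima at least
    ``min_peak_distance_px`` apart.  ``contrast_guard_sd`` rejects blank
    fields: if the foreground/background mean separation after thresholding
    is below this many background standard deviations, no objects are
    returned.
    """

    smoothing_sigma: float = 2.0
    threshold: float | str = "otsu"
    min_area_px: int = 40
    split_touching: bool = True
    fill_holes: bool = True
    exclude_border: bool = False
    min_peak_distance_px: int = 7
    contrast_guard_sd: float = 4.0


@dataclass
class FocusParams:
    """Autofocus-failure rejection settings.

    The sharpness score is the variance of the Laplacian of Ch1.  A field is
    accepted when its score is at least ``relative_cutoff`` times the
    reference median (within-well by default, supplied via
    ``reference_median`` when a plate-wide reference is preferred).
    """

    relative_cutoff: float = 0.5
    reference_median: float | None = None


@dataclass
class AnalysisConfig:
    """Everything needed to analyze a well."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegParams = field(default_factory=SegParams)
    dilation_px: int = 10
    fixed_threshold: float = 200.0
    response_limit: float = 200.0
    focus: FocusParams = field(default_factory=FocusParams)

    def to_dict(self) -> dict:
        return {
            "preprocess": vars(self.preprocess).copy(),
            "segmentation": vars(self.segmentation).copy(),
            "dilation_px": self.dilation_px,
            "fixed_threshold": self.fixed_threshold,
            "response_limit": self.response_limit,
            "focus": vars(self.focus).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(
            preprocess=PreprocessParams(**d.get("preprocess", {})),
            segmentation=SegParams(**d.get("segmentation", {})),
            dilation_px=int(d.get("dilation_px", 10)),
            fixed_threshold=float(d.get("fixed_threshold", 200.0)),
            response_limit=float(d.get("response_limit", 200.0)),
            focus=FocusParams(**d.get("focus", {})),
        )

    def with_thresholds(self, fixed_threshold: float, response_limit: float) -> "AnalysisConfig":
        return replace(self, fixed_threshold=fixed_threshold, response_limit=response_limit)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def preprocess_background(
    raster: np.ndarray, params: PreprocessParams | None = None
) -> np.ndarray:
    """Estimate and subtract a smoothly varying background.

    Returns a float raster of the same shape with negatives clipped to 0; a
    uniform input maps to an all-zero output, and the output never exceeds
    the input at any pixel (the background estimate is non-negative).
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise InputError("empty raster")
    params = params or PreprocessParams()
    img = raster.astype(np.float64)
    k = max(int(params.kernel_px), 1)
    if params.method == "opening":
        bg = ndi.grey_opening(img, size=(k, k), mode="nearest")
    elif params.method == "median":
        bg = ndi.median_filter(img, size=k, mode="nearest")
    else:
        raise ParameterError(f"unknown background method {params.method!r}")
    if params.smooth_sigma and params.smooth_sigma > 0:
        bg = ndi.gaussian_filter(bg, params.smooth_sigma, mode="nearest")
    out = img - bg
    np.clip(out, 0.0, None, out=out)
    return out


def segment_nuclei(
    ch1: np.ndarray, params: SegParams | None = None
) -> list[NucleusObject]:
    """Segment nuclei in the (preprocessed) Ch1 raster as primary objects.

    A blank/noise-only raster returns an empty list.  Objects touching the
    image border are retained unless ``exclude_border`` is set.
    """
    params = params or SegParams()
    img = np.asarray(ch1, dtype=np.float64)
    if img.size == 0:
        raise InputError("empty raster")
    if params.smoothing_sigma > 0:
        img = ndi.gaussian_filter(img, params.smoothing_sigma, mode="nearest")

    if isinstance(params.threshold, str):
        if params.threshold != "otsu":
            raise ParameterError(f"unknown threshold strategy {params.threshold!r}")
        if np.ptp(img) == 0:
            return []
        thr = threshold_otsu(img)
    else:
        thr = float(params.threshold)
    mask = img >= thr
    if not mask.any() or mask.all():
        return []

    # Blank-field guard: Otsu always splits something, so require genuine
    # foreground/background contrast before accepting any objects.
    if isinstance(params.threshold, str) and params.contrast_guard_sd > 0:
        bg_vals = img[~mask]
        sep = img[mask].mean() - bg_vals.mean()
        if sep < params.contrast_guard_sd * max(bg_vals.std(), 1e-12):
            return []

    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)

    if params.split_touching:
        distance = ndi.distance_transform_edt(mask)
        distance_s = ndi.gaussian_filter(distance, 1.0)
        coords = peak_local_max(
            distance_s,
            min_distance=max(int(params.min_peak_distance_px), 1),
            labels=sk_label(mask),
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels = sk_label(mask)
        else:
            labels = watershed(-distance_s, markers, mask=mask)
    else:
        labels = sk_label(mask)

    if params.exclude_border:
        labels = clear_border(labels)

    objects: list[NucleusObject] = []
    next_label = 1
    for prop in regionprops(labels):
        if prop.area < params.min_area_px:
            continue
        objects.append(
            NucleusObject(
                label=next_label,
                pixels=np.asarray(prop.coords, dtype=np.intp),
                centroid_rc=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_px=int(prop.area),
            )
        )
        next_label += 1
    return objects


def build_roi(
    nucleus: NucleusObject, dilation_px: int, field_shape: tuple[int, int]
) -> np.ndarray:
    """Expand a nucleus into its circular whole-cell ROI.

    The ROI is the morphological dilation of the nucleus mask by a disk of
    radius ``dilation_px``, clipped to the field bounds; it always contains
    the nucleus pixels.  Returns an ``(n, 2)`` array of ``(row, col)``
    coordinates.
    """
    if dilation_px < 0:
        raise ParameterError("dilation_px must be >= 0")
    if dilation_px == 0:
        return nucleus.pixels.copy()
    d = int(dilation_px)
    rmin = max(int(nucleus.pixels[:, 0].min()) - d, 0)
    rmax = min(int(nucleus.pixels[:, 0].max()) + d, field_shape[0] - 1)
    cmin = max(int(nucleus.pixels[:, 1].min()) - d, 0)
    cmax = min(int(nucleus.pixels[:, 1].max()) + d, field_shape[1] - 1)
    local = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    local[nucleus.pixels[:, 0] - rmin, nucleus.pixels[:, 1] - cmin] = True
    dilated = ndi.binary_dilation(local, structure=disk(d))
    rr, cc = np.nonzero(dilated)
    return np.column_stack((rr + rmin, cc + cmin)).astype(np.intp)


def measure_target(
    ch2: np.ndarray,
    roi: np.ndarray,
    fixed_threshold: float,
    label: int = 0,
) -> CellMeasurement:
    """Measure a cell's Ch2 target statistics inside its ROI.

    Target pixels are the ROI pixels with intensity at or above the fixed
    threshold; ``target_avg_intensity`` is their mean, or 0 when none pass.
    """
    if fixed_threshold < 0:
        raise ParameterError("fixed_threshold must be >= 0")
    roi = np.asarray(roi)
    if roi.size == 0:
        raise MeasurementError("empty ROI")
    vals = np.asarray(ch2, dtype=np.float64)[roi[:, 0], roi[:, 1]]
    sel = vals >= fixed_threshold
    n_target = int(sel.sum())
    tai = float(vals[sel].mean()) if n_target else 0.0
    return CellMeasurement(
        label=label,
        roi_area_px=int(vals.size),
        target_area_px=n_target,
        target_avg_intensity=tai,
        roi_avg_intensity=float(vals.mean()),
        roi_sd_intensity=float(vals.std()),
    )


def classify_response(
    measurements: Sequence[CellMeasurement], response_limit: float
) -> tuple[list[CellMeasurement], float]:
    """Flag responders and compute the percent of "high" cells.

    A cell responds when its target average intensity is at or above the
    response limit (inclusive).  Empty input yields 0%.
    """
    if response_limit < 0:
        raise ParameterError("response_limit must be >= 0")
    out = list(measurements)
    n_high = 0
    for m in out:
        m.responder = m.target_avg_intensity >= response_limit
        n_high += int(m.responder)
    pct = 100.0 * n_high / len(out) if out else 0.0
    return out, pct


def focus_score(ch1: np.ndarray) -> float:
    """Variance-of-Laplacian sharpness score of the nuclei channel."""
    return float(ndi.laplace(np.asarray(ch1, dtype=np.float64)).var())


def assess_focus(
    fieldimg: FieldImage, params: FocusParams | None = None
) -> tuple[float, bool]:
    """Score one field and accept/reject it against a reference median.

    Without a ``reference_median`` a single field is always accepted; batch
    acceptance against the within-well median is done by
    :func:`assess_focus_batch`.
    """
    params = params or FocusParams()
    score = focus_score(fieldimg.ch1)
    if params.reference_median is None:
        return score, True
    return score, score >= params.relative_cutoff * params.reference_median


def assess_focus_batch(
    fields: Sequence[FieldImage], params: FocusParams | None = None
) -> list[tuple[float, bool]]:
    """Score a group of fields and accept those near the group median.

    The reference is ``params.reference_median`` when given (e.g. a
    plate-wide median), otherwise the median score of the group itself, so
    identical fields are all accepted.
    """
    params = params or FocusParams()
    scores = [focus_score(f.ch1) for f in fields]
    ref = params.reference_median
    if ref is None:
        ref = float(np.median(scores)) if scores else 0.0
    cutoff = params.relative_cutoff * ref
    return [(s, s >= cutoff) for s in scores]


def analyze_well(
    fields: Sequence[FieldImage], config: AnalysisConfig
) -> tuple[WellFeatures, list[CellMeasurement]]:
    """Run the full per-well analysis: focus QC, segmentation, measurement.

    Fields failing focus QC are excluded from every statistic:
    ``nuclei_per_field_avg`` averages accepted fields only, and cell
    measurements are pooled across accepted fields before classification.
    If every field is rejected the well is flagged ``no_analyzable_fields``
    and the numeric features are ``None``.
    """
    if not fields:
        raise InputError("analyze_well requires at least one field")
    focus = assess_focus_batch(fields, config.focus)
    accepted = [f for f, (_, ok) in zip(fields, focus) if ok]
    flags: set[str] = set()
    if not accepted:
        return (
            WellFeatures(
                fields_accepted=0,
                nuclei_per_field_avg=None,
                n_cells=0,
                pct_cells_high=None,
                flags={"no_analyzable_fields"},
            ),
            [],
        )

    measurements: list[CellMeasurement] = []
    per_field_counts: list[int] = []
    for f in accepted:
        ch1 = preprocess_background(f.ch1, config.preprocess)
        ch2 = preprocess_background(f.ch2, config.preprocess)
        nuclei = segment_nuclei(ch1, config.segmentation)
        per_field_counts.append(len(nuclei))
        for nuc in nuclei:
            roi = build_roi(nuc, config.dilation_px, f.shape)
            m = measure_target(ch2, roi, config.fixed_threshold, label=nuc.label)
            m.field_index = f.field_index
            m.centroid_rc = nuc.centroid_rc
            m.area_px = nuc.area_px
            measurements.append(m)

    measurements, pct = classify_response(measurements, config.response_limit)
    if not measurements:
        flags.add("no_cells")
        pct = 0.0
    features = WellFeatures(
        fields_accepted=len(accepted),
        nuclei_per_field_avg=float(np.mean(per_field_counts)),
        n_cells=len(measurements),
        pct_cells_high=pct,
        flags=flags,
    )
    return features, measurements


def pooled_roi_pixel_stats(
    measurements: Iterable[CellMeasurement],
) -> tuple[float, float, int]:
    """Pool per-cell ROI pixel moments into (mean, sd, n) over all pixels.

    Uses each cell's ``(roi_area_px, roi_avg_intensity, roi_sd_intensity)``
    so no pixel values need to be retained; SDs are population (ddof=0).
    """
    n_tot = 0
    s1 = 0.0
    s2 = 0.0
    for m in measurements:
        n = m.roi_area_px
        n_tot += n
        s1 += n * m.roi_avg_intensity
        s2 += n * (m.roi_sd_intensity**2 + m.roi_avg_intensity**2)
    if n_tot == 0:
        raise InputError("no ROI pixels to pool")
    mean = s1 / n_tot
    var = max(s2 / n_tot - mean**2, 0.0)
    return mean, float(np.sqrt(var)), n_tot
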