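"""Seeded synthetic two-channel fluorescence fields, wells and plates.

The simulator emulates the signal structure of a cell-surface binding assay
imaged at ~20x in two channels: Hoechst-stained nuclei rendered as
soft-edged disks in Ch1, and ligand binding rendered in Ch2 as an annular
membrane ring around the nucleus of each *bound* cell.  Cells are placed by
rejection sampling with a minimum centre spacing (a clumping mode relaxes
the spacing to create touching nuclei for segmentation stress tests); a
transfected flag is drawn per cell and a bound flag per transfected cell,
so ``bound => transfected`` always.  Both channels receive a constant
background, additive Gaussian noise and optional Gaussian defocus blur,
and are clipped/quantized to the configured bit depth.

Every generated field carries its ground truth (cell centres, radii,
transfected/bound flags), which is what makes the downstream analysis
pipeline verifiable without an instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile

from .imgcore import FieldImage
from .platescreen import PlateSpec, ROLE_EDGE, ROLE_NEG, build_layout


class SimParameterError(ValueError):
    """A simulation parameter violates its constraints."""


class GenerationError(RuntimeError):
    """Generation is infeasible (e.g. field too small for the min spacing)."""


class ConfigurationError(ValueError):
    """Plate generation is missing required per-role parameters."""


def _pair(x) -> tuple[float, float]:
    if np.isscalar(x):
        return float(x), float(x)
    a, b = x
    return float(a), float(b)


@dataclass
class SimParams:
    """Knobs of the field simulator.

    Two-valued fields ``nucleus_radius_px``, ``ch1_signal`` and
    ``ch2_ring_signal`` are (mean, SD) pairs; ``background_level`` and
    ``noise_sd`` are per-channel (Ch1, Ch2) pairs, with a scalar applied to
    both.  ``bound_fraction`` is the fraction of *transfected* cells that
    display the membrane ring.  The default field is 1104x1104 px at a
    notional 20x scale with ~50 cells, matching a well seeded at 10,000
    cells imaged one field at a time.
    """

    field_height_px: int = 1104
    field_width_px: int = 1104
    bit_depth: int = 16
    n_cells_mean: float = 50.0
    nucleus_radius_px: tuple[float, float] = (10.0, 1.5)
    min_center_spacing_px: float = 32.0
    transfected_fraction: float = 0.4
    bound_fraction: float = 1.0
    ch1_signal: tuple[float, float] = (3000.0, 400.0)
    ch2_ring_signal: tuple[float, float] = (2500.0, 300.0)
    ch2_ring_width_px: float = 4.0
    membrane_offset_px: float = 3.0
    background_level: tuple[float, float] = (400.0, 300.0)
    noise_sd: tuple[float, float] = (60.0, 50.0)
    defocus_sigma_px: float = 0.0
    clump_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.nucleus_radius_px = _pair(self.nucleus_radius_px)
        self.ch1_signal = _pair(self.ch1_signal)
        self.ch2_ring_signal = _pair(self.ch2_ring_signal)
        self.background_level = _pair(self.background_level)
        self.noise_sd = _pair(self.noise_sd)
        self.validate()

    def validate(self) -> None:
        if self.bit_depth not in (8, 16):
            raise SimParameterError("bit_depth must be 8 or 16")
        if self.field_height_px <= 0 or self.field_width_px <= 0:
            raise SimParameterError("field dimensions must be positive")
        for name in ("transfected_fraction", "bound_fraction", "clump_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimParameterError(f"{name} must be in [0, 1], got {v}")
        nonneg = {
            "n_cells_mean": self.n_cells_mean,
            "min_center_spacing_px": self.min_center_spacing_px,
            "ch2_ring_width_px": self.ch2_ring_width_px,
            "membrane_offset_px": self.membrane_offset_px,
            "defocus_sigma_px": self.defocus_sigma_px,
            "nucleus_radius_mean": self.nucleus_radius_px[0],
            "nucleus_radius_sd": self.nucleus_radius_px[1],
            "ch1_signal_mean": self.ch1_signal[0],
            "ch1_signal_sd": self.ch1_signal[1],
            "ch2_ring_mean": self.ch2_ring_signal[0],
            "ch2_ring_sd": self.ch2_ring_signal[1],
            "background_ch1": self.background_level[0],
            "background_ch2": self.background_level[1],
            "noise_sd_ch1": self.noise_sd[0],
            "noise_sd_ch2": self.noise_sd[1],
        }
        for name, v in nonneg.items():
            if v < 0:
                raise SimParameterError(f"{name} must be >= 0, got {v}")

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimParams":
        return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})


@dataclass
class GroundTruthCell:
    center_rc: tuple[float, float]
    nucleus_radius: float
    transfected: bool
    bound: bool

    def __post_init__(self) -> None:
        if self.bound and not self.transfected:
            raise SimParameterError("bound cell must be transfected")


@dataclass
class FieldTruth:
    """Ground truth of one generated field."""

    cells: list[GroundTruthCell]
    params: SimParams
    true_bound_fraction: float = dc_field(init=False)

    def __post_init__(self) -> None:
        n = len(self.cells)
        self.true_bound_fraction = (
            sum(c.bound for c in self.cells) / n if n else 0.0
        )


@dataclass
class PlateWellSim:
    """All simulated fields of one well plus their ground truths."""

    well_id: str
    role: str
    fields: list[FieldImage]
    truths: list[FieldTruth]

    @property
    def true_bound_fraction(self) -> float:
        cells = [c for t in self.truths for c in t.cells]
        return sum(c.bound for c in cells) / len(cells) if cells else 0.0


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------


def _place_cells(params: SimParams, rng: np.random.Generator) -> list[dict]:
    """Rejection-sample cell centres, radii and flags.

    Feasibility is checked against the requested *mean* density: if the
    exclusion disks of ``n_cells_mean`` cells would cover more than half the
    field, generation fails deterministically.  Random draws above the
    random-sequential-adsorption packing limit are capped so tail draws of
    the Poisson cell count cannot jam the sampler.
    """
    h, w = params.field_height_px, params.field_width_px
    excl = np.pi * (params.min_center_spacing_px / 2.0) ** 2
    if excl > 0 and params.n_cells_mean * excl > 0.5 * h * w:
        raise GenerationError(
            f"field {h}x{w} too small for n_cells_mean={params.n_cells_mean} at "
            f"min_center_spacing_px={params.min_center_spacing_px}"
        )
    n = int(rng.poisson(params.n_cells_mean))
    if excl > 0:
        n = min(n, int(0.45 * h * w / excl))
    r_mean, r_sd = params.nucleus_radius_px
    cells: list[dict] = []
    max_attempts = 200
    for _ in range(n):
        radius = float(
            np.clip(rng.normal(r_mean, r_sd), max(0.3 * r_mean, 1.0), 2.0 * r_mean)
        )
        margin = radius
        if h - 2 * margin <= 1 or w - 2 * margin <= 1:
            raise GenerationError(
                f"field {h}x{w} too small for nucleus radius {radius:.1f}"
            )
        clump = bool(cells) and rng.random() < params.clump_fraction
        placed = False
        for _ in range(max_attempts):
            if clump:
                anchor = cells[int(rng.integers(len(cells)))]
                dist = (anchor["radius"] + radius) * rng.uniform(0.9, 1.25)
                theta = rng.uniform(0, 2 * np.pi)
                rr = anchor["center"][0] + dist * np.sin(theta)
                cc = anchor["center"][1] + dist * np.cos(theta)
                if not (margin <= rr < h - margin and margin <= cc < w - margin):
                    continue
                ok = all(
                    np.hypot(rr - c["center"][0], cc - c["center"][1])
                    >= 0.9 * (c["radius"] + radius)
                    for c in cells
                    if c is not anchor
                )
            else:
                rr = rng.uniform(margin, h - margin)
                cc = rng.uniform(margin, w - margin)
                ok = all(
                    np.hypot(rr - c["center"][0], cc - c["center"][1])
                    >= params.min_center_spacing_px
                    for c in cells
                )
            if ok:
                placed = True
                break
        if not placed:
            # Near the packing limit placement can jam; keep what was placed.
            continue
        transfected = bool(rng.random() < params.transfected_fraction)
        bound = bool(transfected and rng.random() < params.bound_fraction)
        amp1 = max(float(rng.normal(*params.ch1_signal)), 0.0)
        amp2 = max(float(rng.normal(*params.ch2_ring_signal)), 0.0)
        cells.append(
            {
                "center": (rr, cc),
                "radius": radius,
                "transfected": transfected,
                "bound": bound,
                "amp1": amp1,
                "amp2": amp2,
            }
        )
    return cells


def _add_patch(img: np.ndarray, center: tuple[float, float], extent: float, values_fn) -> None:
    h, w = img.shape
    r0 = max(int(np.floor(center[0] - extent)), 0)
    r1 = min(int(np.ceil(center[0] + extent)) + 1, h)
    c0 = max(int(np.floor(center[1] - extent)), 0)
    c1 = min(int(np.ceil(center[1] + extent)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d = np.hypot(rr - center[0], cc - center[1])
    img[r0:r1, c0:c1] += values_fn(d)


def generate_field(
    params: SimParams, seed: int | None = None
) -> tuple[FieldImage, FieldTruth]:
    """Generate one two-channel field with its ground truth.

    Identical ``(params, seed)`` yields bit-identical images and truth.
    Ch1 holds one soft-edged nucleus disk per cell; Ch2 holds a membrane
    ring (annulus of width ``ch2_ring_width_px`` at radius
    ``nucleus_radius + membrane_offset_px``) for each bound cell.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cells = _place_cells(params, rng)
    h, w = params.field_height_px, params.field_width_px

    ch1 = np.full((h, w), params.background_level[0], dtype=np.float64)
    ch2 = np.full((h, w), params.background_level[1], dtype=np.float64)
    edge = 0.8  # Gaussian falloff scale (px) at the nucleus rim
    for c in cells:
        r = c["radius"]
        _add_patch(
            ch1,
            c["center"],
            r + 4 * edge,
            lambda d, amp=c["amp1"], r=r: amp
            * np.where(d <= r, 1.0, np.exp(-((d - r) ** 2) / (2 * edge**2))),
        )
        if c["bound"]:
            ring_r = r + params.membrane_offset_px
            half_w = params.ch2_ring_width_px / 2.0
            _add_patch(
                ch2,
                c["center"],
                ring_r + half_w + 1.5,
                lambda d, amp=c["amp2"], q=ring_r, hw=half_w: amp
                * np.clip(hw + 0.5 - np.abs(d - q), 0.0, 1.0),
            )

    if params.defocus_sigma_px > 0:
        ch1 = ndi.gaussian_filter(ch1, params.defocus_sigma_px, mode="nearest")
        ch2 = ndi.gaussian_filter(ch2, params.defocus_sigma_px, mode="nearest")
    ch1 += rng.normal(0.0, params.noise_sd[0], size=(h, w))
    ch2 += rng.normal(0.0, params.noise_sd[1], size=(h, w))

    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    ch1 = np.clip(np.rint(ch1), 0, params.max_intensity).astype(dtype)
    ch2 = np.clip(np.rint(ch2), 0, params.max_intensity).astype(dtype)

    truth = FieldTruth(
        cells=[
            GroundTruthCell(
                center_rc=c["center"],
                nucleus_radius=c["radius"],
                transfected=c["transfected"],
                bound=c["bound"],
            )
            for c in cells
        ],
        params=params,
    )
    return FieldImage(ch1=ch1, ch2=ch2), truth


def apply_defocus(image: FieldImage, sigma: float) -> FieldImage:
    """Gaussian-blur both channels, emulating an autofocus failure.

    ``sigma = 0`` returns an identical copy.  Blur conserves total intensity
    up to boundary effects and dtype rounding.
    """
    if sigma < 0:
        raise SimParameterError("defocus sigma must be >= 0")
    if sigma == 0:
        return FieldImage(
            ch1=image.ch1.copy(),
            ch2=image.ch2.copy(),
            well_id=image.well_id,
            field_index=image.field_index,
        )
    out = []
    for ch in (image.ch1, image.ch2):
        blurred = ndi.gaussian_filter(ch.astype(np.float64), sigma, mode="nearest")
        info = np.iinfo(ch.dtype) if np.issubdtype(ch.dtype, np.integer) else None
        if info is not None:
            blurred = np.clip(np.rint(blurred), info.min, info.max).astype(ch.dtype)
        out.append(blurred)
    return FieldImage(
        ch1=out[0], ch2=out[1], well_id=image.well_id, field_index=image.field_index
    )


# ---------------------------------------------------------------------------
# plate generation and export
# ---------------------------------------------------------------------------


def _field_seed(seed: int, well_index: int, field_index: int) -> int:
    return int(
        np.random.SeedSequence([seed, well_index, field_index]).generate_state(1)[0]
    )


def generate_plate(
    layout: PlateSpec | Mapping[str, str],
    per_role_params: Mapping[str, SimParams],
    seed: int,
    fields_per_well: int | None = None,
    per_well_overrides: Mapping[str, SimParams] | None = None,
) -> dict[str, PlateWellSim]:
    """Generate every analyzable well of a plate, seeded per (well, field).

    ``per_role_params`` maps each role used by the layout (sample,
    negative_control, positive_control) to its simulation parameters;
    negative-control wells are forced to ``bound_fraction = 0``.
    ``per_well_overrides`` lets individual wells (e.g. planted positives)
    deviate from their role's defaults.  Seeding is per (well, field) so
    output is independent of iteration order and bit-reproducible.
    """
    if isinstance(layout, PlateSpec):
        spec = layout
        roles = build_layout(spec)
        if fields_per_well is None:
            fields_per_well = spec.fields_per_well
    else:
        roles = dict(layout)
        if fields_per_well is None:
            fields_per_well = 4
    if fields_per_well < 1:
        raise ConfigurationError("fields_per_well must be >= 1")

    overrides = dict(per_well_overrides or {})
    wells = sorted(wid for wid, role in roles.items() if role != ROLE_EDGE)
    out: dict[str, PlateWellSim] = {}
    for wi, wid in enumerate(wells):
        role = roles[wid]
        if wid in overrides:
            params = overrides[wid]
        else:
            if role not in per_role_params:
                raise ConfigurationError(f"no SimParams configured for role {role!r}")
            params = per_role_params[role]
        if role == ROLE_NEG:
            params = replace(params, bound_fraction=0.0)
        fields, truths = [], []
        for fi in range(fields_per_well):
            img, truth = generate_field(params, seed=_field_seed(seed, wi, fi))
            img.well_id = wid
            img.field_index = fi
            fields.append(img)
            truths.append(truth)
        out[wid] = PlateWellSim(well_id=wid, role=role, fields=fields, truths=truths)
    return out


def write_plate(
    plate: Mapping[str, PlateWellSim],
    out_dir: str | Path,
    plate_id: str = "plate1",
) -> pd.DataFrame:
    """Write a simulated plate to disk: TIFFs, truth sidecars, manifest.

    Per-field grayscale TIFFs are named ``<plate>_<well>_f<field>_ch<1|2>.tif``,
    each well gets a JSON ground-truth sidecar, and the returned manifest
    (also written as ``manifest.csv``) lists every image file with columns
    plate, well, field, channel, path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for wid in sorted(plate):
        sim = plate[wid]
        for img in sim.fields:
            for ch_idx, raster in ((1, img.ch1), (2, img.ch2)):
                name = f"{plate_id}_{wid}_f{img.field_index}_ch{ch_idx}.tif"
                tifffile.imwrite(out_dir / name, raster)
                rows.append(
                    {
                        "plate": plate_id,
                        "well": wid,
                        "field": img.field_index,
                        "channel": ch_idx,
                        "path": name,
                    }
                )
        truth_doc = {
            "well_id": wid,
            "role": sim.role,
            "true_bound_fraction": sim.true_bound_fraction,
            "fields": [
                {
                    "field_index": i,
                    "true_bound_fraction": t.true_bound_fraction,
                    "cells": [
                        {
                            "center_rc": list(c.center_rc),
                            "nucleus_radius": c.nucleus_radius,
                            "transfected": c.transfected,
                            "bound": c.bound,
                        }
                        for c in t.cells
                    ],
                }
                for i, t in enumerate(sim.truths)
            ],
        }
        with open(out_dir / f"{plate_id}_{wid}_truth.json", "w") as fh:
            json.dump(truth_doc, fh, indent=1)
    manifest = pd.DataFrame(rows, columns=["plate", "well", "field", "channel", "path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
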