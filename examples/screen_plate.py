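"""Run a small calibrated screen fully in memory.

Builds a toy plate layout (two negative-control wells, two positive
controls, four sample wells with one planted positive), simulates every
field, calibrates the fixed threshold and response limit from the negative
controls, analyzes all wells, and calls hits.
"""

from dataclasses import replace

from hciscreen import (
    AnalysisConfig,
    PreprocessParams,
    ScreenConfig,
    SegParams,
    SimParams,
    WellRecord,
    generate_plate,
)
from hciscreen.pipeline import screen_records
from hciscreen.platescreen import ROLE_NEG, ROLE_POS, ROLE_SAMPLE

layout = {
    "B02": ROLE_NEG, "C02": ROLE_NEG,
    "B13": ROLE_POS, "C13": ROLE_POS,
    "B03": ROLE_SAMPLE, "C03": ROLE_SAMPLE, "D03": ROLE_SAMPLE, "E03": ROLE_SAMPLE,
}

base = SimParams(
    field_height_px=192, field_width_px=192, n_cells_mean=22,
    nucleus_radius_px=(5.0, 0.6), min_center_spacing_px=24.0,
    membrane_offset_px=2.0, ch2_ring_width_px=3.0,
    transfected_fraction=0.4, bound_fraction=0.0,
)
positive = replace(base, bound_fraction=1.0, transfected_fraction=0.5)

plate = generate_plate(
    layout,
    {ROLE_SAMPLE: base, ROLE_NEG: base, ROLE_POS: positive},
    seed=5,
    fields_per_well=4,
    per_well_overrides={"D03": positive},  # the planted positive sample
)

records = [
    WellRecord(plate_id="demo", well_id=w, role=r,
               clone_id=f"clone_{w}" if r == ROLE_SAMPLE else "")
    for w, r in layout.items()
]
fields = {("demo", w): plate[w].fields for w in plate}
config = AnalysisConfig(
    preprocess=PreprocessParams(kernel_px=32, smooth_sigma=5.0),
    segmentation=SegParams(smoothing_sigma=1.5, min_area_px=20, min_peak_distance_px=7),
    dilation_px=8,
)

records, calibration, hits, hit_threshold = screen_records(
    records, fields, config, ScreenConfig()
)

print(f"calibrated fixed threshold: {calibration.fixed_threshold:.0f}")
print(f"calibrated response limit:  {calibration.response_limit:.0f}")
print(f"hit threshold (% high):     {hit_threshold:.1f}")
for r in records:
    if r.features:
        print(f"  {r.well_id} [{r.role:16s}] % high = {r.features.pct_cells_high:5.1f}")
print("\nhit table:")
print(hits.to_string(index=False))
# Only the planted positive well should appear in the hit table; negative
# controls stay at ~0% high under the calibrated thresholds.
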