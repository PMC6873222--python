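# hciscreen

High-content screening analytics for cell-surface ligand-binding assays.

Extracellular receptor–ligand interactions are mostly low-affinity, which
makes them hard to detect biochemically. A cell-based alternative
overexpresses full-length receptors in 384-well plates, probes the live
cells with highly avid (pentamerized) recombinant ectodomains, and images
each well in two fluorescence channels: nuclei (Hoechst) and a fluorescently
labelled antibody reporting ligand binding at the cell surface. `hciscreen`
implements the complete computational side of such a screen — and a seeded
synthetic image generator with per-cell ground truth so every stage can be
verified without a microscope.

## The readout

For each imaged field, nuclei in channel 1 are segmented as *primary
objects*; each nucleus is dilated into a circular region of interest (ROI)
approximating the whole-cell footprint; a *fixed threshold* T keeps only
high-intensity channel-2 pixels inside the ROI, and the cell's *target
average intensity* is

    I_cell = mean{ ch2[p] : p in ROI, ch2[p] >= T }    (0 if no pixel passes)

A cell with `I_cell >= L` (the *response limit*) is a responder, and the
well-level readout is

    % Cells High = 100 * (# responders) / (# cells analyzed)

T and L are calibrated from negative-control wells as `mean + k·SD` of the
pooled ROI pixel intensities (k = 5 for T; a more stringent multiple for L).
Plate logic excludes border wells (edge effects), reserves interior columns
2 and 13 for controls (leaving 280 sample wells of the 308 interior wells),
flags wells with anomalous nuclei counts, rejects out-of-focus fields by a
variance-of-Laplacian score relative to the well median, and rank-orders
sample wells into a hit table. A small utility normalizes probe
concentrations from β-lactamase/nitrocefin hydrolysis rates (OLS slope of
A485 vs. time).

## Worked example

`examples/analyze_well.py` simulates one 640×640 px field with ~200 cells
(40% of them displaying a membrane ring of ligand signal) and analyzes it:

```
nuclei segmented:   216 (truth: 216)
% cells high:       39.8
truth bound %:      39.8
responder cells:    86 of 216
```

All 216 simulated nuclei are recovered and the measured % Cells High equals
the ground-truth bound fraction. `examples/screen_plate.py` runs a small
calibrated screen with a planted positive among four sample wells:

```
calibrated fixed threshold: 390
calibrated response limit:  643
hit threshold (% high):     26.1
  B02 [negative_control] % high =   0.0
  C02 [negative_control] % high =   0.0
  B13 [positive_control] % high =  52.3
  ...
 rank plate_id well_id  clone_id  pct_cells_high  nuclei_per_field_avg
    1     demo     D03 clone_D03       56.043956                 22.75
```

Only the planted well is called a hit; negative controls sit at 0% under
the calibrated thresholds. See also `examples/simulate_field.py` and
`examples/normalize_probes.py`.

## Command line

```sh
hciscreen simulate --params params.yaml --seed 1 --out plate_dir   # TIFFs + truth + manifest
hciscreen analyze  --manifest plate_dir/manifest.csv --out features.csv
hciscreen screen   --manifest plate_dir/manifest.csv --platemap map.csv --out run_dir
hciscreen layout   --n-clones 2455                                 # plate count/occupancy
hciscreen normalize --activity activity.csv --out plan.csv
hciscreen report   --features run_dir/well_features.csv --out heatmaps/
```

`screen` writes per-well features and hit-table CSVs, per-plate heatmap
PNGs, and a run log with the seed, config hash and every resolved
threshold; reruns on identical inputs are byte-identical.

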