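# Methods

## The measurement model

The pipeline quantifies, per well, the fraction of cells bound by a
fluorescently reported ligand probe. Its stages and assumptions:

1. **Background removal** (both channels). The background estimate is a
   grey opening with a square window much larger than a nucleus diameter
   (default 64 px; separable min/max filters keep this fast at any window
   size), optionally smoothed with a Gaussian so the subtracted surface
   varies slowly. A median-filter estimator is available for small images.
   The estimate is non-negative, so the corrected image never exceeds the
   input; negatives are clipped to zero. Clipping matters downstream: it
   turns the residual noise into a half-Gaussian, which is why threshold
   calibration works on pooled pixel moments rather than assuming
   symmetric noise (see *Calibration*).

2. **Nuclei segmentation** (channel 1). Gaussian smoothing (σ = 2 px
   default) → global threshold (Otsu by default, fixed value optional) →
   hole filling → minimum-area filter (40 px² default) → optional
   distance-transform watershed to split touching nuclei, seeded at local
   maxima at least `min_peak_distance_px` apart. Because Otsu always
   splits *something*, a contrast guard rejects blank fields: objects are
   only accepted when the foreground/background mean separation exceeds 4
   background SDs. Border-touching objects are retained by default
   (exclusion is a flag). Over- and undersegmentation in crowded regions
   is expected and quantified: with touching nuclei (clumping mode) counts
   stay within ±10% of truth when the peak distance is tightened to ~the
   nucleus radius; for non-touching nuclei counts are exact.

3. **ROI expansion.** Each nucleus mask is morphologically dilated by a
   disk (default 10 px) and clipped to the field. The dilation radius must
   cover the membrane ring (nucleus radius + membrane offset + half the
   ring width); neighbouring ROIs may overlap and each cell is measured
   independently — there is no exclusivity rule, so fixture geometry keeps
   the minimum centre spacing at least (nucleus radius + dilation + ring
   outer radius) so one cell's ROI cannot swallow a neighbour's ring.

4. **Target measurement and classification** (channel 2). Target pixels
   are the ROI pixels at or above the fixed threshold (inclusive `>=`
   everywhere); the target average intensity is their mean and exactly 0
   when none pass. A cell responds when its target average is at or above
   the response limit, and `% Cells High` is the percentage of responders.
   Note the readout is *not* monotone in the fixed threshold near zero: a
   threshold that admits the whole ROI dilutes ring intensity with
   background and can hold cells below the response limit, which is
   precisely why the fixed threshold exists. In the operating regime
   (threshold above background) the readout is nonincreasing in both
   thresholds, and the property tests assert it there.

5. **Focus QC.** Sharpness is the variance of the Laplacian of channel 1.
   A field is rejected when its score falls below half (configurable) the
   within-well median (a plate-wide reference can be supplied). Rejected
   fields contribute nothing to any statistic; a well with no surviving
   fields is flagged and its features are null, never fabricated.

## Calibration from controls

The fixed threshold is `mean + 5·SD` of the ROI pixel intensities pooled
over all negative-control cells. Pooling uses each cell's
(pixel count, mean, SD) moments combined exactly, so no pixel data is
retained. Because background clipping skews the pixel distribution, a
`mean + 5·SD` cut on the clipped distribution sits only ~3.3 raw-noise
sigmas up, and a ~10²-px² ROI will contain an occasional noise pixel above
it; since the target average is then at least the threshold, setting the
response limit equal to the fixed threshold would misclassify such cells.
The default limit rule is therefore more stringent, `mean + 10·SD`
(`equal` and `scale` rules are available), which keeps negative-control
wells at ≤1% Cells High while genuinely bound cells — whose ring pixels
sit far above either value — remain responders. The hit threshold on
% Cells High is the midpoint between the highest negative and lowest
positive control when the two separate cleanly, else a fixed 10% fallback.

## The synthetic data generator

The generator emulates the assay's signal structure, not microscope
physics: nuclei are soft-edged disks (Gaussian rim falloff, 0.8 px scale);
ligand binding is an annulus of configurable width at
`nucleus radius + membrane offset`, rendered at full amplitude with
half-pixel anti-aliased edges; per-cell amplitudes are normal draws; both
channels get constant background, additive Gaussian noise clipped to the
bit depth, and optional Gaussian defocus. Cell placement is rejection
sampling with a minimum centre spacing; the clumping mode places a
fraction of cells adjacent to an existing cell to create touching nuclei.
Cell count is Poisson; transfection and binding are per-cell Bernoulli
draws with `bound ⇒ transfected`. Infeasible packing is detected
deterministically from the requested mean density (exclusion disks
covering more than half the field raise a generation error); Poisson tail
draws above the random-sequential-adsorption bound are capped rather than
jammed. Plates are seeded per (well, field) from the master seed, so
generation is order-independent and bit-reproducible.

Not emulated (and therefore not validated by passing tests): optical PSFs,
photobleaching, vignetting, Poisson shot noise, autofluorescence texture,
non-membrane (internalized) staining patterns, and segmentation challenges
from irregular nuclear morphology. Recovery results on synthetic data
bound the pipeline's algorithmic error, not its performance on real
images.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| field size | 1104×1104 px | one 20×-scale field of a well |
| `n_cells_mean` | 50 | expected cells per field (Poisson), ~10,000 cells/well seeding imaged at 20× |
| `nucleus_radius_px` | (10, 1.5) | mean/SD of nucleus radius |
| `min_center_spacing_px` | 32 | hard-disk spacing; ≥ radius + dilation + ring outer radius |
| `transfected_fraction` | 0.4 | realistic transient-transfection efficiency |
| `bound_fraction` | 1.0 | fraction of transfected cells displaying ligand signal |
| `ch1_signal`, `ch2_ring_signal` | (3000, 400), (2500, 300) | nuclear / ring amplitudes (16-bit counts) |
| `background_level`, `noise_sd` | (400, 300), (60, 50) | per-channel background and noise |
| fields per well | 4 | four fields from a notional 5×5 grid centre |

Controls live in interior columns 2 and 13 (14 wells each; top half
negative, bottom half positive by default — the within-column split is a
layout-config choice). Border wells are excluded, leaving 308 analyzable
wells and 280 sample wells per 384-well plate; clones fill sample wells
column-major, so a 2455-clone library occupies 9 plates.

## Problem sizes in tests and the acceptance script

Simulated problem sizes are chosen so the full verification battery runs
comfortably on one CPU while preserving the geometry constraints above:
whole-plate simulations use 192×192 px fields with ~22 cells (radius 5 px,
spacing 24 px, dilation 8 px), and ground-truth recovery uses 640×640 px
fields with ~200 cells (radius 6 px, spacing 28 px). Recovery fixtures use
a nucleus-radius SD of 0.6 px so that exact-count checks probe the
segmentation algorithm rather than the interaction of a 3σ-small nucleus
with the minimum-area filter; the package defaults keep the wider SD.

## Numerical conventions

Coordinates are 0-based (row, col), row-major; intensities are unitless
counts; all threshold comparisons are inclusive; hit-table ties break
lexicographically by (plate, well); SDs in calibration are population
(ddof = 0) for exact pooling; the OLS rate of the activity assay uses the
full series by default (no plateau detection — the assay reads a 20-min
endpoint rate), and the dilution-only normalization takes the slowest
probe as reference so every prescription is a dilution.

## Known limitations

Equivalence with any vendor package's numeric output is not claimed — the
vendor's background, segmentation and object-gating internals are not
public. The readout estimates cell number, it does not guarantee it
(merged or split nuclei shift counts in crowded wells). Spatial edge
effects are handled by exclusion only; no plate-normalization (B-score,
Z′) is applied. Pool deconvolution is bookkeeping only: a hit from a
pooled screen carries its candidate probe set and must be retested with
individual probes.
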