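"""Generate one synthetic two-channel field and inspect its ground truth.

The simulator renders Hoechst-like nuclei in channel 1 and a membrane ring
in channel 2 around every cell that is transfected *and* bound by the
ligand probe, on top of background and Gaussian noise.
"""

from hciscreen import SimParams, generate_field

params = SimParams(
    field_height_px=384,
    field_width_px=384,
    n_cells_mean=60,
    min_center_spacing_px=28,
    transfected_fraction=0.4,  # fraction of cells overexpressing the receptor
    bound_fraction=1.0,  # of those, fraction displaying ligand signal
)
image, truth = generate_field(params, seed=1)

n_bound = sum(c.bound for c in truth.cells)
print(f"cells placed:          {len(truth.cells)}")
print(f"transfected and bound: {n_bound}")
print(f"true bound fraction:   {truth.true_bound_fraction:.3f}")
print(f"ch1 (nuclei) range:    {image.ch1.min()}..{image.ch1.max()}")
print(f"ch2 (ligand) range:    {image.ch2.min()}..{image.ch2.max()}")
# The true bound fraction is the quantity the image pipeline must recover
# as "% Cells High" from the pixel data alone.
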