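"""Render one synthetic microtubule and measure its lattice spacing.

A 41.6 A (compacted, GDP-like) lattice is rendered into a small tomogram
with a +/-60 degree missing wedge and noise at SNR 0.5, then measured by
the full pipeline: segment extraction along the trace, alignment and
non-overlap selection, z-projection and masking, per-segment power
spectra, per-microtubule spectrum summation and layer-line readout.
"""

import numpy as np

import mtlattice as mt

cfg = mt.RunConfig()
shape = (128, 272, 640)
params = mt.LatticeParams(monomer_spacing=41.6)

vol, truth = mt.render_microtubule_volume(
    params, shape, cfg.pixel_size,
    acq=mt.AcquisitionSpec(),            # +/-60 deg tilt fan, 2 deg steps
    noise=mt.NoiseSpec(snr=0.5, seed=11),
)
trace = mt.FilamentTrace("demo", np.array([[8, 135.5, 63.5], [631, 135.5, 63.5]]))

m = mt.measure_filament(vol, trace, cfg, condition="demo")
print(f"true spacing      : {truth.params.monomer_spacing:.2f} A")
print(f"measured spacing  : {m.spacing:.2f} A from {m.n_segments} segments "
      f"(layer line at {m.meta['peak_offset_px']:.2f} px of a "
      f"{cfg.box_px * cfg.pad_factor}-px spectrum)")
# The measured value should sit within ~0.1 A of the truth: the layer
# line position is robust to the wedge and to noise once the per-segment
# spectra of one microtubule are summed.
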