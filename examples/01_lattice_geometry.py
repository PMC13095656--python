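"""Lattice arithmetic: from per-subunit helical parameters to protomer
spacing, dimer rise and the expected layer-line position.

The 13-protofilament, 3-start microtubule lattice closes only if 13
lateral subunit steps climb exactly 3 monomer spacings, so the measured
per-subunit rise fixes the axial repeat:
monomer spacing = n_pf * rise / n_start.
"""

import mtlattice as mt

sp = mt.spacing_from_subunit_params(n_pf=13, n_start=3, subunit_rise=9.61)
print(f"subunit rise 9.61 A  ->  monomer spacing {sp.monomer:.2f} A, "
      f"dimer rise {sp.dimer:.1f} A")

# Where does that repeat sit in a power spectrum of a 1000-px box at
# 2.116 A/px?  (rows from the equator)
for spacing in (41.6, 43.1):
    off = mt.layerline_offset_px(spacing, box=1000, pixel_size=2.116)
    print(f"spacing {spacing:.1f} A  ->  layer line {off:.2f} px from the equator")

# and back through the printed readout formula
off = mt.layerline_offset_px(43.1, 1000, 2.116)
back = mt.measure_spacing(pixel_size=2.116, box=1000, equator_row=500,
                          peak_row=500 + off)
print(f"round trip through measure_spacing: {back:.2f} A")

# A dimer rise above ~82 A is an expanded (GTP-like) lattice; below is
# compacted (GDP-like).
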