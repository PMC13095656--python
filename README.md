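# mtlattice

Microtubule lattice-spacing analysis from cryo-electron tomograms via
helical layer-line power spectra.

## The problem

Microtubules are cylinders of ~13 protofilaments of α/β-tubulin. The
axial repeat between tubulin protomers (~40–44 Å) reports the
conformational state of the lattice: a dimer rise 2·spacing above ~82 Å
is an *expanded* (GTP-like, stable) lattice, below is *compacted*
(GDP-like). Because a helical object of axial repeat *s* produces a layer
line at axial frequency 1/*s* in the Fourier transform of its projection,
the spacing can be read per microtubule directly from a tomogram: box the
filament, project, transform, sum the power spectra of its segments, and
locate the ~1/40 Å⁻¹ layer line. With the filament axis along image *y*
and a centered spectrum,

```
spacing (Å) = pixel size (Å/px) × box size (px) ÷ |equator row − layer-line row|
```

`mtlattice` implements this measurement end to end for people doing
cellular or in vitro cryo-ET of microtubules: lattice geometry and the
closure relation `monomer spacing = n_pf × subunit rise / n_start`, a
synthetic tomogram generator (missing wedge, noise, bundles of
near-parallel filaments) with ground truth, segment
extraction/alignment/masking, the Fourier readout, per-condition
statistics (mean, s.d., t-based 95% CI, Welch comparison), and a grid
search for helical rise/twist on 3D maps by self-consistency under the
helical operator.

## Worked example

```python
import numpy as np
import mtlattice as mt

# geometry: the measured per-subunit helical parameters fix the repeat
sp = mt.spacing_from_subunit_params(n_pf=13, n_start=3, subunit_rise=9.61)
# -> monomer 41.64 Å, dimer 83.3 Å (an expanded lattice)

# simulate one microtubule and measure it back
cfg = mt.RunConfig()                       # 2.116 Å/px, 256-px boxes, 37–48 Å window
vol, truth = mt.render_microtubule_volume(
    mt.LatticeParams(monomer_spacing=41.6), (128, 272, 640), cfg.pixel_size,
    acq=mt.AcquisitionSpec(),              # ±60° tilt fan -> missing wedge
    noise=mt.NoiseSpec(snr=0.5, seed=11),
)
trace = mt.FilamentTrace("demo", np.array([[8, 135.5, 63.5], [631, 135.5, 63.5]]))
m = mt.measure_filament(vol, trace, cfg)
```

printing `m.spacing` gives `41.62` (Å): the 41.6 Å truth recovered to
0.02 Å from two summed segment spectra despite wedge and noise. The
narrative scripts in `examples/` run each capability; `examples/03` is
the full two-condition experiment (10 microtubules each at 41.6 vs
43.1 Å truth) and prints

```
gdp_like     truth 41.6 A: n=10 mean=41.58 A sd=0.002 A  CI95=(41.57, 41.58)
gmpcpp_like  truth 43.1 A: n=10 mean=43.10 A sd=0.002 A  CI95=(43.10, 43.10)
difference (gdp - gmpcpp): -1.53 A, Welch t=-1590.3, df=17.8, p=2.3e-47
```

i.e. both condition means recovered to within a few hundredths of an
Ångström and the compacted/expanded difference detected at overwhelming
confidence. `examples/04` recovers (rise 9.61 Å, twist −27.67°) and the
83.3 Å dimer rise by grid search on a synthetic map.

The same pipeline runs from the shell on real tomograms (MRC volumes plus
filament traces as CSV or IMOD ASCII point listings):

```
mtlattice measure --volume tomo.mrc --traces mts.csv --condition axon --out out/
mtlattice stats --measurements out/measurements.csv --out stats/
mtlattice helixsearch --map c1_map.mrc --out hs/
mtlattice pipeline --seed 1 --out demo/     # the synthetic experiment
```

Every command writes a `provenance.json` (config, seeds, versions).

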