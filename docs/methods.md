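# Methods

## The measurement

A microtubule is a helical polymer: ~13 protofilaments of α/β-tubulin
protomers with an axial repeat (monomer spacing) of ~40–44 Å. In the 2D
power spectrum of a projection of the filament (axis along image *y*),
this repeat produces a layer line at axial frequency 1/spacing, i.e. at

    offset (rows) = box × pixel_size / spacing

from the equator (the zero-axial-frequency row). The pipeline measures
one spacing per microtubule:

1. **Extraction.** Boxes of `box_px` (default 256 px at 2.116 Å/px,
   ~27 dimers) are cut along the traced filament every `step_px`
   (default = box, so boxes share no voxels). Each segment records the
   local in-plane tangent angle and out-of-plane tilt; boxes that leave
   the volume are dropped with a log record, and a trace shorter than one
   box yields an empty list plus a warning rather than an error.
2. **Alignment and selection.** Each segment's z-projection (rotated so
   the axis is image *y*, mean-subtracted) is cross-correlated along the
   axis against the running average of the previous segments; the
   normalized correlation at the optimum is the alignment score, with
   sub-pixel refinement by a 3-point parabola. The correlation must be
   computed on the 2D projection: collapsing to a 1D axial profile first
   cancels the lattice modulation, because the 13 staggered
   protofilaments fill the repeat almost uniformly when integrated across
   the filament width. The shift search is limited to less than half a
   repeat (box/32) so the correlation cannot lock onto the next protomer.
   Selection is greedy along the filament on the extraction centers
   (score ≥ 0.1 by default and separation ≥ `step_px`).
3. **Projection and masking.** Z slices whose variance is below 5% of the
   maximum slice variance carry no filament signal and are dropped before
   summation. Segments tilted more than 7° out of the plane are first
   leveled by a 3D rotation. The summed image is rotated so the filament
   axis is image *y*; pixels outside the mask — a user polygon, or an
   axis-aligned band of half-width lattice radius + 3σ_blob — are set to
   the image mean (not zero) so the mask edge adds no equatorial streak.
4. **Fourier readout.** Per-segment centered power spectra (plain
   transform, no window; optional Hann apodization) are summed per
   microtubule. The axial profile is the row-sum over the full masked
   width, excluding the meridian column (it carries the DC pixel and the
   box-edge streak). The layer-line peak is located inside a 37–48 Å
   window on both sides of the equator, refined by 3-point parabolic
   interpolation, accepted only if it exceeds 1.5× the local background
   (median of the window excluding ±2 rows around the maximum), and the
   two Friedel mates are averaged. Spectra are computed on a 4× zero-
   padded grid (mean-subtracted before padding): padding interpolates the
   spectrum so the peak position can be read with less quantization; the
   frequency step becomes 1/(4·box·pixel) and the readout formula is
   applied with the padded box. A missing peak is a signal
   (`usable = False`), not an exception, and such microtubules are
   excluded from statistics and counted in the log.

The spacing follows the readout formula exactly, with no internal
rounding. Statistics pool per-microtubule spacings within a condition
(the microtubule, not the segment, is the unit of replication): sample
mean, s.d. (n−1), CI95 = mean ± t(0.975, n−1)·sd/√n, and a Welch
(unequal-variance) two-sample t test with a Welch–Satterthwaite CI for
the two-condition comparison. No hierarchical (per-cell) nesting and no
multiple-testing correction are applied — the design is a small fixed
set of contrasts on pooled microtubules.

## Lattice geometry

`LatticeParams` carries the protofilament count `n_pf` (default 13), the
monomer-helix start number `n_start` (default 3), the monomer spacing,
the lattice radius (default 115 Å, the middle of the 130–330 Å annulus
used for cylindrical masking) and the per-subunit twist. Closure of the
lattice ties the parameterizations together:

    monomer_spacing = n_pf × subunit_rise / n_start
    dimer_rise      = 2 × monomer_spacing

Sign convention: negative twist = left-handed, with rotation about +z
right-handed viewed from +z; the filament axis is z in 3D and image *y*
after projection. Subunit centers are generated by two operators: the
lateral step (subunit_rise, subunit_twist) and the axial monomer step
(monomer_spacing, skew), where skew = (n_pf·twist + 360)/n_start degrees
is the azimuthal drift per monomer forced by closure. It is exactly zero
at the default twist −360/n_pf; for a measured twist such as −27.67°
(13 × 27.67 = 359.71) it is ~0.097°/monomer — the familiar protofilament
supertwist. Without it the lattice would carry a spurious 0.29° closure
seam that measurably biases twist recovery. A subunit is included iff
its axial center lies in [0, length) (deterministic counts). The seam
(the one α–β lateral contact) is not modeled: the 1/spacing layer line
is insensitive to it at this resolution.

## The synthetic generator

The generator reproduces only the statistical structure the measurement
relies on: each protomer is an isotropic Gaussian blob (σ = 6 Å,
comparable to a tubulin monomer half-width at tomographic contrast) at
the lattice positions, swept along a near-straight polyline trace
(transverse frames are not parallel-transported, so sharp bends would
shear the lattice); the missing wedge is a hard Fourier mask keeping the
±60° tilt fan about the y tilt axis (the 2° increment is recorded but
the fan is treated as filled, as after reconstruction); noise is
additive Gaussian calibrated so signal variance / noise variance equals
the requested SNR. Noise is added after the wedge and is itself
unfiltered. Every stochastic operation takes an explicit seed; there is
no hidden global state.

What is *not* emulated: CTF (at the several-μm defocus used for such
data the ~1/41 Å⁻¹ peak position is not moved by the CTF envelope),
per-tilt dose weighting, membranes, vesicles, MAP decoration, crowding,
and reconstruction artifacts other than the wedge. Passing tests
therefore demonstrate the correctness and precision of the measurement
chain under its geometric and noise assumptions, not robustness to every
feature of real cellular tomograms.

Default study conditions for the two-condition experiment: 10
microtubules per condition at true spacings 41.6 Å (GDP-like) and
43.1 Å (GMPCPP-like); 2 near-parallel filaments per field, 120 px
(25 nm) apart laterally, in (128, 384, 896)-voxel fields at 2.116 Å/px
(three 256-px segments per microtubule); ±60° wedge; SNR 0.5. The per-
field seeds spawn deterministically from the experiment seed. These
sizes keep a full experiment around one minute on a single CPU while
leaving each microtubule ~0.19 μm long — short but within the range a
single tomogram field of view provides.

## Helical parameter search

The rise/twist of a 3D map (axis = z through the box center, no axis
refinement) are found by maximizing self-consistency: the normalized
cross-correlation between the map and its copy transformed by
(translate rise along z, rotate twist about z), inside a cylindrical
annulus (default diameters 130/330 Å) over the central 65% of the box
height. The map is resampled once onto a (z, φ, r) cylindrical grid
(512 azimuth bins, trilinear), after which the helical operator is a
plain (z, φ) shift: the φ shift is applied exactly via FFT phase shift
(the axis is periodic), the z shift by linear interpolation with edge
cropping. The reference metric used in the established helix tools is
unpublished, so this metric is defined here and validated purely by
ground-truth recovery on synthetic lattices: the subunit-level window
(rise 9–10 Å, twist −28 to −27°, 0.01 steps) recovers (9.61, −27.67)
exactly, and the dimer-level window (rise 80–85 Å, twist −1 to 1°)
recovers 83.29 Å with the small positive supertwist. The search is
exhaustive over the grid; a coarse-to-fine helper (default 10× coarser
first pass, then the full step inside one coarse cell) gives the same
answer when the score surface is unimodal at the coarse scale, which
holds for these windows. A flat map yields NaN scores (undefined), and
an all-NaN grid is an error.

## Numerical choices and degenerate inputs

- Coordinates are 0-based pixel indices with voxel centers at integers;
  trace coordinates are in pixels of the volume they index, and Å
  conversions always go through the explicit voxel size (never inferred
  from binning conventions).
- All rotations use linear interpolation (cubic optional where exposed);
  rotation fill values are the image mean.
- Both Friedel mates are averaged by default (halves peak-location
  noise); single-sided readout is available and flagged when one side is
  excluded.
- Parabolic sub-pixel refinement is used for the layer-line peak, the
  alignment shift and the autocorrelation oracle in the tests; the
  vertex formula is only applied at an interior discrete maximum with
  negative curvature.
- Degenerate inputs raise early with the offending quantity named:
  non-positive spacings/steps, odd boxes, empty annuli, rises exceeding
  the usable box height, self-intersecting mask polygons, traces with
  duplicate consecutive points (with the row number for file input).
- Identical constant groups in the Welch comparison return p = 1
  (difference 0) or p = 0 (nonzero difference) rather than dividing by a
  zero standard error.

## Known limitations

- Filament traces are inputs; there is no automated tracing, polarity
  calling, protofilament-number classification or seam detection.
- The helix search does not refine the helical axis; maps must be
  reasonably centered and axis-aligned.
- MRC I/O supports mode-2 (float32) isotropic-voxel maps; axis-order
  metadata is honored on read, anisotropic voxels are rejected.
- Confidence intervals pool microtubules across cells/tomograms; a
  mixed-effects treatment of the nesting is out of scope.
- Full Bessel-order indexing of the diffraction pattern, Moiré/supertwist
  analysis beyond the closure skew, and CTF correction of spectra are
  out of scope.
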