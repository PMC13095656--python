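"""Synthetic cryo-ET volumes of microtubule lattices.

The generator produces the statistical structure the layer-line analysis
assumes and nothing more: each tubulin protomer is an isotropic Gaussian
blob placed at the lattice positions of :mod:`mtlattice.lattice`, swept
along a (near-straight) filament trace; the tomographic missing wedge is a
hard Fourier mask over the un-tilted fan; noise is additive Gaussian
scaled to a requested signal-to-noise ratio.  No CTF, dose weighting,
membranes or decoration are simulated -- the measured statistic is the
position of a single low-resolution layer line, which none of those move.

Geometry: volumes are (z, y, x); the beam direction is z, the tilt axis is
y, so the missing wedge excludes Fourier voxels whose (kx, kz) direction
lies more than the maximum tilt away from the kx axis.  Filament traces
are given in pixel coordinates (x, y, z), one point per row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import LatticeParams, lattice_positions
from .volume import DensityVolume

__all__ = [
    "AcquisitionSpec",
    "NoiseSpec",
    "GroundTruth",
    "missing_wedge_mask",
    "apply_missing_wedge",
    "render_field",
    "render_microtubule_volume",
]

#: Default protomer blob width (Gaussian sigma), Å.  Comparable to the
#: half-width of a tubulin monomer at tomographic resolution.
DEFAULT_BLOB_SIGMA_A = 6.0


@dataclass
class AcquisitionSpec:
    """Tilt geometry of the simulated acquisition.

    Defaults follow the bidirectional dose-symmetric scheme common for
    cellular tomography: 0 to -60 then 0 to +60 degrees in 2-degree steps.
    The wedge mask itself depends only on the tilt extremes (the fan is
    treated as filled); the increment is recorded for provenance.
    """

    tilt_min: float = -60.0
    tilt_max: float = 60.0
    tilt_increment: float = 2.0
    wedge_axis: str = "y"

    def __post_init__(self) -> None:
        if not self.tilt_min < self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")
        if not self.tilt_increment > 0:
            raise ValueError("tilt_increment must be positive")
        if self.wedge_axis != "y":
            raise ValueError("only wedge_axis='y' (tilt axis = volume y) is supported")


@dataclass
class NoiseSpec:
    """Additive Gaussian noise at a given signal-to-noise ratio.

    ``snr`` is the ratio of lattice-signal variance to noise variance over
    the rendered volume.
    """

    snr: float
    seed: int

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError(f"snr must be positive, got {self.snr}")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of one rendered filament."""

    params: LatticeParams
    trace_px: np.ndarray  # (N, 3) points (x, y, z) in pixels
    pixel_size: float
    seed: int | None
    wedge_applied: bool
    blob_sigma: float = DEFAULT_BLOB_SIGMA_A

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "trace_px": np.asarray(self.trace_px).tolist(),
            "pixel_size": self.pixel_size,
            "seed": self.seed,
            "wedge_applied": self.wedge_applied,
            "blob_sigma": self.blob_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["params"] = LatticeParams.from_dict(d["params"])
        d["trace_px"] = np.asarray(d["trace_px"], dtype=float)
        return cls(**d)


def missing_wedge_mask(shape: tuple[int, int, int], tilt_max: float) -> np.ndarray:
    """Boolean keep-mask for an rfft grid of the given real-space shape.

    Tilting about y sweeps central sections through the (kx, kz) plane;
    the union over tilts in [-tilt_max, +tilt_max] keeps every frequency
    whose (kx, kz) direction lies within tilt_max of the kx axis.
    """
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.rfftfreq(nx)[None, None, :]
    ang = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
    keep = ang <= tilt_max + 1e-12
    return np.broadcast_to(keep, (nz, ny, kx.shape[-1]))


def apply_missing_wedge(data: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    """Zero Fourier components outside the tilt fan (hard wedge mask).

    The output keeps the input dtype (the wedge is exact in the working
    precision of the transform).
    """
    tilt_max = max(abs(acq.tilt_min), abs(acq.tilt_max))
    F = np.fft.rfftn(data)
    F *= missing_wedge_mask(data.shape, tilt_max)
    out = np.fft.irfftn(F, s=data.shape, axes=(0, 1, 2))
    return out.astype(data.dtype, copy=False)


def _trace_frames(trace_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arclength and per-vertex unit tangents of a polyline."""
    pts = np.asarray(trace_px, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("trace must be an (N>=2, 3) array of (x, y, z) points")
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if np.any(seglen == 0):
        raise ValueError("trace has duplicate consecutive points")
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    return s, seg / seglen[:, None]


def _sweep_positions(
    local: np.ndarray, trace_px: np.ndarray, pixel_size: float
) -> np.ndarray:
    """Map lattice-frame positions (x, y, z_axial in Å) onto a trace.

    The axial coordinate is interpreted as arclength along the polyline;
    the transverse (x, y) coordinates are laid out in a frame perpendicular
    to the local tangent.  Valid for near-straight traces (the frame is not
    parallel-transported, so sharp bends would shear the lattice).
    """
    s, tangents = _trace_frames(trace_px)
    pts = np.asarray(trace_px, dtype=float)
    s_axial = local[:, 2] / pixel_size  # arclength in px
    seg_idx = np.clip(np.searchsorted(s[1:], s_axial, side="right"), 0, len(tangents) - 1)
    t = tangents[seg_idx]
    base = pts[seg_idx] + (s_axial - s[seg_idx])[:, None] * t
    # transverse frame: e1, e2 perpendicular to t
    ref = np.where(
        (np.abs(t[:, 2:3]) < 0.9), np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]])
    )
    e1 = np.cross(ref, t)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(t, e1)
    return base + (local[:, 0:1] * e1 + local[:, 1:2] * e2) / pixel_size


def _stamp_blobs(
    data: np.ndarray, centers_px: np.ndarray, sigma_px: float
) -> None:
    """Accumulate isotropic Gaussian blobs at the given (x, y, z) centers."""
    nz, ny, nx = data.shape
    r = max(2, int(math.ceil(4.0 * sigma_px)))
    for cx, cy, cz in centers_px:
        iz0, iz1 = max(0, int(cz) - r), min(nz, int(cz) + r + 1)
        iy0, iy1 = max(0, int(cy) - r), min(ny, int(cy) + r + 1)
        ix0, ix1 = max(0, int(cx) - r), min(nx, int(cx) + r + 1)
        if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
            continue
        z = np.arange(iz0, iz1, dtype=np.float32) - cz
        y = np.arange(iy0, iy1, dtype=np.float32) - cy
        x = np.arange(ix0, ix1, dtype=np.float32) - cx
        g = np.exp(
            -(
                z[:, None, None] ** 2
                + y[None, :, None] ** 2
                + x[None, None, :] ** 2
            )
            / (2.0 * sigma_px**2)
        )
        data[iz0:iz1, iy0:iy1, ix0:ix1] += g


def render_field(
    filaments: list[tuple[LatticeParams, np.ndarray]],
    shape: tuple[int, int, int],
    pixel_size: float,
    acq: AcquisitionSpec | None = None,
    noise: NoiseSpec | None = None,
    blob_sigma: float = DEFAULT_BLOB_SIGMA_A,
) -> tuple[DensityVolume, list[GroundTruth]]:
    """Render several filaments into one volume (an axon-bundle-like field).

    Parameters
    ----------
    filaments
        ``(LatticeParams, trace)`` pairs; traces are (N, 3) pixel
        coordinates (x, y, z) that must lie inside the volume.
    shape
        Volume shape ``(nz, ny, nx)``.
    pixel_size
        Å per pixel; must satisfy ``pixel_size <= monomer_spacing / 4``
        for every filament so the protomer-repeat frequency is comfortably
        inside Nyquist.
    acq, noise
        If given, a missing wedge is applied / Gaussian noise is added
        (in that order; noise is not wedge-filtered).
    """
    data = np.zeros(shape, dtype=np.float32)
    truths: list[GroundTruth] = []
    nz, ny, nx = shape
    for i, (params, trace) in enumerate(filaments):
        limit = params.monomer_spacing / 4.0
        if pixel_size > limit:
            raise ValueError(
                f"pixel_size {pixel_size} Å/px undersamples the "
                f"{params.monomer_spacing} Å repeat of filament {i}: the "
                f"1/{params.monomer_spacing:.2f} 1/Å layer line requires "
                f"pixel_size <= {limit:.3f} Å/px"
            )
        trace = np.asarray(trace, dtype=float)
        if trace.ndim != 2 or trace.shape[1] != 3:
            raise ValueError(f"filament {i}: trace must be (N, 3)")
        hi = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
        if np.any(trace < 0) or np.any(trace > hi):
            raise ValueError(f"filament {i}: trace exits the volume {shape}")
        s, _ = _trace_frames(trace)
        length_A = s[-1] * pixel_size
        local = lattice_positions(params, length_A)
        centers = _sweep_positions(local, trace, pixel_size)
        _stamp_blobs(data, centers, blob_sigma / pixel_size)
        truths.append(
            GroundTruth(
                params=params,
                trace_px=trace,
                pixel_size=pixel_size,
                seed=None if noise is None else noise.seed,
                wedge_applied=acq is not None,
                blob_sigma=blob_sigma,
            )
        )
    if acq is not None and filaments:
        data = apply_missing_wedge(data, acq)
    if noise is not None:
        sig_var = float(np.var(data))
        rng = np.random.default_rng(noise.seed)
        sigma = math.sqrt(sig_var / noise.snr) if sig_var > 0 else 1.0
        data = data + rng.normal(0.0, sigma, size=data.shape).astype(np.float32)
    return DensityVolume(data, pixel_size), truths


def render_microtubule_volume(
    params: LatticeParams,
    shape: tuple[int, int, int],
    pixel_size: float,
    acq: AcquisitionSpec | None = None,
    noise: NoiseSpec | None = None,
    orientation: str = "x",
    margin_px: float = 1.0,
    blob_sigma: float = DEFAULT_BLOB_SIGMA_A,
) -> tuple[DensityVolume, GroundTruth]:
    """Render a single straight microtubule through the volume center.

    ``orientation`` is the volume axis the filament runs along ("x", "y"
    or "z"); the trace spans the full extent of that axis minus ``margin_px``
    at each end.  Equivalent to a one-filament :func:`render_field`.
    """
    nz, ny, nx = shape
    extent = {"x": nx, "y": ny, "z": nz}
    if orientation not in extent:
        raise ValueError(f"orientation must be 'x', 'y' or 'z', got {orientation!r}")
    cen = {"x": (nx - 1) / 2.0, "y": (ny - 1) / 2.0, "z": (nz - 1) / 2.0}
    lo, hi = margin_px, extent[orientation] - 1 - margin_px
    if hi <= lo:
        raise ValueError("volume too small for the requested margin")
    p0 = np.array([cen["x"], cen["y"], cen["z"]])
    p1 = p0.copy()
    axis_col = {"x": 0, "y": 1, "z": 2}[orientation]
    p0[axis_col], p1[axis_col] = lo, hi
    vol, truths = render_field(
        [(params, np.vstack([p0, p1]))],
        shape,
        pixel_size,
        acq=acq,
        noise=noise,
        blob_sigma=blob_sigma,
    )
    return vol, truths[0]
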