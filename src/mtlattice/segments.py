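"""From a tomographic volume plus a filament trace to aligned, masked 2D
projections, one per non-overlapping microtubule segment.

This reproduces, in code, the interactive subtomogram workflow used for
layer-line measurements: crop boxes along the traced filament axis, align
them axially against a running average, keep a non-overlapping well-aligned
subset, sum each box along the beam (z) axis dropping empty slices, rotate
the projection so the filament axis is the image y axis, and mask away
everything but the microtubule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lattice import DEFAULT_RADIUS_A
from .simulate import DEFAULT_BLOB_SIGMA_A, _trace_frames
from .volume import DensityVolume, Image2D

logger = logging.getLogger(__name__)

__all__ = [
    "FilamentTrace",
    "Segment",
    "extract_segments",
    "align_and_select",
    "project_and_mask",
]

#: Out-of-plane tilt (degrees) above which a segment is leveled before
#: projection; segments tilted less are summed as-is.
TILT_CORRECTION_THRESHOLD_DEG = 7.0


@dataclass
class FilamentTrace:
    """An ordered 3D polyline tracing one microtubule, in pixel units."""

    mt_id: str
    points: np.ndarray  # (N, 3) as (x, y, z), pixels
    volume_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError(f"trace {self.mt_id}: need an (N>=2, 3) point array")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError(f"trace {self.mt_id}: duplicate consecutive points")

    @property
    def arclength(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def out_of_plane_tilt(self) -> float:
        """Mean inclination of the trace out of the xy plane, degrees."""
        d = self.points[-1] - self.points[0]
        r = math.hypot(d[0], d[1])
        return math.degrees(math.atan2(d[2], r)) if r > 0 else 90.0


@dataclass
class Segment:
    """A boxed subvolume cut along a filament, plus its local geometry."""

    mt_id: str
    index: int
    center_px: np.ndarray  # (x, y, z) in the source volume
    center_s: float  # arclength of the center along the trace, px
    box: int
    in_plane_angle: float  # filament axis direction in the xy plane, deg from +x
    out_of_plane_tilt: float  # deg
    pixel_size: float
    subvolume: np.ndarray | None = None  # (nz, box, box)
    score: float | None = None
    shift_px: float = 0.0  # axial shift found by alignment
    center_s_refined: float | None = None  # center_s corrected by the shift
    kept: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.box % 2:
            raise ValueError(f"box must be even, got {self.box}")


def extract_segments(
    volume: DensityVolume,
    trace: FilamentTrace,
    box: int,
    step: int | None = None,
) -> list[Segment]:
    """Cut box-sized segments every ``step`` px of arclength along a trace.

    Centers are placed at arclengths ``box/2, box/2 + step, ...`` while the
    whole box stays inside the trace; centers whose in-plane crop would
    leave the volume are dropped with a log record.  A trace shorter than
    one box yields an empty list (with a warning, not an exception).

    The subvolume is an axis-aligned crop: ``box x box`` in (y, x) around
    the center, and the lesser of ``box`` and the volume depth in z.
    """
    if step is None:
        step = box
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    s_vert, tangents = _trace_frames(trace.points)
    total = s_vert[-1]
    half = box / 2.0
    if total < box:
        logger.warning(
            "trace %s: arclength %.1f px shorter than box %d px; no segments",
            trace.mt_id,
            total,
            box,
        )
        return []
    nz, ny, nx = volume.shape
    segments: list[Segment] = []
    idx = 0
    s = half
    while s <= total - half + 1e-9:
        seg_idx = int(np.clip(np.searchsorted(s_vert[1:], s, side="right"), 0, len(tangents) - 1))
        t = tangents[seg_idx]
        center = trace.points[seg_idx] + (s - s_vert[seg_idx]) * t
        cx, cy, cz = center
        iy0 = int(round(cy)) - box // 2
        ix0 = int(round(cx)) - box // 2
        if iy0 < 0 or ix0 < 0 or iy0 + box > ny or ix0 + box > nx:
            logger.info(
                "trace %s: segment at s=%.1f px dropped (box exits volume)",
                trace.mt_id,
                s,
            )
            s += step
            continue
        depth = min(box, nz)
        iz0 = int(np.clip(int(round(cz)) - depth // 2, 0, nz - depth))
        sub = np.array(volume.data[iz0 : iz0 + depth, iy0 : iy0 + box, ix0 : ix0 + box])
        in_plane = math.degrees(math.atan2(t[1], t[0]))
        r_inplane = math.hypot(t[0], t[1])
        oop = math.degrees(math.atan2(t[2], r_inplane)) if r_inplane > 0 else 90.0
        segments.append(
            Segment(
                mt_id=trace.mt_id,
                index=idx,
                center_px=center,
                center_s=s,
                box=box,
                in_plane_angle=in_plane,
                out_of_plane_tilt=oop,
                pixel_size=volume.voxel_size,
                subvolume=sub,
            )
        )
        idx += 1
        s += step
    return segments


def _canonical_projection(segment: Segment) -> np.ndarray:
    """Mean-subtracted z-projection with the filament axis along image y.

    Alignment must work on the 2D projection: collapsing it to a 1D axial
    profile would cancel the lattice modulation, because the staggered
    protofilaments of a full microtubule fill the axial repeat almost
    uniformly when integrated across the filament width.
    """
    proj = segment.subvolume.sum(axis=0).astype(float)
    angle = 90.0 - segment.in_plane_angle
    if abs(angle) > 1e-9:
        proj = ndimage.rotate(
            proj, -angle, reshape=False, order=1, mode="constant", cval=float(proj.mean())
        )
    return proj - proj.mean()


def _best_shift(image: np.ndarray, reference: np.ndarray, max_shift: int) -> tuple[float, float]:
    """Sub-pixel axial (row) shift of ``image`` relative to ``reference``.

    Cross-correlates along the axis for every column and sums the column
    correlations (FFT-based, zero-padded); returns (shift, score) with the
    score the normalized cross-correlation at the optimum and the shift
    refined by 3-point parabolic interpolation.  Positive shift means the
    image content sits ``shift`` rows further along the axis than the
    reference.
    """
    denom = np.linalg.norm(image) * np.linalg.norm(reference)
    if denom == 0:
        return 0.0, 0.0
    n = image.shape[0]
    size = 2 * n
    fa = np.fft.rfft(image, n=size, axis=0)
    fb = np.fft.rfft(reference, n=size, axis=0)
    cc = np.fft.irfft((fa * np.conj(fb)).sum(axis=1), n=size) / denom
    lags = np.concatenate([np.arange(-max_shift, 0), np.arange(0, max_shift + 1)])
    cc_w = cc[lags]  # negative lags index from the end
    order = np.argsort(lags)
    lags_w, cc_w = lags[order], cc_w[order]
    i = int(np.argmax(cc_w))
    shift = float(lags_w[i])
    score = float(cc_w[i])
    if 0 < i < len(cc_w) - 1:
        a, b, c3 = cc_w[i - 1], cc_w[i], cc_w[i + 1]
        denom2 = a - 2 * b + c3
        if denom2 < 0:
            shift += 0.5 * (a - c3) / denom2
    return shift, score


def align_and_select(
    segments: list[Segment],
    min_separation: int | None = None,
    score_threshold: float = 0.1,
    max_shift: int | None = None,
) -> list[Segment]:
    """Axially align segments against a running average and keep a
    non-overlapping, well-aligned subset.

    Each segment's axial density profile is cross-correlated with the
    running average of previously aligned segments; the shift and score
    are stored on the segment (``center_s_refined`` carries the corrected
    center).  Selection is greedy along the filament on the extraction
    centers -- which is what makes "non-overlapping" literal, since boxes
    ``min_separation`` apart (default: the box size) share no voxels -- a
    segment is kept iff its score is at least ``score_threshold`` and its
    center is at least ``min_separation`` px past the last kept center.
    """
    if not segments:
        raise ValueError("align_and_select needs at least one segment")
    if min_separation is None:
        min_separation = segments[0].box
    if max_shift is None:
        # sub-repeat phase alignment: keep the search inside half a ~40 Å
        # repeat so the correlation cannot lock onto the next protomer
        max_shift = max(2, segments[0].box // 32)
    reference = None
    n_ref = 0
    for seg in segments:
        proj = _canonical_projection(seg)
        if reference is None:
            seg.shift_px, seg.score = 0.0, 1.0
            reference = proj.copy()
            n_ref = 1
            continue
        shift, score = _best_shift(proj, reference / n_ref, max_shift)
        seg.shift_px, seg.score = shift, score
        reference += np.roll(proj, -int(round(shift)), axis=0)
        n_ref += 1
    for seg in segments:
        seg.center_s_refined = seg.center_s - seg.shift_px
    ordered = sorted(segments, key=lambda s: s.center_s)
    selected: list[Segment] = []
    for seg in ordered:
        seg.kept = False
        if seg.score is None or seg.score < score_threshold:
            continue
        if selected and seg.center_s - selected[-1].center_s < min_separation:
            continue
        seg.kept = True
        selected.append(seg)
    if not selected:
        logger.warning("no segment reached the alignment score threshold %.2f", score_threshold)
    return selected


def _validate_polygon(polygon: np.ndarray) -> np.ndarray:
    from shapely.geometry import Polygon as ShapelyPolygon

    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (N>=3, 2) vertex list of (x, y)")
    if not ShapelyPolygon(poly).is_valid:
        raise ValueError("polygon is not simple (self-intersecting)")
    return poly


def _polygon_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    from matplotlib.path import Path

    poly = _validate_polygon(polygon)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return Path(poly).contains_points(pts).reshape(shape)


def project_and_mask(
    segment: Segment,
    polygon: np.ndarray | None = None,
    mask_half_width_px: float | None = None,
    tilt_threshold: float = TILT_CORRECTION_THRESHOLD_DEG,
    empty_slice_fraction: float = 0.05,
) -> Image2D:
    """Project a segment along z, rotate the filament axis onto image y and
    mask out non-microtubule signal.

    Z slices whose variance is below ``empty_slice_fraction`` of the
    maximum slice variance carry no filament signal and are dropped before
    summation.  If the segment's out-of-plane tilt exceeds
    ``tilt_threshold`` degrees the subvolume is first leveled (rotated to
    0 degrees tilt).  Outside the mask -- a user polygon in image
    coordinates, or an axis-aligned band of ``mask_half_width_px`` about
    the filament axis (default: lattice radius + 3 blob sigma) -- pixels
    are set to the image mean, not zero, to avoid a masking step edge at
    the equator of the spectrum.
    """
    if segment.subvolume is None:
        raise ValueError("segment has no subvolume")
    if polygon is not None:
        _validate_polygon(polygon)
    sub = segment.subvolume
    var = sub.var(axis=(1, 2))
    vmax = var.max()
    if vmax == 0:
        raise ValueError("all slices are empty: no filament signal to project")
    keep = var > empty_slice_fraction * vmax
    if not keep.any():
        raise ValueError("all slices fall below the empty-slice threshold")
    sub = sub[keep]
    angle = 90.0 - segment.in_plane_angle
    if abs(segment.out_of_plane_tilt) > tilt_threshold:
        # level in 3D: in-plane rotation to the canonical axis, then
        # out-of-plane rotation about image x, then plain z-summation
        if abs(angle) > 1e-9:
            sub = ndimage.rotate(sub, -angle, axes=(1, 2), reshape=False, order=1)
        sub = ndimage.rotate(sub, -segment.out_of_plane_tilt, axes=(0, 1), reshape=False, order=1)
        image = sub.sum(axis=0).astype(float)
    else:
        image = sub.sum(axis=0).astype(float)
        if abs(angle) > 1e-9:
            image = ndimage.rotate(
                image, -angle, reshape=False, order=1, mode="constant", cval=float(image.mean())
            )
    fill = float(image.mean())
    if polygon is not None:
        mask = _polygon_mask(image.shape, polygon)
    else:
        if mask_half_width_px is None:
            mask_half_width_px = (
                DEFAULT_RADIUS_A + 3.0 * DEFAULT_BLOB_SIGMA_A
            ) / segment.pixel_size
        cols = np.arange(image.shape[1])
        c = (image.shape[1] - 1) / 2.0
        mask = np.broadcast_to(
            np.abs(cols - c) <= mask_half_width_px, image.shape
        )
    image = np.where(mask, image, fill)
    return Image2D(
        image,
        segment.pixel_size,
        meta={"mt_id": segment.mt_id, "index": segment.index, "mask_fill": fill},
    )
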