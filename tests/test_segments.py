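"""Segment extraction, alignment/selection, projection and masking."""

import logging

import numpy as np
import pytest
from scipy import ndimage

import mtlattice as mt
from mtlattice.segments import Segment
from mtlattice.volume import DensityVolume


def _zeros_volume(shape=(8, 220, 420), px=2.0):
    return DensityVolume(np.zeros(shape, dtype=np.float32), px)


def _trace(x0, x1, y=105.0, z=3.5, mt_id="mt"):
    return mt.FilamentTrace(mt_id, np.array([[x0, y, z], [x1, y, z]]))


class TestExtractSegments:
    def test_placement_arithmetic(self):
        segs = mt.extract_segments(_zeros_volume(), _trace(5, 405), box=190, step=190)
        assert [round(s.center_s) for s in segs] == [95, 285]
        assert all(s.box == 190 for s in segs)

    def test_trace_shorter_than_box(self, caplog):
        with caplog.at_level(logging.WARNING):
            segs = mt.extract_segments(_zeros_volume(), _trace(5, 194), box=190)
        assert segs == []
        assert any("shorter than box" in r.message for r in caplog.records)

    def test_box_exiting_volume_dropped(self):
        vol = _zeros_volume((8, 220, 420))
        tr = mt.FilamentTrace("m", np.array([[5, 40.0, 3.5], [405, 40.0, 3.5]]))
        # box 190 around y=40 would span y in [-55, 135): every center dropped
        assert mt.extract_segments(vol, tr, box=190, step=190) == []

    def test_curved_trace_orientation_tracks_tangent(self):
        # gentle arc in the xy plane
        t = np.linspace(0, 1, 40)
        x = 5 + 400 * t
        y = 105 + 18 * np.sin(np.pi * t)
        pts = np.column_stack([x, y, np.full_like(x, 3.5)])
        tr = mt.FilamentTrace("arc", pts)
        segs = mt.extract_segments(_zeros_volume(), tr, box=100, step=50)
        assert len(segs) >= 4
        for seg in segs:
            # independent finite-difference tangent at the nearest vertex
            i = int(np.argmin(np.linalg.norm(pts[:, :2] - seg.center_px[:2], axis=1)))
            lo, hi = max(0, i - 1), min(len(pts) - 1, i + 1)
            d = pts[hi] - pts[lo]
            ang = np.degrees(np.arctan2(d[1], d[0]))
            assert abs(seg.in_plane_angle - ang) < 1.0

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            mt.extract_segments(_zeros_volume(), _trace(5, 405), box=190, step=0)


class TestAlignAndSelect:
    def test_noiseless_segments_all_pass_and_tile(self, noiseless_volume):
        vol, trace, _ = noiseless_volume
        segs = mt.extract_segments(vol, trace, box=256, step=256)
        selected = mt.align_and_select(segs, min_separation=256)
        assert len(selected) == len(segs) == 2
        centers = [s.center_s for s in selected]
        assert all(b - a >= 256 for a, b in zip(centers, centers[1:]))
        assert all(s.score > 0.5 for s in selected)

    def test_duplicate_center_kept_once(self, noiseless_volume):
        vol, trace, _ = noiseless_volume
        segs = mt.extract_segments(vol, trace, box=256, step=256)
        dup = Segment(
            mt_id=segs[0].mt_id,
            index=99,
            center_px=segs[0].center_px.copy(),
            center_s=segs[0].center_s,
            box=segs[0].box,
            in_plane_angle=segs[0].in_plane_angle,
            out_of_plane_tilt=segs[0].out_of_plane_tilt,
            pixel_size=segs[0].pixel_size,
            subvolume=segs[0].subvolume.copy(),
        )
        selected = mt.align_and_select([segs[0], dup], min_separation=256)
        assert len(selected) == 1

    def test_known_axial_shift_recovered(self, noiseless_volume):
        vol, trace, _ = noiseless_volume
        base = mt.extract_segments(vol, trace, box=256, step=256)
        mt.align_and_select(base, min_separation=256)
        shifted = mt.extract_segments(vol, trace, box=256, step=256)
        shifted[1].subvolume = np.roll(shifted[1].subvolume, 5, axis=2)
        mt.align_and_select(shifted, min_separation=256)
        recovered = shifted[1].shift_px - base[1].shift_px
        assert recovered == pytest.approx(5.0, abs=0.5)

    def test_score_threshold_filters_all(self, caplog):
        rng = np.random.default_rng(0)
        vol = DensityVolume(rng.normal(size=(8, 300, 300)).astype(np.float32), 2.0)
        tr = mt.FilamentTrace("m", np.array([[5, 150.0, 3.5], [295, 150.0, 3.5]]))
        segs = mt.extract_segments(vol, tr, box=128, step=128)
        with caplog.at_level(logging.WARNING):
            selected = mt.align_and_select(segs, min_separation=128, score_threshold=1.1)
        assert selected == []

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mt.align_and_select([])


def _toy_segment(sub, angle=90.0, tilt=0.0, px=2.0):
    return Segment(
        mt_id="toy",
        index=0,
        center_px=np.zeros(3),
        center_s=0.0,
        box=sub.shape[1],
        in_plane_angle=angle,
        out_of_plane_tilt=tilt,
        pixel_size=px,
        subvolume=sub.astype(np.float32),
    )


class TestProjectAndMask:
    def test_empty_slices_dropped(self):
        rng = np.random.default_rng(1)
        sub = np.zeros((5, 64, 64))
        sub[1] = rng.normal(size=(64, 64))
        sub[2] = rng.normal(size=(64, 64))
        sub[4] = rng.normal(size=(64, 64))
        img = mt.project_and_mask(_toy_segment(sub), mask_half_width_px=100)
        np.testing.assert_allclose(
            img.data, sub[[1, 2, 4]].sum(axis=0), rtol=1e-4, atol=1e-6
        )

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            mt.project_and_mask(_toy_segment(np.zeros((4, 32, 32))))

    @pytest.mark.parametrize("tilt, applied", [(8.0, True), (6.0, False)])
    def test_out_of_plane_rule_at_7_degrees(self, tilt, applied):
        rng = np.random.default_rng(2)
        sub = rng.normal(size=(16, 64, 64)) + 5.0
        plain = mt.project_and_mask(_toy_segment(sub, tilt=0.0), mask_half_width_px=100)
        tilted = mt.project_and_mask(_toy_segment(sub, tilt=tilt), mask_half_width_px=100)
        same = np.allclose(plain.data, tilted.data)
        assert same != applied

    def test_mask_fill_is_image_mean(self):
        rng = np.random.default_rng(3)
        sub = rng.normal(size=(4, 64, 64))
        img = mt.project_and_mask(_toy_segment(sub), mask_half_width_px=10)
        fill = img.meta["mask_fill"]
        cols = np.abs(np.arange(64) - 31.5) > 10
        outside = img.data[:, cols]
        assert outside.sum() == pytest.approx(outside.size * fill, rel=1e-9)

    def test_polygon_mask(self):
        sub = np.ones((3, 64, 64))
        sub += np.random.default_rng(4).normal(size=sub.shape) * 0.01
        poly = np.array([[10, 10], [50, 10], [50, 50], [10, 50]], dtype=float)
        img = mt.project_and_mask(_toy_segment(sub), polygon=poly)
        fill = img.meta["mask_fill"]
        assert img.data[0, 0] == pytest.approx(fill)
        assert img.data[30, 30] != pytest.approx(fill)

    def test_non_simple_polygon_raises(self):
        sub = np.ones((3, 32, 32))
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(ValueError, match="simple"):
            mt.project_and_mask(_toy_segment(sub), polygon=bowtie)

    def test_projection_rotation_commutes(self):
        """Summing then rotating matches rotating the volume then summing
        (to interpolation tolerance) for an in-plane rotation."""
        rng = np.random.default_rng(5)
        sub = ndimage.gaussian_filter(rng.normal(size=(6, 96, 96)), 3.0)
        seg = _toy_segment(sub, angle=60.0)
        img = mt.project_and_mask(seg, mask_half_width_px=1000)
        rot3d = ndimage.rotate(sub, -30.0, axes=(1, 2), reshape=False, order=1)
        expected = rot3d.sum(axis=0)
        inner = (slice(30, 66), slice(30, 66))
        corr = np.corrcoef(img.data[inner].ravel(), expected[inner].ravel())[0, 1]
        assert corr > 0.99
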