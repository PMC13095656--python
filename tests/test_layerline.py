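"""Power spectra, profile summation, peak finding and the spacing formula."""

import numpy as np
import pytest

import mtlattice as mt
from mtlattice.lattice import LatticeParams, lattice_positions, layerline_offset_px
from mtlattice.layerline import (
    LayerLineProfile,
    find_layerline_peak,
    power_spectrum_2d,
    summed_profile,
)
from mtlattice.volume import Image2D


def synthetic_segment_image(spacing, box, pixel_size, sigma_A=6.0, rng=None, snr=None):
    """2D projection of a lattice: Gaussian blobs at projected subunit
    positions (axial coordinate along rows, matching the pipeline
    convention), optionally with additive noise."""
    pos = lattice_positions(LatticeParams(monomer_spacing=spacing), box * pixel_size)
    img = np.zeros((box, box))
    sig = sigma_A / pixel_size
    r = int(4 * sig) + 1
    cx = (box - 1) / 2.0
    for X, _, Z in pos:
        col, row = cx + X / pixel_size, Z / pixel_size
        rr = np.arange(max(0, int(row) - r), min(box, int(row) + r + 1))
        cc = np.arange(max(0, int(col) - r), min(box, int(col) + r + 1))
        img[np.ix_(rr, cc)] += np.exp(
            -((rr - row)[:, None] ** 2 + (cc - col)[None, :] ** 2) / (2 * sig * sig)
        )
    if snr is not None:
        img = img + rng.normal(0.0, np.sqrt(img.var() / snr), size=img.shape)
    return Image2D(img, pixel_size)


class TestPowerSpectrum2D:
    def test_cosine_peaks_at_exact_rows(self):
        box = 400
        y = np.arange(box)
        img = Image2D(np.cos(2 * np.pi * y / 20.0)[:, None] * np.ones((1, box)), 2.0)
        ps = power_spectrum_2d(img)
        v = ps.values.copy()
        c = box // 2
        v[c, c] = 0  # DC
        rows = np.argsort(v.max(axis=1))[-2:]
        assert sorted(rows) == [c - 20, c + 20]

    def test_parseval(self):
        rng = np.random.default_rng(0)
        img = Image2D(rng.normal(size=(64, 64)), 2.0)
        ps = power_spectrum_2d(img)
        assert ps.values.sum() == pytest.approx(
            64**2 * (img.data**2).sum(), rel=1e-6
        )

    def test_constant_image_all_dc(self):
        ps = power_spectrum_2d(Image2D(np.full((32, 32), 3.0), 2.0))
        v = ps.values.copy()
        assert v[16, 16] > 0
        v[16, 16] = 0
        assert np.all(np.abs(v) < 1e-6 * ps.values[16, 16])

    def test_friedel_symmetry(self):
        rng = np.random.default_rng(1)
        ps = power_spectrum_2d(Image2D(rng.normal(size=(64, 64)), 2.0))
        c = 32
        v = ps.values
        for r, col in [(10, 5), (40, 50), (20, 33)]:
            assert v[r, col] == pytest.approx(v[2 * c - r, 2 * c - col], rel=1e-6)

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            power_spectrum_2d(Image2D(np.zeros((32, 64)), 2.0))

    def test_padding_refines_grid_without_moving_peak(self):
        img = synthetic_segment_image(41.6, 256, 2.116)
        p1 = summed_profile([power_spectrum_2d(img, pad_factor=1)])
        p4 = summed_profile([power_spectrum_2d(img, pad_factor=4)])
        off1 = find_layerline_peak(p1).offset_px
        off4 = find_layerline_peak(p4).offset_px
        assert p4.box == 4 * p1.box
        s1 = mt.measure_spacing(2.116, p1.box, p1.equator_row, p1.equator_row + off1)
        s4 = mt.measure_spacing(2.116, p4.box, p4.equator_row, p4.equator_row + off4)
        assert s4 == pytest.approx(s1, abs=0.5)


class TestSummedProfile:
    def test_linearity(self):
        rng = np.random.default_rng(2)
        ps = power_spectrum_2d(Image2D(rng.normal(size=(64, 64)), 2.0))
        one = summed_profile([ps])
        five = summed_profile([ps] * 5)
        np.testing.assert_allclose(five.power, 5 * one.power, rtol=1e-12)
        assert five.n_summed == 5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        spectra = [
            power_spectrum_2d(Image2D(rng.normal(size=(64, 64)), 2.0)) for _ in range(4)
        ]
        a = summed_profile(spectra)
        b = summed_profile(spectra[::-1])
        np.testing.assert_allclose(a.power, b.power, rtol=1e-12)

    def test_mixed_geometry_names_offender(self):
        rng = np.random.default_rng(4)
        a = power_spectrum_2d(Image2D(rng.normal(size=(64, 64)), 2.0))
        b = power_spectrum_2d(Image2D(rng.normal(size=(32, 32)), 2.0))
        with pytest.raises(ValueError, match="spectrum 1"):
            summed_profile([a, b])

    def test_summation_improves_peak_contrast(self):
        """Summing noisy per-segment spectra must not degrade the layer
        line: contrast of the sum >= the median single-segment contrast."""
        rng = np.random.default_rng(5)
        spectra = [
            power_spectrum_2d(
                synthetic_segment_image(41.6, 256, 2.116, rng=rng, snr=0.25),
                pad_factor=2,
            )
            for _ in range(10)
        ]

        def contrast(profile):
            eq, box, px = profile.equator_row, profile.box, profile.pixel_size
            r_lo = int(np.ceil(box * px / 48.0))
            r_hi = int(np.floor(box * px / 37.0))
            w = profile.power[eq + r_lo : eq + r_hi + 1]
            return w.max() / np.median(w)

        summed = contrast(summed_profile(spectra))
        singles = sorted(contrast(summed_profile([ps])) for ps in spectra)
        assert summed >= singles[len(singles) // 2]


class TestFindLayerlinePeak:
    def _flat_profile(self, box=1000, px=2.116):
        return LayerLineProfile(
            power=np.zeros(box), box=box, pixel_size=px, equator_row=box // 2
        )

    def test_delta_profile_exact_offset(self):
        prof = self._flat_profile()
        prof.power[500 + 50] = 10.0
        prof.power[500 - 50] = 10.0
        res = find_layerline_peak(prof)
        assert res.found
        assert res.offset_px == pytest.approx(50.000, abs=1e-9)

    def test_parabolic_triplet_vertex(self):
        prof = self._flat_profile()
        prof.power[549:552] = [3.0, 5.0, 4.0]
        res = find_layerline_peak(prof, sides="upper")
        assert res.offset_px == pytest.approx(50 + 1 / 6, abs=1e-9)

    def test_no_peak_is_a_signal_not_an_exception(self):
        prof = self._flat_profile()
        prof.power[:] = 1.0  # flat: nothing exceeds 1.5x background
        res = find_layerline_peak(prof)
        assert not res.found
        assert res.offset_px is None

    def test_synthetic_43_1_offset(self):
        img = synthetic_segment_image(43.1, 1000, 2.116)
        prof = summed_profile([power_spectrum_2d(img)])
        res = find_layerline_peak(prof)
        expected = layerline_offset_px(43.1, 1000, 2.116)  # 49.10
        assert res.found
        assert res.offset_px == pytest.approx(expected, abs=0.5)

    def test_window_beyond_nyquist_raises(self):
        prof = self._flat_profile(px=25.0)
        with pytest.raises(ValueError):
            find_layerline_peak(prof, window=(37.0, 48.0))


class TestMeasureSpacing:
    @pytest.mark.parametrize(
        "px, box, eq, peak, expected",
        [
            (2.0, 1000, 500, 450, 40.0),
            (2.116, 1000, 500, 449.135, 41.60),
            (2.116, 1000, 500, 450.90, 43.10),
        ],
    )
    def test_printed_formula(self, px, box, eq, peak, expected):
        assert mt.measure_spacing(px, box, eq, peak) == pytest.approx(expected, abs=0.005)

    def test_uses_absolute_separation(self):
        assert mt.measure_spacing(2.0, 1000, 500, 550) == mt.measure_spacing(
            2.0, 1000, 500, 450
        )

    def test_zero_separation_raises(self):
        with pytest.raises(ValueError):
            mt.measure_spacing(2.0, 1000, 500, 500)

    def test_invariance_to_scaling_and_translation(self):
        img = synthetic_segment_image(41.6, 256, 2.116)
        base = find_layerline_peak(
            summed_profile([power_spectrum_2d(img, pad_factor=4)])
        ).offset_px
        scaled = Image2D(img.data * 7.3, img.pixel_size)
        rolled = Image2D(np.roll(img.data, 17, axis=0), img.pixel_size)
        for variant in (scaled, rolled):
            off = find_layerline_peak(
                summed_profile([power_spectrum_2d(variant, pad_factor=4)])
            ).offset_px
            assert off == pytest.approx(base, abs=0.05)
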