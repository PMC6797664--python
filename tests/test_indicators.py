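"""Indicator signals: HGD, RIA, ANG/DIS, CUR and the peak detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from conftest import digital_circle, digital_line
from vesselchar.indicators import (
    compute_ang_dis,
    compute_cur,
    compute_hgd,
    compute_ria,
    detect_peaks,
    ria_rotations,
    segment_curvature,
)
from vesselchar.segments import SegmentSet, VesselSegment, assign_reference


def _segset(*paths):
    return SegmentSet(segments=tuple(assign_reference(np.asarray(p)) for p in paths))


def _stripes(shape=(128, 128), period=8):
    img = np.zeros(shape)
    img[:, ::period] = 1.0
    return ndimage.gaussian_filter(img, 1.0)


class TestHGD:
    def test_unit_sum(self):
        h = compute_hgd(_stripes())
        assert h.min() >= 0
        assert np.isclose(h.sum(), 1.0)

    def test_flat_image_empty_histogram(self):
        assert compute_hgd(np.full((64, 64), 0.5)).sum() == 0.0

    def test_vertical_stripes_concentrate_two_opposite_bins(self):
        h = compute_hgd(_stripes())
        i, j = np.argsort(h)[-2:]
        sep = abs(i - j) * (360 / h.size)
        assert min(sep, 360 - sep) == pytest.approx(180, abs=4)
        assert h[i] + h[j] > 0.6

    def test_intensity_scale_invariant(self):
        img = _stripes()
        np.testing.assert_allclose(compute_hgd(img), compute_hgd(7.3 * img))

    def test_rot90_equivariance(self):
        img = ndimage.gaussian_filter(
            np.random.default_rng(0).standard_normal((128, 128)), 2.0
        )
        h0, h90 = compute_hgd(img), compute_hgd(np.rot90(img))
        shift = round(90 / (360 / h0.size))
        tv = min(
            0.5 * np.abs(np.roll(h0, s) - h90).sum() for s in (shift, -shift)
        )
        assert tv < 0.1


class TestRIA:
    def test_zero_image_zero_ria(self):
        assert np.all(compute_ria(np.zeros((64, 64))) == 0)

    def test_length_is_sum_of_rotated_row_counts(self):
        img = np.random.default_rng(1).random((48, 80))
        total = sum(len(s) for _, s in ria_rotations(img))
        assert compute_ria(img).size == total

    def test_horizontal_lines_give_k_peaks_at_zero_rotation(self):
        img = np.zeros((128, 128))
        rows = [20, 50, 80, 110]
        img[rows, :] = 1.0
        s0 = dict(ria_rotations(img))[0.0]
        peaks = detect_peaks(s0, prominence_frac=0.5)
        assert peaks.n_p == len(rows)

    def test_aligned_energy_exceeds_orthogonal(self):
        img = np.zeros((128, 128))
        img[[20, 50, 80, 110], :] = 1.0
        rots = dict(ria_rotations(img))
        assert (rots[0.0] ** 2).sum() > (rots[90.0] ** 2).sum()


class TestAngDis:
    def test_straight_row_segment(self):
        path = np.array([[10, c] for c in range(5, 30)])
        (ang,), (dis,) = compute_ang_dis(_segset(path))
        np.testing.assert_allclose(dis, np.arange(25.0))
        np.testing.assert_allclose(ang, 0.0)

    def test_right_angle_point(self):
        # C five pixels perpendicular to the AB baseline
        path = np.array([[10, 5], [11, 5], [12, 5], [13, 5], [14, 5], [15, 5]])
        (ang,), (dis,) = compute_ang_dis(_segset(path))
        assert dis[5] == pytest.approx(5.0)
        assert ang[5] == pytest.approx(90.0)

    def test_antiparallel_gives_180(self):
        path = np.array([[10, 5], [10, 4], [10, 3]])
        (ang,), _ = compute_ang_dis(_segset(path))
        assert ang[1] == pytest.approx(180.0)
        assert ang[2] == pytest.approx(180.0)

    def test_ranges_and_head_pixel(self):
        path = digital_circle(12, center=20.0)
        (ang,), (dis,) = compute_ang_dis(_segset(path))
        assert dis[0] == 0.0 and ang[0] == 0.0
        assert np.all(dis >= 0)
        assert np.all((ang >= 0) & (ang <= 180))

    def test_sinusoidal_segment_distance_non_monotone(self):
        t = np.linspace(0, 4 * np.pi, 300)
        path = np.stack([40 + 35 * np.sin(t), 5 + 8 * t], axis=1)
        path = np.round(path).astype(int)
        _, (dis,) = compute_ang_dis(_segset(path))
        flips = np.sum(np.abs(np.diff(np.sign(np.diff(dis)))) > 0)
        assert flips >= 2


class TestCurvature:
    def test_straight_lines_near_zero(self):
        for slope in (0.0, 0.3, 0.5, 1.0, 2.7):
            k = segment_curvature(digital_line(slope))
            assert np.abs(k).max() < 0.01, f"slope {slope}"

    @pytest.mark.parametrize("r", [10, 20, 40])
    def test_circle_matches_inverse_radius(self, r):
        k = segment_curvature(digital_circle(r))
        assert np.abs(k).mean() == pytest.approx(1.0 / r, rel=0.2)

    def test_concatenation_length(self):
        a, b = digital_line(0.0, 40), digital_circle(10)
        segs = _segset(a, b)
        assert compute_cur(segs).size == len(a) + len(b)

    def test_reversal_flips_sign_keeps_magnitude(self):
        path = digital_circle(15)
        k_f = segment_curvature(path)
        k_r = segment_curvature(path[::-1])
        np.testing.assert_allclose(
            np.abs(k_f), np.abs(k_r[::-1]), atol=1e-9
        )
        assert np.sign(np.median(k_f)) == -np.sign(np.median(k_r))


class TestDetectPeaks:
    def test_flat_signal_no_peaks(self):
        assert detect_peaks(np.ones(50)).n_p == 0

    def test_triangular_pulse(self):
        x = np.zeros(41)
        x[15:26] = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        p = detect_peaks(x)
        assert p.n_p == 1
        assert p.onset[0] <= 15 and p.offset[0] >= 25
        assert p.amplitude[0] == pytest.approx(1.0)

    def test_small_peak_below_prominence_dropped(self):
        g = np.linspace(-1, 1, 100)
        x = np.exp(-((g + 0.5) ** 2) / 0.005) + 0.05 * np.exp(
            -((g - 0.5) ** 2) / 0.005
        )
        assert detect_peaks(x, prominence_frac=0.1).n_p == 1

    def test_peak_count_monotone_in_prominence(self):
        rng = np.random.default_rng(4)
        x = ndimage.gaussian_filter1d(rng.standard_normal(300), 3)
        counts = [
            detect_peaks(x, prominence_frac=f).n_p
            for f in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=10, max_size=150))
    def test_peak_count_monotone_property(self, values):
        x = np.asarray(values)
        counts = [detect_peaks(x, f).n_p for f in (0.05, 0.2, 0.6)]
        assert counts[0] >= counts[1] >= counts[2]

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ang_dis_ranges_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        steps = rng.integers(-1, 2, size=(60, 2))
        steps[np.all(steps == 0, axis=1)] = (0, 1)
        path = np.cumsum(np.vstack([[50, 50], steps]), axis=0)
        (ang,), (dis,) = compute_ang_dis(_segset(path))
        assert np.all((ang >= 0) & (ang <= 180))
        assert np.all(dis >= 0) and dis[0] == 0.0

    def test_onsets_precede_offsets(self):
        rng = np.random.default_rng(9)
        x = ndimage.gaussian_filter1d(rng.standard_normal(200), 4)
        p = detect_peaks(x)
        assert np.all(p.onset < p.offset)
        assert np.all(p.amplitude > 0) and np.all(p.width > 0)
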