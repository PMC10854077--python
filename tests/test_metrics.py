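"""Postprocessing: crops, slices, band proportions, summaries, peak timing."""

import numpy as np
import pytest

from marrowflow.geometry import GeometrySpec, generate_trabecular
from marrowflow.metrics import (
    crop_center,
    crop_center_mask,
    fss_bin_proportions,
    peak_time,
    section_slices,
    summarize,
    time_fraction_in_band,
)
from marrowflow.stokes import InterfaceFSS
from marrowflow.waveforms import LoadSpec, displacement_rate

from conftest import make_block_domain


def voxel_centroids(domain):
    sl = domain.core_slices
    idx = np.argwhere(np.ones(domain.core.shape, dtype=bool))
    return (idx + np.array([s.start for s in sl]) + 0.5) * domain.pitch


def make_iface(points, fss, times):
    n = len(points)
    return InterfaceFSS(
        axes=np.zeros(n, dtype=int),
        normals=np.tile([1.0, 0, 0], (n, 1)),
        points=np.asarray(points, dtype=float),
        fss=np.asarray(fss, dtype=float),
        times=np.asarray(times, dtype=float),
    )


class TestCrop:
    def test_fraction_one_is_identity(self):
        dom = make_block_domain(16)
        pts = voxel_centroids(dom)
        vals = np.arange(len(pts), dtype=float)
        assert len(crop_center(vals, pts, dom, core_fraction=1.0)) == len(vals)

    def test_uniform_field_summary_unchanged(self):
        dom = make_block_domain(16)
        pts = voxel_centroids(dom)
        vals = np.full(len(pts), 3.14)
        s_all = summarize(vals)
        s_crop = summarize(crop_center(vals, pts, dom))
        assert s_crop.mean == s_all.mean and s_crop.sd == s_all.sd

    def test_48_grid_default_fraction_gives_42_subcube(self):
        dom = make_block_domain(48)
        pts = voxel_centroids(dom)
        mask = crop_center_mask(pts, dom, core_fraction=0.875)
        assert mask.sum() == 42**3

    def test_bad_fraction_rejected(self):
        dom = make_block_domain(8)
        with pytest.raises(ValueError):
            crop_center_mask(np.zeros((1, 3)), dom, core_fraction=0.0)


class TestSections:
    def test_half_height_layer_index(self):
        dom = make_block_domain(48)
        pts = voxel_centroids(dom)
        z = pts[:, 2]
        sl = section_slices(z, pts, dom, fractions=(0.5,))
        # layer 24 of the core -> centroids at (2 + 24 + 0.5) * pitch
        assert np.allclose(sl[0.5], (2 + 24 + 0.5) * dom.pitch)
        assert len(sl[0.5]) == 48 * 48

    def test_constant_field_slices_constant(self):
        dom = make_block_domain(16)
        pts = voxel_centroids(dom)
        vals = np.full(len(pts), 7.0)
        for v in section_slices(vals, pts, dom).values():
            assert np.allclose(v, 7.0)

    def test_monotone_field_orders_sections(self):
        """A field increasing with height gives 1/4 < 1/2 < 3/4 slice means."""
        dom = make_block_domain(32)
        pts = voxel_centroids(dom)
        vals = pts[:, 2] ** 1.5
        sl = section_slices(vals, pts, dom)
        assert sl[0.25].mean() < sl[0.5].mean() < sl[0.75].mean()


class TestBinProportions:
    def test_single_band(self):
        iface = make_iface(np.zeros((5, 3)), np.full((5, 1), 2.0), [0.0])
        bp = fss_bin_proportions(iface, 0.0)
        assert np.allclose(bp.proportions, [0, 0, 1, 0])

    def test_one_face_per_band(self):
        fss = np.array([[0.05], [0.5], [2.0], [5.0]])
        iface = make_iface(np.zeros((4, 3)), fss, [0.0])
        bp = fss_bin_proportions(iface, 0.0)
        assert np.allclose(bp.proportions, [0.25, 0.25, 0.25, 0.25])

    def test_partition_of_unity_on_simulation(self, cycle_small):
        for t in cycle_small.times:
            bp = fss_bin_proportions(cycle_small.interface, t)
            assert bp.proportions.sum() == pytest.approx(1.0, abs=1e-12)
            assert (bp.proportions >= 0).all()

    def test_band_edges_half_open(self):
        fss = np.array([[0.1], [1.0], [3.0]])
        iface = make_iface(np.zeros((3, 3)), fss, [0.0])
        bp = fss_bin_proportions(iface, 0.0)
        # 0.1 -> second band, 1.0 -> third, 3.0 -> fourth
        assert np.allclose(bp.proportions, [0, 1 / 3, 1 / 3, 1 / 3])

    def test_unsampled_time_rejected(self):
        iface = make_iface(np.zeros((2, 3)), np.ones((2, 2)), [0.0, 0.5])
        with pytest.raises(ValueError):
            fss_bin_proportions(iface, 0.123)


class TestTimeFraction:
    def test_always_in_band(self):
        iface = make_iface(np.zeros((4, 3)), np.full((4, 10), 2.0),
                           np.linspace(0, 0.9, 10))
        assert time_fraction_in_band(iface, (1.0, 3.0), 0.5) == 1.0

    def test_never_in_band(self):
        iface = make_iface(np.zeros((4, 3)), np.full((4, 10), 5.0),
                           np.linspace(0, 0.9, 10))
        assert time_fraction_in_band(iface, (1.0, 3.0), 0.5) == 0.0

    def test_sinusoidal_duty_cycle_matches_enumeration(self):
        """Faces scaled off a rectified cosine: in-band time computable by
        direct enumeration of the 20 samples."""
        times = np.arange(20) * 0.05
        amps = np.array([0.5, 1.5, 2.0, 2.9, 4.0, 8.0])
        fss = amps[:, None] * np.abs(np.cos(2 * np.pi * times))[None, :]
        iface = make_iface(np.zeros((len(amps), 3)), fss, times)
        got = time_fraction_in_band(iface, (1.0, 3.0), 0.5)
        # independent brute force
        count = 0
        for a in amps:
            in_band = [(1.0 <= a * abs(np.cos(2 * np.pi * t)) < 3.0)
                       for t in times]
            if sum(in_band) / len(times) > 0.5:
                count += 1
        assert got == pytest.approx(count / len(amps))

    def test_monotone_in_min_fraction(self, cycle_small):
        fr = [time_fraction_in_band(cycle_small.interface, (1.0, 3.0), m)
              for m in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(fr, fr[1:]))


class TestSummarize:
    def test_constant_field(self):
        s = summarize(np.full(10, 4.2))
        assert s.mean == pytest.approx(4.2, rel=1e-14)
        assert s.median == 4.2
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_small_example(self):
        s = summarize([1.0, 2.0, 3.0, 4.0])
        assert s.mean == 2.5 and s.median == 2.5

    def test_against_sorting_oracle(self):
        rng = np.random.default_rng(7)
        v = rng.standard_normal(1000)
        s = summarize(v)
        sv = np.sort(v)

        def q(p):
            # linear interpolation quantile on the sorted sample
            idx = p * (len(sv) - 1)
            lo = int(np.floor(idx))
            frac = idx - lo
            return sv[lo] * (1 - frac) + sv[min(lo + 1, len(sv) - 1)] * frac

        assert s.median == pytest.approx(q(0.5), rel=1e-12)
        assert s.q1 == pytest.approx(q(0.25), rel=1e-9)
        assert s.q3 == pytest.approx(q(0.75), rel=1e-9)
        assert s.sd == pytest.approx(np.sqrt(np.mean((v - v.mean()) ** 2)))

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestPeakTime:
    def test_rate_series_peaks_at_quarter(self):
        load = LoadSpec()
        times = np.arange(20) * 0.05
        series = np.abs(displacement_rate(times, load))
        assert peak_time(times, series, 1.0) == pytest.approx(0.25, abs=1e-12)

    def test_constant_series_returns_first_sample(self):
        times = np.arange(10) * 0.1
        assert peak_time(times, np.ones(10), 1.0) == 0.0

    def test_quadratic_refinement_off_sample(self):
        times = np.arange(16) / 16
        series = np.cos(2 * np.pi * (times - 0.27)) + 1
        assert peak_time(times, series, 1.0) == pytest.approx(0.27, abs=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            peak_time(np.arange(4) * 0.25, np.arange(4), 1.0)
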