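"""Structure-tensor orientation recovery, angle conventions, histograms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import circular_diff_deg
from situtomo.meniscus import (
    OrientationHistogram,
    average_histograms,
    orientation_histograms,
    structure_tensor_orientation,
    track_peak_height,
    vectors_to_angles,
)
from situtomo.synthetic import FiberPhantomSpec, gen_fiber_phantom


class TestAngleConvention:
    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    def test_antipodal_vectors_map_to_same_angles(self, v):
        v = np.asarray(v)
        if np.linalg.norm(v) < 1e-6:
            return
        phi1, th1 = vectors_to_angles(v)
        phi2, th2 = vectors_to_angles(-v)
        assert circular_diff_deg(float(phi1), float(phi2)) < 1e-9
        assert abs(float(th1) - float(th2)) < 1e-9

    def test_cardinal_directions(self):
        # (z, y, x) component order
        phi, th = vectors_to_angles(np.array([0.0, 0.0, 1.0]))
        assert (phi, th) == (0.0, 0.0)
        phi, th = vectors_to_angles(np.array([0.0, 1.0, 0.0]))
        assert (phi, th) == (90.0, 0.0)
        phi, th = vectors_to_angles(np.array([1.0, 0.0, 0.0]))
        assert (phi, th) == (0.0, 90.0)


class TestOrientationRecovery:
    def test_delta_phantom_recovered_within_2_degrees(self, delta_fiber_field):
        vol, truth, field = delta_fiber_field
        sel = vol.mask & field.valid_mask
        az = np.median(field.azimuth_deg[sel & field.azimuth_valid_mask])
        el = np.median(field.elevation_deg[sel])
        assert circular_diff_deg(az, truth.azimuth_deg[0]) < 2.0
        assert abs(el - truth.elevation_deg[0]) < 2.0

    def test_vertical_fibers_have_degenerate_azimuth(self):
        spec = FiberPhantomSpec(shape=(64, 64, 64), n_fibers=15,
                                elevation_deg=("delta", 90.0), noise_sd=0.1, seed=3)
        vol, _ = gen_fiber_phantom(spec)
        field = structure_tensor_orientation(vol)
        sel = vol.mask & field.valid_mask
        assert np.median(np.abs(field.elevation_deg[sel])) > 88.0
        # azimuth flagged meaningless where fibers are near-vertical
        assert (sel & field.azimuth_valid_mask).sum() < 0.5 * sel.sum()

    def test_invariant_to_intensity_scale_and_inversion(self, delta_fiber):
        vol, _ = delta_fiber
        f0 = structure_tensor_orientation(vol)
        scaled = type(vol)(data=vol.data * 3.7, voxel_size_um=vol.voxel_size_um)
        inverted = type(vol)(data=-vol.data, voxel_size_um=vol.voxel_size_um)
        for other in (scaled, inverted):
            f1 = structure_tensor_orientation(other)
            np.testing.assert_allclose(f1.azimuth_deg[f0.valid_mask],
                                       f0.azimuth_deg[f0.valid_mask], atol=1e-3)
            np.testing.assert_allclose(f1.elevation_deg[f0.valid_mask],
                                       f0.elevation_deg[f0.valid_mask], atol=1e-3)

    def test_angles_within_supports_and_coherence_bounded(self, delta_fiber_field):
        _, _, field = delta_fiber_field
        v = field.valid_mask
        assert np.all(field.azimuth_deg[v] >= 0) and np.all(field.azimuth_deg[v] < 180)
        assert np.all(np.abs(field.elevation_deg[v]) <= 90)
        assert np.all(field.coherence[v] >= 0) and np.all(field.coherence[v] <= 1 + 1e-6)

    def test_edge_voxels_marked_invalid(self, delta_fiber_field):
        _, _, field = delta_fiber_field
        margin = field.meta["edge_margin_px"]
        assert margin == 8
        assert not field.valid_mask[:margin].any()
        assert not field.valid_mask[:, :margin].any()

    def test_too_small_volume_rejected(self):
        from situtomo.io_core import Volume3D

        with pytest.raises(ValueError, match="too small"):
            structure_tensor_orientation(Volume3D(np.zeros((20, 64, 64), np.float32)))


class TestHistograms:
    def test_delta_phantom_mass_concentrated_at_truth(self, delta_fiber_field):
        vol, truth, field = delta_fiber_field
        az, el = orientation_histograms(field, mask=vol.mask)
        for hist, true_angle in ((az, truth.azimuth_deg[0]), (el, truth.elevation_deg[0])):
            centers = hist.bin_centers_deg
            period = 180.0 if hist.angle_kind == "azimuth" else 360.0
            near = np.array([circular_diff_deg(c, true_angle, period) <= 3.5
                             for c in centers])
            assert hist.counts_norm[near].sum() >= 0.90

    def test_counts_normalized(self, delta_fiber_field):
        _, _, field = delta_fiber_field
        az, el = orientation_histograms(field)
        assert az.counts_norm.sum() == pytest.approx(1.0, abs=1e-9)
        assert el.counts_norm.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_fibers_give_cosine_elevation_histogram(self):
        spec = FiberPhantomSpec(shape=(96, 96, 96), n_fibers=200,
                                azimuth_deg=("uniform",), elevation_deg=("uniform",),
                                noise_sd=0.2, seed=7)
        vol, _ = gen_fiber_phantom(spec)
        field = structure_tensor_orientation(vol)
        _, el = orientation_histograms(field, mask=vol.mask)
        coarse = el.counts_norm.reshape(12, 15).sum(axis=1)  # 15-degree bins
        edges = np.deg2rad(np.arange(-90, 91, 15))
        expected = np.diff(np.sin(edges)) / 2.0
        assert np.max(np.abs(coarse - expected)) < 0.06

    def test_empty_mask_rejected(self, delta_fiber_field):
        _, _, field = delta_fiber_field
        with pytest.raises(ValueError, match="valid voxels"):
            orientation_histograms(field, mask=np.zeros_like(field.valid_mask))


def _vonmises_histogram(kappa: float, n: int = 200_000, seed: int = 0) -> OrientationHistogram:
    rng = np.random.default_rng(seed)
    theta = np.rad2deg(rng.vonmises(0.0, kappa, n)) / 2.0  # concentrate near 0
    edges = np.arange(-90.0, 90.5, 1.0)
    counts, _ = np.histogram(theta, bins=edges)
    return OrientationHistogram(edges, counts / counts.sum(), "elevation")


class TestPeakTracking:
    def test_sharpening_histograms_give_increasing_peak_height(self):
        hists = {i: _vonmises_histogram(kappa) for i, kappa in enumerate([2, 5, 10, 30])}
        series = track_peak_height(hists)
        heights = [h for _, _, h in series]
        assert all(b > a for a, b in zip(heights, heights[1:]))

    def test_identical_histograms_give_constant_series(self):
        h = _vonmises_histogram(5)
        series = track_peak_height({0: h, 1: h, 2: h})
        assert len({(a, b) for _, a, b in series}) == 1

    def test_single_time_point(self):
        series = track_peak_height({0: _vonmises_histogram(5)})
        assert len(series) == 1

    def test_mismatched_binning_rejected(self):
        h1 = _vonmises_histogram(5)
        edges = np.arange(-90.0, 91.0, 2.0)
        counts = np.ones(len(edges) - 1)
        h2 = OrientationHistogram(edges, counts / counts.sum(), "elevation")
        with pytest.raises(ValueError, match="binned"):
            track_peak_height({0: h1, 1: h2})


def test_average_histograms_stays_normalized():
    hists = [_vonmises_histogram(k, n=10_000, seed=k) for k in (2, 5, 9)]
    avg = average_histograms(hists)
    assert avg.counts_norm.sum() == pytest.approx(1.0, abs=1e-9)
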