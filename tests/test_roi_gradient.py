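"""Seed selection, geodesic band dilation and gradient regression."""

import numpy as np
import pandas as pd
import pytest

from colliflow import (TriangleMesh, VertexHRFSet, band_profile,
                       dilate_band_rois, fit_gradient, select_seed_roi)
from colliflow.hrf_analysis import NHRF, PHRF
from colliflow.roi_gradient import SeedSelectionError


def _plane_mesh(n=41, spacing=0.25):
    """Regular triangulated square grid in the z = 0 plane."""
    xs = (np.arange(n) - n // 2) * spacing
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return TriangleMesh(verts, np.array(faces))


def _stats(mesh, amps, cnrs):
    return pd.DataFrame({
        "vertex": np.arange(len(mesh.vertices)),
        "class": PHRF,
        "peak_amplitude": amps,
        "peak_cnr": cnrs,
    })


class TestSeedSelection:
    def test_top_fraction_count(self):
        mesh = _plane_mesh(11, 1.0)
        n = len(mesh.vertices)
        rng = np.random.default_rng(0)
        amps = rng.permutation(n).astype(float)      # distinct amplitudes
        tab = _stats(mesh, amps, np.full(n, 5.0))
        # candidate count before the connected-component step
        cutoff = pd.Series(amps).quantile(0.8)
        assert np.sum(amps >= cutoff) == int(np.ceil(0.2 * n))

    def test_rostral_component_selected(self):
        mesh = _plane_mesh(21, 0.5)
        v = mesh.vertices
        amps = np.zeros(len(v))
        # two clusters of equal strength, one at x ~ +4, one at x ~ -4
        amps[np.linalg.norm(v[:, :2] - [4.0, 0.0], axis=1) < 1.0] = 2.0
        amps[np.linalg.norm(v[:, :2] + [4.0, 0.0], axis=1) < 1.0] = 2.0
        cnrs = np.where(amps > 0, 5.0, 0.1)
        tab = _stats(mesh, amps, cnrs)
        seed = select_seed_roi(tab, mesh, np.arange(len(v)),
                               np.array([1.0, 0.0, 0.0]), top_fraction=0.5)
        assert np.all(v[seed, 0] > 0)                # the +x cluster wins

    def test_singleton_candidate(self):
        mesh = _plane_mesh(11, 1.0)
        n = len(mesh.vertices)
        amps = np.zeros(n)
        amps[17] = 1.0
        cnrs = np.full(n, 0.5)
        cnrs[17] = 5.0
        tab = _stats(mesh, amps, cnrs)
        seed = select_seed_roi(tab, mesh, np.arange(n), np.array([1.0, 0, 0]))
        assert list(seed) == [17]

    def test_no_candidate_raises_with_diagnostics(self):
        mesh = _plane_mesh(11, 1.0)
        n = len(mesh.vertices)
        tab = _stats(mesh, np.ones(n), np.ones(n))   # all CNR == 1 < 3
        with pytest.raises(SeedSelectionError, match="CNR"):
            select_seed_roi(tab, mesh, np.arange(n), np.array([1.0, 0, 0]))

    def test_phantom_seed_near_rostral_pole(self, fast_result):
        truth = fast_result.dataset.truth
        for label, res in fast_result.sc_results.items():
            seed = res["_seed"]
            d = truth.rc_distance(fast_result.mesh_tectum.vertices[seed])
            assert d.min() <= 2.0


class TestBandDilation:
    def test_planar_annulus(self):
        mesh = _plane_mesh(41, 0.25)
        v = mesh.vertices
        sc = np.arange(len(v))
        seed = np.flatnonzero(np.linalg.norm(v[:, :2], axis=1) <= 3.0)
        bands = dilate_band_rois(seed, mesh, sc, band_mm=1.0)
        assert bands.n_bands >= 1
        r0 = np.linalg.norm(v[bands.bands[0], :2], axis=1)
        # band 0 is the annulus [3, 4) within one edge length of error
        edge = 0.25 * np.sqrt(2)
        assert np.all(r0 >= 3.0 - edge) and np.all(r0 <= 4.0 + edge)

    def test_seed_covering_sc_gives_zero_bands(self):
        mesh = _plane_mesh(11, 1.0)
        sc = np.arange(len(mesh.vertices))
        bands = dilate_band_rois(sc, mesh, sc)
        assert bands.n_bands == 0

    def test_empty_seed_rejected(self):
        mesh = _plane_mesh(5, 1.0)
        with pytest.raises(ValueError, match="empty"):
            dilate_band_rois(np.array([], dtype=int), mesh,
                             np.arange(len(mesh.vertices)))

    def test_seed_outside_sc_rejected(self):
        mesh = _plane_mesh(5, 1.0)
        with pytest.raises(ValueError, match="SC"):
            dilate_band_rois(np.array([0]), mesh, np.array([5, 6]))

    def test_phantom_band_count_and_containment(self, fast_result):
        for label, res in fast_result.sc_results.items():
            assert res["n_bands"] in (6, 7, 8)
            sc = set(fast_result.mesh_tectum.labels[label].tolist())
            bands = res["_bands"]
            for b in bands.bands:
                assert set(b.tolist()) <= sc

    def test_partition_and_disjointness(self, fast_result):
        for label, res in fast_result.sc_results.items():
            bands = res["_bands"]
            groups = [bands.seed] + list(bands.bands)
            all_v = np.concatenate(groups)
            assert len(all_v) == len(set(all_v.tolist()))
            finite = np.flatnonzero(np.isfinite(bands.geodesic_mm))
            sc = fast_result.mesh_tectum.labels[label]
            covered = set(all_v.tolist())
            assert set(np.intersect1d(finite, sc).tolist()) == covered

    def test_geodesic_at_least_chord(self, fast_result):
        label, res = sorted(fast_result.sc_results.items())[0]
        bands = res["_bands"]
        v = fast_result.mesh_tectum.vertices
        seed_pts = v[bands.seed]
        for b in bands.bands:
            for vi in b[::5]:
                chord = np.linalg.norm(seed_pts - v[vi], axis=1).min()
                assert bands.geodesic_mm[vi] >= chord - 1e-9


class TestBandProfile:
    def _vertex_set(self, epochs_by_vertex):
        ep = np.asarray(epochs_by_vertex)
        return VertexHRFSet(epochs=ep, vertex_ids=np.arange(len(ep)),
                            tr_s=1.25, depth_range_mm=(0.5, 2.0), rng_seed=0)

    def test_identical_vertices_match_single_vertex(self):
        from colliflow import synth_hrf_kernel
        from colliflow.roi_gradient import BandROISet
        rng = np.random.default_rng(0)
        base = synth_hrf_kernel(np.arange(21) * 1.25) + \
            rng.normal(0, 0.1, size=(85, 21))
        vs = self._vertex_set([base, base.copy()])
        single = BandROISet(seed=np.array([0]), bands=[])
        double = BandROISet(seed=np.array([0, 1]), bands=[])
        h1 = band_profile(single, vs, n_boot=300, rng_seed=4)[0]
        h2 = band_profile(double, vs, n_boot=300, rng_seed=4)[0]
        np.testing.assert_array_equal(h1.mean, h2.mean)
        np.testing.assert_array_equal(h1.ci_low, h2.ci_low)

    def test_noiseless_band_amplitudes_match_truth(self, noiseless_result):
        truth = noiseless_result.dataset.truth
        mesh = noiseless_result.mesh_tectum
        for label, res in noiseless_result.sc_results.items():
            bands = res["_bands"]
            profile = res["_profile"]
            for k, (roi, hrf) in enumerate(zip(
                    [bands.seed] + list(bands.bands), profile)):
                if hrf is None or hrf.label != PHRF:
                    continue
                true_mean = truth.amplitude(mesh.vertices[roi]).mean()
                if true_mean < 0.1:       # relative tolerance breaks near 0
                    continue
                assert hrf.peak_amplitude == pytest.approx(true_mean, rel=0.1)

    def test_noiseless_band_amplitudes_strictly_decreasing(self, noiseless_result):
        for label, res in noiseless_result.sc_results.items():
            amps = [a for a, h in zip(res["band_peak_amplitudes"],
                                      res["_profile"])
                    if h is not None and h.label == PHRF]
            assert np.all(np.diff(amps) < 0)

    def test_caudal_band_is_negative_response(self, noiseless_result):
        for label, res in noiseless_result.sc_results.items():
            assert res["band_classes"][-1] == NHRF


class TestFitGradient:
    def _mk(self, amps, label=PHRF):
        out = []
        for a in amps:
            t = np.arange(251) * 0.1
            mean = a * np.exp(-0.5 * ((t - 5.0) / 1.5) ** 2)
            from colliflow import BootstrappedHRF
            h = BootstrappedHRF(t=t, mean=mean, ci_low=mean - 0.01,
                                ci_high=mean + 0.01, n_epochs=85)
            from colliflow import classify_hrf
            out.append(classify_hrf(h))
        return out

    def test_perfect_decreasing_line(self):
        # amplitudes exactly linear in the ROI centres (seed at 0, band
        # k centred at (k + 0.5) mm)
        centers = np.array([0.0, 0.5, 1.5, 2.5, 3.5])
        fit = fit_gradient(self._mk(list(2.0 - 0.4 * centers)))
        assert fit.fitted and fit.slope < 0
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-9)
        assert fit.p_value < 1e-6
        assert fit.significant

    def test_flat_profile_not_significant(self):
        fit = fit_gradient(self._mk([1.0, 1.0, 1.0, 1.0]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.pearson_r == 0.0
        assert not fit.significant

    def test_too_few_phrf_bands(self):
        hrfs = self._mk([1.0, 0.5])
        fit = fit_gradient(hrfs)
        assert not fit.fitted and "pHRF" in fit.reason

    def test_normalized_distances_span_unit_interval(self):
        fit = fit_gradient(self._mk([2.0, 1.5, 1.0, 0.5]))
        assert fit.distances[0] == 0.0
        assert fit.distances[-1] == 1.0
        assert np.all(np.diff(fit.distances) > 0)
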