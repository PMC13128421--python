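"""Normalized depth, 5-point gradients, streamlines and thickness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colliflow import (gradient_field, normalized_depth, thickness_map,
                       trace_streamline, trace_streamlines)
from colliflow.depth_field import TerminationStatus, _trilinear, _world_to_voxel


class TestNormalizedDepth:
    @pytest.mark.parametrize("s_t,s_ca,expect", [
        (0.0, -3.0, 0.0),       # on the tectum surface
        (1.0, -1.0, 0.5),       # algebraic midpoint
        (2.0, 0.0, 1.0),        # at the CA interface
    ])
    def test_defining_equation(self, s_t, s_ca, expect):
        f = normalized_depth(np.full((5, 5, 5), s_t), np.full((5, 5, 5), s_ca))
        assert f.w[2, 2, 2] == pytest.approx(expect)

    def test_validity_mask(self):
        s_t = np.array([[[1.0, -1.0]]])
        s_ca = np.array([[[-1.0, -1.0]]])
        f = normalized_depth(s_t, s_ca)
        assert f.mask[0, 0, 0] and not f.mask[0, 0, 1]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            normalized_depth(np.zeros((3, 3, 3)), np.zeros((4, 3, 3)))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_self_reciprocity(self, seed):
        # swapping the surfaces maps w -> 1 - w wherever the denominator
        # is above the floor; sign conventions swap as S -> -S
        rng = np.random.default_rng(seed)
        s_t = rng.uniform(-3, 3, size=(4, 4, 4))
        s_ca = rng.uniform(-3, 3, size=(4, 4, 4))
        f = normalized_depth(s_t, s_ca)
        g = normalized_depth(-s_ca, -s_t)
        ok = np.abs(s_t - s_ca) > 1e-3
        np.testing.assert_allclose(g.w[ok], 1.0 - f.w[ok], atol=1e-9)


class TestGradientField:
    def test_linear_ramp(self):
        h = 0.5
        x = np.arange(8) * h
        w = np.broadcast_to(x[:, None, None] / 4.0, (8, 8, 8)).copy()
        g = gradient_field(w, h)
        np.testing.assert_allclose(g[2:-2, :, :, 0], 0.25, atol=1e-12)
        np.testing.assert_allclose(g[..., 1:], 0.0, atol=1e-12)

    def test_constant_field(self):
        g = gradient_field(np.full((6, 6, 6), 0.3), 1.0)
        np.testing.assert_allclose(g, 0.0, atol=1e-14)

    def test_quadratic_exact_at_interior(self):
        # the 5-point stencil is exact for cubics
        h = 0.25
        x = np.arange(12) * h
        w = np.broadcast_to((x**2)[:, None, None], (12, 12, 12)).copy()
        g = gradient_field(w, h)
        expect = 2 * x[2:-2]
        np.testing.assert_allclose(g[2:-2, 3, 3, 0],
                                   expect, rtol=0, atol=1e-10)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            gradient_field(np.zeros((4, 6, 6)), 1.0)


def _slab_depth(nz=30, thickness=3.0, voxel=0.25):
    """Planar slab: tectum plane at z=0, CA plane at z=-thickness."""
    n = nz
    aff = np.diag([voxel] * 3 + [1.0])
    aff[:3, 3] = [-n * voxel / 2, -n * voxel / 2, -thickness - 1.0]
    idx = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1)
    z = (idx @ aff[:3, :3].T + aff[:3, 3])[..., 2]
    s_t = -z                          # positive below the tectum plane
    s_ca = -z - thickness             # positive below the CA plane
    return normalized_depth(s_t, s_ca, aff)


class TestStreamlines:
    def test_slab_straight_trace(self):
        depth = _slab_depth()
        grad = gradient_field(depth.w, 0.25)
        s = trace_streamline(np.array([0.0, 0.0, 0.0]),
                             np.array([0.0, 0.0, -1.0]), grad, depth,
                             step_mm=0.1)
        assert s.status == TerminationStatus.REACHED_CA
        assert s.total_length == pytest.approx(3.0, abs=0.1 + 0.06)
        # straight polyline: x, y never move
        np.testing.assert_allclose(s.points[:, :2], 0.0, atol=1e-9)
        assert np.all(np.diff(s.arc_length) > 0)

    def test_degenerate_start_at_ca(self):
        depth = _slab_depth()
        grad = gradient_field(depth.w, 0.25)
        s = trace_streamline(np.array([0.0, 0.0, -2.99]),
                             np.array([0.0, 0.0, -1.0]), grad, depth)
        assert s.status == TerminationStatus.REACHED_CA
        assert s.total_length <= 0.1

    def test_sphere_phantom_radial_arc_length(self, fast_result):
        streams = fast_result.streamlines
        ok = np.array([st == TerminationStatus.REACHED_CA
                       for st in streams.status])
        assert ok.all()
        arc = streams.terminal_arc_length()
        assert np.all(np.abs(arc - 3.0) <= 2 * streams.step_mm + 0.08)

    def test_sphere_traces_are_radial(self, fast_result):
        streams = fast_result.streamlines
        devs = []
        for v in range(0, len(streams), 7):
            s = streams[v]
            u = s.points / np.linalg.norm(s.points, axis=1, keepdims=True)
            cos = np.clip(u @ u[0], -1, 1)
            devs.append(np.degrees(np.arccos(cos)).max())
        assert np.median(devs) <= 2.0

    def test_w_monotone_along_traces(self, fast_result):
        streams = fast_result.streamlines
        depth = fast_result.depth
        viol = 0
        for v in range(0, len(streams), 5):
            s = streams[v]
            wv = _trilinear(depth.w, _world_to_voxel(s.points, depth.affine))
            viol += np.sum(np.diff(wv) < -1e-6)
        assert viol == 0

    def test_endpoint_reaches_ca_interface(self, fast_result):
        streams = fast_result.streamlines
        depth = fast_result.depth
        ends = np.array([streams[v].points[-1] for v in range(len(streams))])
        s_ca = _trilinear(depth.s_ca, _world_to_voxel(ends, depth.affine))
        voxel_diag = np.sqrt(3) * depth.voxel_size_mm
        assert np.all(np.abs(s_ca) <= streams.step_mm + voxel_diag)


class TestThicknessMap:
    def test_sphere_shell_thickness(self, fast_result):
        th = fast_result.thickness_mm
        ok = np.isfinite(th)
        assert ok.all()
        rel = np.abs(th[ok] - 3.0) / 3.0
        assert np.mean(rel <= 0.05) >= 0.95

    def test_slab_thickness(self):
        depth = _slab_depth()
        grad = gradient_field(depth.w, 0.25)
        starts = np.array([[x, y, 0.0] for x in (-1.0, 0.0, 1.0)
                           for y in (-1.0, 0.0, 1.0)])
        normals = np.tile([0.0, 0.0, -1.0], (len(starts), 1))
        streams = trace_streamlines(starts, normals, grad, depth, step_mm=0.1)
        arc = streams.terminal_arc_length()
        assert np.all(np.abs(arc - 3.0) <= 0.16)

    def test_streamline_table_round_trip(self):
        depth = _slab_depth()
        grad = gradient_field(depth.w, 0.25)
        starts = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        normals = np.tile([0.0, 0.0, -1.0], (2, 1))
        streams = trace_streamlines(starts, normals, grad, depth, step_mm=0.1)
        tab = streams.to_frame()
        assert set(tab.columns) == {"vertex", "point", "x_mm", "y_mm", "z_mm",
                                    "arc_mm", "status"}
        assert set(tab["status"]) == {"reached_CA"}
        one = tab[tab.vertex == 0]
        np.testing.assert_allclose(one["arc_mm"],
                                   np.arange(len(one)) * 0.1, atol=1e-12)

    def test_failed_trace_yields_missing_value(self, fast_result):
        streams = fast_result.streamlines
        # forge one failed status and confirm it propagates as NaN
        status = streams.status.copy()
        status[3] = TerminationStatus.LEFT_DOMAIN
        forged = type(streams)(points=streams.points, n_points=streams.n_points,
                               step_mm=streams.step_mm, status=status)
        th = thickness_map(forged, fast_result.mesh_tectum)
        assert np.isnan(th[3]) and np.isfinite(th[4])
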