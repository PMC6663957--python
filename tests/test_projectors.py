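import math

import numpy as np
import pytest

from blockpet.projection_data import Bin, ProjData, ProjDataInfo, lor_from_bin
from blockpet.projectors import (CachedProjector, VoxelImage, back_project,
                                 forward_project, rays_for_bin, siddon_path)


def oracle_crossing_lengths(p1, p2, grid):
    """Independent per-voxel lengths: gather every axis-plane crossing, sort,
    and attribute each interval to the voxel containing its midpoint."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    d = p2 - p1
    h = np.array(grid.half_extent)
    n = np.array(grid.shape_xyz)
    v = np.array(grid.voxel_size)
    a0, a1 = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) > 1e-12:
            t = sorted([(-h[ax] - p1[ax]) / d[ax], (h[ax] - p1[ax]) / d[ax]])
            a0, a1 = max(a0, t[0]), min(a1, t[1])
        elif abs(p1[ax]) >= h[ax]:
            return {}, 0.0
    if a1 <= a0:
        return {}, 0.0
    alphas = [a0, a1]
    for ax in range(3):
        if abs(d[ax]) > 1e-12:
            planes = -h[ax] + v[ax] * np.arange(n[ax] + 1)
            a = (planes - p1[ax]) / d[ax]
            alphas.extend(a[(a > a0) & (a < a1)])
    alphas = np.unique(np.asarray(alphas))
    L = np.linalg.norm(d)
    out = {}
    for lo, hi in zip(alphas[:-1], alphas[1:]):
        if hi - lo < 1e-12:
            continue
        mid = p1 + (lo + hi) / 2.0 * d
        idx = np.floor((mid + h) / v).astype(int)
        if np.any(idx < 0) or np.any(idx >= n):
            continue
        key = (idx[2], idx[1], idx[0])  # (iz, iy, ix)
        out[key] = out.get(key, 0.0) + (hi - lo) * L
    return out, (a1 - a0) * L


def dense_sampling_lengths(p1, p2, grid, n_samples=100_000):
    """Brute-force oracle: equidistant points binned by containing voxel."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    t = (np.arange(n_samples) + 0.5) / n_samples
    pts = p1[None, :] + t[:, None] * (p2 - p1)[None, :]
    h = np.array(grid.half_extent)
    v = np.array(grid.voxel_size)
    n = np.array(grid.shape_xyz)
    idx = np.floor((pts + h) / v).astype(int)
    inside = np.all((idx >= 0) & (idx < n[None, :]), axis=1)
    inside &= np.all(np.abs(pts) < h[None, :], axis=1)
    step = np.linalg.norm(p2 - p1) / n_samples
    out = {}
    for iz, iy, ix in zip(idx[inside, 2], idx[inside, 1], idx[inside, 0]):
        out[(iz, iy, ix)] = out.get((iz, iy, ix), 0.0) + step
    return out


def random_detector_rays(rng, n, radius=12.0):
    """Ray endpoint pairs on a sphere surrounding the grid."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    w = rng.normal(size=(n, 3))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return radius * u, radius * w


class TestSiddonPath:
    def test_axis_aligned_unit_voxels(self):
        g = VoxelImage.zeros((5, 3, 3), (1.0, 1.0, 1.0))
        segs = siddon_path((-10.0, 0.2, 0.3), (10.0, 0.2, 0.3), g)
        assert len(segs) == 5
        assert all(s.length == pytest.approx(1.0, abs=1e-9) for s in segs)
        # ordered along the ray: x index increasing
        assert [s.voxel[2] for s in segs] == [0, 1, 2, 3, 4]

    def test_cube_main_diagonal(self):
        g = VoxelImage.zeros((1, 1, 1), (1.0, 1.0, 1.0))
        segs = siddon_path((-1.0, -1.0, -1.0), (1.0, 1.0, 1.0), g)
        assert len(segs) == 1
        assert segs[0].length == pytest.approx(math.sqrt(3), abs=1e-9)

    def test_miss_returns_empty(self):
        g = VoxelImage.zeros((3, 3, 3), (1.0, 1.0, 1.0))
        assert siddon_path((-10, 10, 0), (10, 10, 0), g) == []

    def test_degenerate_ray_raises(self):
        g = VoxelImage.zeros((3, 3, 3), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            siddon_path((1, 2, 3), (1, 2, 3), g)

    def test_against_plane_crossing_oracle(self, rng):
        g = VoxelImage.zeros((11, 11, 11), (1.0, 1.0, 1.0))
        p1s, p2s = random_detector_rays(rng, 200)
        for p1, p2 in zip(p1s, p2s):
            segs = siddon_path(p1, p2, g)
            got = {}
            for s in segs:
                got[s.voxel] = got.get(s.voxel, 0.0) + s.length
            want, chord = oracle_crossing_lengths(p1, p2, g)
            assert set(got) == set(want)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-9)
            assert sum(got.values()) == pytest.approx(chord, abs=1e-9)

    def test_against_dense_sampling_oracle(self, rng):
        g = VoxelImage.zeros((11, 11, 11), (1.0, 1.0, 1.0))
        p1s, p2s = random_detector_rays(rng, 20)
        for p1, p2 in zip(p1s, p2s):
            got = {}
            for s in siddon_path(p1, p2, g):
                got[s.voxel] = got.get(s.voxel, 0.0) + s.length
            want = dense_sampling_lengths(p1, p2, g)
            keys = set(got) | set(want)
            for k in keys:
                # sampling resolution limits the tolerance
                assert got.get(k, 0.0) == pytest.approx(want.get(k, 0.0),
                                                        abs=2e-3)

    def test_chord_conservation_anisotropic_grid(self, rng):
        g = VoxelImage.zeros((7, 9, 4), (0.7, 1.3, 2.1))
        p1s, p2s = random_detector_rays(rng, 100, radius=15.0)
        for p1, p2 in zip(p1s, p2s):
            segs = siddon_path(p1, p2, g)
            _, chord = oracle_crossing_lengths(p1, p2, g)
            assert sum(s.length for s in segs) == pytest.approx(chord, abs=1e-9)


class TestRaysForBin:
    def test_single_ray_is_nominal_lor(self, mini_info):
        b = Bin(0, 0, 1, 0)
        rays = rays_for_bin(b, mini_info, 1)
        lor = lor_from_bin(b, mini_info)
        assert len(rays) == 1
        assert np.allclose(rays[0][0], lor.p1)
        assert np.allclose(rays[0][1], lor.p2)

    def test_ten_rays_symmetric_zero_mean(self, mini_info):
        b = Bin(0, 0, 1, 0)
        rays = rays_for_bin(b, mini_info, 10)
        lor = lor_from_bin(b, mini_info)
        offs = [r[0] - lor.p1 for r in rays]
        assert np.allclose(np.mean(offs, axis=0), 0.0, atol=1e-12)
        norms = sorted(np.linalg.norm(o) for o in offs)
        assert norms[0] == pytest.approx(norms[1])  # pairwise symmetric

    def test_two_rays_at_quarter_pitch(self, mini_info):
        b = Bin(0, 0, 1, 0)
        rays = rays_for_bin(b, mini_info, 2)
        lor = lor_from_bin(b, mini_info)
        pitch = mini_info.spec.crystal_pitch_transaxial
        d1 = np.linalg.norm(rays[0][0] - lor.p1)
        d2 = np.linalg.norm(rays[1][0] - lor.p1)
        assert d1 == pytest.approx(pitch / 4, abs=1e-12)
        assert d2 == pytest.approx(pitch / 4, abs=1e-12)

    def test_invalid_ray_count(self, mini_info):
        with pytest.raises(ValueError):
            rays_for_bin(Bin(0, 0, 1, 0), mini_info, 0)


class TestForwardBackProject:
    def test_zero_image_projects_to_zero(self, mini_info, small_grid):
        assert forward_project(small_grid, mini_info, 1).total() == 0.0

    def test_zero_data_backprojects_to_zero(self, mini_info, small_grid):
        img = back_project(ProjData.zeros(mini_info), mini_info, 1,
                           grid=small_grid)
        assert np.all(img.values == 0)

    def test_linearity(self, mini_info, small_grid, rng):
        f1 = small_grid.like(rng.random(small_grid.values.shape))
        f2 = small_grid.like(rng.random(small_grid.values.shape))
        a, b = 2.5, -0.7
        lhs = forward_project(small_grid.like(a * f1.values + b * f2.values),
                              mini_info, 3).counts
        rhs = (a * forward_project(f1, mini_info, 3).counts
               + b * forward_project(f2, mini_info, 3).counts)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_hot_voxel_matches_siddon_recomputation(self, mini_info, small_grid,
                                                    rng):
        f = small_grid.copy()
        f.values[2, 10, 10] = 1.0
        fp = forward_project(f, mini_info, 1)
        for _ in range(20):
            s = rng.integers(0, mini_info.num_sinograms)
            v = rng.integers(0, mini_info.num_views)
            t = rng.integers(mini_info.tang_min, mini_info.tang_max + 1)
            # reconstruct the bin from the flat sinogram index
            for seg in mini_info.segments():
                for ax in range(mini_info.num_axial(seg)):
                    if mini_info.sinogram_index(seg, ax) == s:
                        b = Bin(seg, ax, int(v), int(t))
            lor = lor_from_bin(b, mini_info)
            expect = sum(seg.length for seg in siddon_path(lor.p1, lor.p2, f)
                         if seg.voxel == (2, 10, 10))
            assert fp.counts[s, v, t - mini_info.tang_min] == pytest.approx(
                expect, abs=1e-9)

    @pytest.mark.parametrize("n_rays", [1, 4])
    def test_adjoint_identity(self, mini_info, small_grid, rng, n_rays):
        for _ in range(10):
            f = small_grid.like(rng.random(small_grid.values.shape))
            q = ProjData(mini_info, rng.random(mini_info.shape))
            lhs = np.sum(forward_project(f, mini_info, n_rays).counts * q.counts)
            rhs = np.sum(f.values
                         * back_project(q, mini_info, n_rays,
                                        grid=small_grid).values)
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_one_bin_impulse_support(self, mini_info, small_grid):
        b = Bin(0, 0, 1, 0)
        q = ProjData.zeros(mini_info)
        q.counts[q.bin_index(b)] = 1.0
        img = back_project(q, mini_info, 1, grid=small_grid)
        lor = lor_from_bin(b, mini_info)
        expect = {s.voxel for s in siddon_path(lor.p1, lor.p2, small_grid)}
        got = {tuple(v) for v in np.argwhere(img.values > 0)}
        assert got == expect

    def test_cached_projector_matches_kernels(self, mini_info, small_grid, rng):
        f = small_grid.like(rng.random(small_grid.values.shape))
        q = rng.random(mini_info.shape)
        cp = CachedProjector(mini_info, small_grid, n_rays=3)
        fp = forward_project(f, mini_info, 3).counts
        np.testing.assert_allclose(cp.forward(f), fp, rtol=1e-9, atol=1e-12)
        bp = back_project(ProjData(mini_info, q), mini_info, 3, grid=small_grid)
        np.testing.assert_allclose(cp.back(q).values, bp.values, rtol=1e-9,
                                   atol=1e-12)
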