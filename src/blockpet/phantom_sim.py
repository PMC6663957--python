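"""Analytic stand-in for Monte Carlo acquisitions.

Phantoms are voxelized with 3x3x3 sub-voxel partial-volume sampling; the
acquisition model is back-to-back 511 keV emission, exact block-geometry
detection, water attenuation and Poisson counting noise.  Positron range,
non-collinearity, scatter and randoms are deliberately absent: ground truth is
always the block geometry, and the cylindrical pipeline only ever sees the
same data remapped onto the virtual cylindrical scanner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .corrections import MU_WATER_PER_CM, attenuation_sinogram
from .geometry import nearest_cylindrical_detector
from .projection_data import (BLOCKS, CYLINDRICAL, ProjData, ProjDataInfo,
                              bin_arrays_from_detector_pairs,
                              crystal_pair_tables)
from .projectors import VoxelImage, _forward_array

__all__ = [
    "PhantomSpec",
    "derenzo_sphere_layout",
    "voxelize_phantom",
    "simulate_acquisition",
    "simulate_plane_runs",
    "remap_to_cylindrical",
    "DEFAULT_SEED",
]

log = logging.getLogger(__name__)

DEFAULT_SEED = 20190729

_KINDS = ("derenzo", "uniform_cylinder", "point_source", "nema_iq", "plane_source")


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom kind plus kind-specific geometry parameters (mm).

    Recognized parameters by kind:

    * ``uniform_cylinder``: length, diameter, center (x, y, z)
    * ``point_source``: position (x, y, z), diameter
    * ``derenzo``: sphere_diameters (6 values), cylinder_diameter,
      cylinder_length, inner_margin
    * ``nema_iq``: rod_diameters, body_diameter, body_length, rod_circle_radius,
      cold_rod_diameter
    * ``plane_source``: width (transaxial), length (axial), thickness, angle (rad)
    """

    kind: str
    params: dict = field(default_factory=dict)
    total_counts: float = 1e6
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")


def derenzo_sphere_layout(sphere_diameters, cylinder_radius: float,
                          inner_margin: float = 2.0):
    """Sphere centers of a six-sector resolution phantom.

    Sector k holds spheres of the k-th diameter on a triangular lattice with
    center spacing twice the diameter, rows starting ``inner_margin`` plus one
    spacing from the phantom center, clipped to the cylinder and to the 60
    degree wedge.  Returns a list of (x, y, diameter).
    """
    diameters = list(sphere_diameters)
    if len(diameters) != 6:
        raise ValueError("derenzo layout needs exactly 6 sphere diameters")
    out = []
    for k, d in enumerate(diameters):
        s = 2.0 * d
        bisector = math.radians(60.0 * k + 30.0)
        r0 = inner_margin + s
        i = 0
        while True:
            r = r0 + i * s * math.sqrt(3.0) / 2.0
            if r + d / 2.0 > cylinder_radius - 0.5:
                break
            placed = False
            for j in range(i + 1):
                off = (j - i / 2.0) * s
                x = r * math.cos(bisector) - off * math.sin(bisector)
                y = r * math.sin(bisector) + off * math.cos(bisector)
                rr = math.hypot(x, y)
                if rr + d / 2.0 > cylinder_radius - 0.5:
                    continue
                ang = math.atan2(y, x) - bisector
                ang = (ang + math.pi) % (2 * math.pi) - math.pi
                if abs(ang) > math.radians(29.0):
                    continue
                out.append((x, y, d))
                placed = True
            if not placed and i > 0:
                break
            i += 1
    return out


def _subsample_indicator(grid: VoxelImage, indicator, n_sub: int = 3) -> np.ndarray:
    """Volume fraction per voxel of ``indicator(x, y, z)`` via sub-voxel sampling."""
    vx, vy, vz = grid.voxel_size
    frac = np.zeros(grid.values.shape)
    x, y, z = grid.coordinate_grids()
    offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    for oz in offs:
        for oy in offs:
            for ox in offs:
                frac += indicator(x + ox * vx, y + oy * vy, z + oz * vz)
    return frac / n_sub ** 3


def _cyl(x, y, z, cx, cy, cz, diameter, length):
    return (((x - cx) ** 2 + (y - cy) ** 2 <= (diameter / 2.0) ** 2)
            & (np.abs(z - cz) <= length / 2.0))


def voxelize_phantom(spec: PhantomSpec, grid: VoxelImage):
    """(activity, mu) images of the phantom on ``grid``.

    Activity is proportional to source volume per voxel; mu is
    ``MU_WATER_PER_CM`` in water regions and zero in air.  Features smaller
    than twice the voxel size trigger a warning, not an error.
    """
    p = spec.params
    min_vox = min(grid.voxel_size)

    def warn_small(feature):
        if feature < 2.0 * min_vox:
            log.warning("phantom feature %.3g mm below grid resolution %.3g mm",
                        feature, min_vox)

    if spec.kind == "uniform_cylinder":
        length = p.get("length", 25.0)
        diam = p.get("diameter", 60.0)
        cx, cy, cz = p.get("center", (0.0, 0.0, 0.0))
        warn_small(diam)
        act = _subsample_indicator(
            grid, lambda x, y, z: _cyl(x, y, z, cx, cy, cz, diam, length))
        mu = act * MU_WATER_PER_CM
        return grid.like(act), grid.like(mu)

    if spec.kind == "point_source":
        px, py, pz = p.get("position", (0.0, 0.0, 0.0))
        diam = p.get("diameter", 1.0)
        warn_small(diam)
        act = _subsample_indicator(
            grid, lambda x, y, z:
            (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2 <= (diam / 2.0) ** 2)
        if act.sum() == 0:  # ensure at least the containing voxel is hot
            act = np.zeros(grid.values.shape)
            ix = int(round(px / grid.voxel_size[0] + (grid.shape_xyz[0] - 1) / 2.0))
            iy = int(round(py / grid.voxel_size[1] + (grid.shape_xyz[1] - 1) / 2.0))
            iz = int(round(pz / grid.voxel_size[2] + (grid.shape_xyz[2] - 1) / 2.0))
            act[iz, iy, ix] = 1.0
        return grid.like(act), grid.like(np.zeros_like(act))

    if spec.kind == "derenzo":
        diams = p.get("sphere_diameters", (1.6, 1.8, 2.0, 2.2, 2.4, 2.8))
        cyl_d = p.get("cylinder_diameter", 30.0)
        cyl_l = p.get("cylinder_length", 25.0)
        margin = p.get("inner_margin", 2.0)
        warn_small(min(diams))
        spheres = derenzo_sphere_layout(diams, cyl_d / 2.0, margin)

        def act_ind(x, y, z):
            m = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape), dtype=bool)
            for sx, sy, d in spheres:
                m |= (x - sx) ** 2 + (y - sy) ** 2 + z ** 2 <= (d / 2.0) ** 2
            return m

        act = _subsample_indicator(grid, act_ind)
        water = _subsample_indicator(
            grid, lambda x, y, z: _cyl(x, y, z, 0, 0, 0, cyl_d, cyl_l))
        return grid.like(act), grid.like(water * MU_WATER_PER_CM)

    if spec.kind == "nema_iq":
        rod_d = p.get("rod_diameters", (1.0, 2.0, 3.0, 4.0, 5.0))
        body_d = p.get("body_diameter", 30.0)
        body_l = p.get("body_length", 50.0)
        rod_r = p.get("rod_circle_radius", 7.0)
        cold_d = p.get("cold_rod_diameter", 8.0)
        warn_small(min(rod_d))
        # rod section: lower 20 mm; hot chamber: upper 30 mm with two cold rods
        z_rod = (-body_l / 2.0, -body_l / 2.0 + 20.0)
        z_hot = (z_rod[1], body_l / 2.0)
        z_cold = (body_l / 2.0 - 15.0, body_l / 2.0)
        rods = [(rod_r * math.cos(2 * math.pi * i / len(rod_d)),
                 rod_r * math.sin(2 * math.pi * i / len(rod_d)), d)
                for i, d in enumerate(rod_d)]

        def act_ind(x, y, z):
            hot = ((x ** 2 + y ** 2 <= (body_d / 2.0) ** 2)
                   & (z > z_hot[0]) & (z <= z_hot[1]))
            for cx in (-7.5, 7.5):
                hot &= ~(((x - cx) ** 2 + y ** 2 <= (cold_d / 2.0) ** 2)
                         & (z > z_cold[0]))
            for rx, ry, d in rods:
                hot |= (((x - rx) ** 2 + (y - ry) ** 2 <= (d / 2.0) ** 2)
                        & (z > z_rod[0]) & (z <= z_rod[1]))
            return hot

        act = _subsample_indicator(grid, act_ind)
        water = _subsample_indicator(
            grid, lambda x, y, z: _cyl(x, y, z, 0, 0, 0, body_d, body_l))
        return grid.like(act), grid.like(water * MU_WATER_PER_CM)

    # plane_source
    width = p.get("width", 32.0)
    length = p.get("length", 120.0)
    thick = p.get("thickness", 1.0)
    angle = p.get("angle", 0.0)

    def plane_ind(x, y, z):
        along = x * math.cos(angle) + y * math.sin(angle)
        across = -x * math.sin(angle) + y * math.cos(angle)
        return ((np.abs(across) <= thick / 2.0) & (np.abs(along) <= width / 2.0)
                & (np.abs(z) <= length / 2.0))

    act = _subsample_indicator(grid, plane_ind)
    return grid.like(act), grid.like(np.zeros_like(act))  # air: no attenuation


def simulate_acquisition(activity: VoxelImage, mu: VoxelImage | None,
                         info_block: ProjDataInfo, total_counts: float,
                         seed: int, n_rays: int = 10) -> ProjData:
    """Poisson acquisition through the true block geometry.

    Expected data = attenuation x forward projection with an ``n_rays`` bundle,
    rescaled to ``total_counts`` expected coincidences; the output is a Poisson
    sample, deterministic for a fixed seed.
    """
    if info_block.mode != BLOCKS:
        raise ValueError("ground-truth acquisition requires a block-mode info")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    expected = _forward_array(activity, info_block, n_rays)
    if mu is not None and np.any(mu.values > 0):
        expected = expected * attenuation_sinogram(mu, info_block, 1).factors.counts
    s = expected.sum()
    if s > 0:
        expected *= total_counts / s
    rng = np.random.default_rng(seed)
    return ProjData(info_block, rng.poisson(expected).astype(np.float64))


def expected_acquisition(activity: VoxelImage, mu: VoxelImage | None,
                         info_block: ProjDataInfo, total_counts: float,
                         n_rays: int = 10) -> ProjData:
    """Noiseless expectation of :func:`simulate_acquisition` (same scaling)."""
    if info_block.mode != BLOCKS:
        raise ValueError("ground-truth acquisition requires a block-mode info")
    expected = _forward_array(activity, info_block, n_rays)
    if mu is not None and np.any(mu.values > 0):
        expected = expected * attenuation_sinogram(mu, info_block, 1).factors.counts
    s = expected.sum()
    if s > 0:
        expected *= total_counts / s
    return ProjData(info_block, expected)


def simulate_plane_runs(info_block: ProjDataInfo, grid: VoxelImage,
                        n_positions: int = 6, counts_per_position: float = 1e6,
                        seed: int = DEFAULT_SEED, n_rays: int = 10,
                        width: float = 32.0, length: float = 120.0,
                        noiseless: bool = False):
    """Rotating-plane acquisitions at equally spaced angles over 180 degrees.

    The plane is air-filled (no attenuation).  Returns (sinograms, angles).
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    angles = np.arange(n_positions) * math.pi / n_positions
    sinos = []
    for i, ang in enumerate(angles):
        spec = PhantomSpec("plane_source",
                           {"width": width, "length": length, "angle": float(ang)})
        act, _ = voxelize_phantom(spec, grid)
        if noiseless:
            sinos.append(expected_acquisition(act, None, info_block,
                                              counts_per_position, n_rays))
        else:
            sinos.append(simulate_acquisition(act, None, info_block,
                                              counts_per_position,
                                              seed + i, n_rays))
    return sinos, angles


def remap_to_cylindrical(data, info_cyl: ProjDataInfo) -> ProjData:
    """Re-bin block-truth data under the virtual cylindrical scanner.

    ``data`` is either a block-mode ProjData or an (n, 4) array of
    (ring1, crystal1, ring2, crystal2) events.  Each event's true Cartesian
    detection positions (block map) are assigned to the nearest cylindrical
    detectors, whose pair is then binned under the cylindrical convention;
    tangential positions are clipped into range so bin totals are conserved.
    This reproduces the remapping distortion of reconstructing block-scanner
    data with a cylindrical scanner model.
    """
    if info_cyl.mode != CYLINDRICAL:
        raise ValueError("target info must be cylindrical")
    from .geometry import build_block_detector_map

    block_map = build_block_detector_map(info_cyl.spec)
    cyl_map = info_cyl.detector_map

    if isinstance(data, ProjData):
        info_b = data.info
        c1, c2 = crystal_pair_tables(info_b)  # (nv, nt)
        r1, r2 = info_b.sinogram_rings()  # (ns,)
        # broadcast to the full bin grid
        ns = r1.size
        c1 = np.broadcast_to(c1[None, :, :], (ns,) + c1.shape)
        c2 = np.broadcast_to(c2[None, :, :], (ns,) + c2.shape)
        r1 = np.broadcast_to(r1[:, None, None], c1.shape)
        r2 = np.broadcast_to(r2[:, None, None], c1.shape)
        weights = data.counts
    else:
        ev = np.asarray(data, dtype=np.int64)
        r1, c1, r2, c2 = ev[:, 0], ev[:, 1], ev[:, 2], ev[:, 3]
        weights = np.ones(r1.shape)

    def to_cyl(r, c):
        return nearest_cylindrical_detector(
            cyl_map, block_map.xy[c, 0], block_map.xy[c, 1], block_map.z[r])

    r1c, c1c = to_cyl(r1, c1)
    r2c, c2c = to_cyl(r2, c2)
    # equal transaxial index after remapping has no tangential coordinate: nudge
    # one crystal onto its neighbour so the event lands in the nearest valid bin
    same = c1c == c2c
    if np.any(same):
        nd = info_cyl.spec.detectors_per_ring
        c2c = np.where(same, (c2c + 1) % nd, c2c)
    seg, ax, v, t, _ = bin_arrays_from_detector_pairs(r1c, c1c, r2c, c2c, info_cyl)
    t = np.clip(t, info_cyl.tang_min, info_cyl.tang_max)
    valid = np.abs(seg) <= info_cyl.max_ring_difference
    out = ProjData.zeros(info_cyl)
    sino = info_cyl.sinogram_index(seg[valid], ax[valid])
    np.add.at(out.counts, (sino, v[valid], t[valid] - info_cyl.tang_min),
              np.broadcast_to(weights, valid.shape)[valid])
    out.n_rejected = int(np.broadcast_to(weights, valid.shape)[~valid].sum())
    return out
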