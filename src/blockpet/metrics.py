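"""Image-quality metrics: COV, FWHM, peak-to-valley, spill-over, recovery.

ROI membership is decided by voxel-center inclusion and all standard
deviations are sample (ddof=1) ones, so every metric is invariant under global
positive scaling of the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .projectors import VoxelImage

__all__ = [
    "ROI",
    "RodSpec",
    "roi_mask",
    "cov",
    "fwhm",
    "spill_over_ratio",
    "peak_to_valley",
    "recovery_coefficients",
    "line_profile",
]


@dataclass(frozen=True)
class ROI:
    """kind: cylinder | sphere | annulus | circle.

    ``dimensions``: cylinder -> (diameter, length); sphere -> diameter;
    annulus -> (inner diameter, outer diameter), a 3D spherical shell;
    circle -> diameter (single transaxial slab one voxel thick at center z).
    """

    kind: str
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dimensions: tuple | float = ()

    def __post_init__(self):
        if self.kind not in ("cylinder", "sphere", "annulus", "circle"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "annulus":
            inner, outer = self.dimensions
            if not outer > inner > 0:
                raise ValueError("annulus requires outer > inner > 0")


def roi_mask(image: VoxelImage, roi: ROI) -> np.ndarray:
    x, y, z = image.coordinate_grids()
    cx, cy, cz = roi.center
    dx, dy, dz = x - cx, y - cy, z - cz
    if roi.kind == "cylinder":
        diam, length = roi.dimensions
        m = (dx ** 2 + dy ** 2 <= (diam / 2) ** 2) & (np.abs(dz) <= length / 2)
    elif roi.kind == "sphere":
        diam = float(np.atleast_1d(roi.dimensions)[0])
        m = dx ** 2 + dy ** 2 + dz ** 2 <= (diam / 2) ** 2
    elif roi.kind == "annulus":
        inner, outer = roi.dimensions
        r2 = dx ** 2 + dy ** 2 + dz ** 2
        m = (r2 > (inner / 2) ** 2) & (r2 <= (outer / 2) ** 2)
    else:  # circle
        diam = float(np.atleast_1d(roi.dimensions)[0])
        m = ((dx ** 2 + dy ** 2 <= (diam / 2) ** 2)
             & (np.abs(dz) <= image.voxel_size[2] / 2))
    return np.broadcast_to(m, image.values.shape)


def cov(image: VoxelImage, roi: ROI) -> float:
    """Coefficient of variation, 100 x sample STD / mean over the ROI."""
    vals = image.values[roi_mask(image, roi)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("ROI mean must be positive for COV")
    return float(100.0 * vals.std(ddof=1) / mean)


def fwhm(profile: np.ndarray, spacing: float) -> float:
    """Full width at half maximum of a 1D profile by linear interpolation."""
    p = np.asarray(profile, dtype=np.float64)
    m = int(np.argmax(p))
    half = p[m] / 2.0
    # left crossing
    i = m
    while i > 0 and p[i - 1] >= half:
        i -= 1
    if i == 0 and p[0] >= half:
        raise ValueError("half maximum not bracketed on the left")
    xl = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1])
    # right crossing
    j = m
    n = p.size
    while j < n - 1 and p[j + 1] >= half:
        j += 1
    if j == n - 1 and p[n - 1] >= half:
        raise ValueError("half maximum not bracketed on the right")
    xr = j + (p[j] - half) / (p[j] - p[j + 1])
    return float((xr - xl) * spacing)


def spill_over_ratio(image: VoxelImage, sphere_center, sphere_diameter: float) -> float:
    """mean(annular shell, 1x-2x diameter) / mean(sphere)."""
    sphere = ROI("sphere", tuple(sphere_center), sphere_diameter)
    shell = ROI("annulus", tuple(sphere_center),
                (sphere_diameter, 2.0 * sphere_diameter))
    ms, ma = roi_mask(image, sphere), roi_mask(image, shell)
    if not ms.any() or not ma.any():
        raise ValueError("empty ROI")
    denom = image.values[ms].mean()
    if denom == 0:
        return math.inf
    return float(image.values[ma].mean() / denom)


def peak_to_valley(profile: np.ndarray, expected_spacing: float,
                   spacing: float = 1.0) -> float:
    """Mean of profile peaks divided by mean of the valleys between them.

    ``expected_spacing`` is the source center-to-center distance in the same
    units as ``spacing`` (the sample step).  A constant profile gives 1.0;
    zero-valued valleys give inf.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.size < 3:
        raise ValueError("profile too short")
    if np.ptp(p) < 1e-12 * max(1.0, abs(p).max()):
        return 1.0
    dist = max(1, int(round(0.6 * expected_spacing / spacing)))
    peaks, _ = signal.find_peaks(p, distance=dist, height=0.5 * p.max())
    if peaks.size < 2:
        raise ValueError("fewer than two identifiable peaks")
    valleys = [p[peaks[i]:peaks[i + 1] + 1].min() for i in range(peaks.size - 1)]
    vmean = float(np.mean(valleys))
    pmean = float(p[peaks].mean())
    if vmean == 0:
        return math.inf
    return pmean / vmean


def line_profile(image: VoxelImage, start, stop, step: float | None = None):
    """Trilinear-interpolated samples along the segment start -> stop.

    Returns (samples, spacing).  Default step is half the smallest voxel size.
    """
    start = np.asarray(start, dtype=np.float64)
    stop = np.asarray(stop, dtype=np.float64)
    if step is None:
        step = min(image.voxel_size) / 2.0
    length = float(np.linalg.norm(stop - start))
    n = max(2, int(round(length / step)) + 1)
    pts = start[None, :] + np.linspace(0, 1, n)[:, None] * (stop - start)[None, :]
    nx, ny, nz = image.shape_xyz
    vx, vy, vz = image.voxel_size
    # world -> fractional (z, y, x) voxel coordinates
    coords = np.stack([
        pts[:, 2] / vz + (nz - 1) / 2.0,
        pts[:, 1] / vy + (ny - 1) / 2.0,
        pts[:, 0] / vx + (nx - 1) / 2.0,
    ])
    samples = ndimage.map_coordinates(image.values, coords, order=1,
                                      mode="constant", cval=0.0)
    return samples, length / (n - 1)


@dataclass(frozen=True)
class RodSpec:
    center_xy: tuple[float, float]
    diameter: float
    z_center: float  # axial center of the rod section
    z_length: float = 10.0  # axial slab averaged per NEMA NU-4


def recovery_coefficients(iq_image: VoxelImage, uniform_region_roi: ROI,
                          rod_specs) -> list[tuple[float, float]]:
    """NEMA NU-4 style recovery coefficients for hot rods.

    For each rod: average slices over the central slab of the rod section,
    locate the maximum pixel in a circle of twice the rod diameter around the
    nominal position, take the axial profile through that transverse location,
    then RC = mean(profile) / mean(uniform region) and
    %STD = 100 sqrt((STD_p/mean_p)^2 + (STD_u/mean_u)^2).
    """
    uvals = iq_image.values[roi_mask(iq_image, uniform_region_roi)]
    if uvals.size == 0:
        raise ValueError("empty uniform region")
    umean, ustd = uvals.mean(), uvals.std(ddof=1)
    x, y, z = iq_image.coordinate_grids()
    zc = z.ravel()
    out = []
    for rod in rod_specs:
        in_slab = np.abs(zc - rod.z_center) <= rod.z_length / 2.0
        if not in_slab.any():
            raise ValueError("rod slab outside image")
        slab = iq_image.values[in_slab, :, :].mean(axis=0)
        cx, cy = rod.center_xy
        search = ((x[0] - cx) ** 2 + (y[0] - cy) ** 2
                  <= rod.diameter ** 2)  # radius = 2 x rod radius
        if not search.any():
            raise ValueError("rod search region outside image")
        masked = np.where(search, slab, -np.inf)
        iy, ix = np.unravel_index(int(np.argmax(masked)), masked.shape)
        prof = iq_image.values[in_slab, iy, ix]
        pmean, pstd = prof.mean(), prof.std(ddof=1) if prof.size > 1 else 0.0
        rc = float(pmean / umean)
        pct = float(100.0 * math.sqrt((pstd / pmean) ** 2 + (ustd / umean) ** 2)
                    if pmean > 0 else math.inf)
        out.append((rc, pct))
    return out
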