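"""Normalization from rotating-plane-source scans and attenuation sinograms.

Normalization factors are built the measured way: from each plane position keep
the views nearly orthogonal to the plane, assemble one complete sinogram, add
symmetric views (the polygon's rotational period) and axially mirrored
positions to raise per-bin statistics, invert, cap the never-hit bins, and
rescale to mean one.

Attenuation factors are the per-ray exponential of the forward-projected
mu-map (mu in 1/cm, path lengths in mm), averaged over the ray bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .projection_data import ProjData, ProjDataInfo
from .projectors import VoxelImage, _forward_array, ray_offsets

__all__ = [
    "MU_WATER_PER_CM",
    "CoverageError",
    "NormalizationSinogram",
    "AttenuationSinogram",
    "extract_orthogonal_views",
    "build_normalization",
    "attenuation_sinogram",
]

MU_WATER_PER_CM = 0.096  # linear attenuation coefficient of water at 511 keV


class CoverageError(ValueError):
    """Plane positions do not cover all sinogram views."""


@dataclass
class NormalizationSinogram:
    factors: ProjData
    cap_value: float
    source_stats: float  # mean counts per folded bin over hit bins
    hit: np.ndarray = None  # bool mask: bins with counts inside the usable FOV


@dataclass
class AttenuationSinogram:
    factors: ProjData


def extract_orthogonal_views(plane_sino: ProjData | None, plane_angle: float,
                             info: ProjDataInfo, n_positions: int = 6,
                             n_views: int | None = None) -> np.ndarray:
    """Indices of the views most orthogonal to a plane source at ``plane_angle``.

    Returns ``num_views // n_positions`` (or ``n_views``) contiguous view
    indices (modulo num_views) centered on the view whose LOR azimuth is
    closest to ``plane_angle + pi/2``.  ``plane_sino`` is accepted for API
    symmetry; the selection is purely geometric.
    """
    if not 0.0 <= plane_angle < math.pi + 1e-12:
        raise ValueError("plane_angle must be in [0, pi)")
    nv = info.num_views
    n = nv // n_positions if n_views is None else n_views
    if n < 1:
        raise ValueError("selection would be empty")
    step = math.pi / nv  # view-angle increment
    target = (plane_angle + math.pi / 2.0) % math.pi
    center = int(round(target / step)) % nv
    return (center - n // 2 + np.arange(n)) % nv


def _axial_mirror_indices(info: ProjDataInfo) -> np.ndarray:
    """Flat sinogram index of the axially mirrored (segment, axial) plane."""
    mir = np.empty(info.num_sinograms, dtype=np.int64)
    for s in info.segments():
        ax = np.arange(info.num_axial(s))
        mir[info.sinogram_index(s, ax)] = info.sinogram_index(
            -s, info.num_axial(s) - 1 - ax)
    return mir


def fold_symmetric(counts: np.ndarray, info: ProjDataInfo) -> np.ndarray:
    """Sum rotationally symmetric views and mirrored axial positions.

    Views repeat with the polygon period (one view class per
    ``2 * num_views / n_sides`` indices); the folded sums are broadcast back to
    the full sinogram shape.
    """
    nv = info.num_views
    period = 2 * nv // info.spec.n_sides
    if period < 1 or nv % period:
        raise ValueError("view count is not divisible by the polygon period")
    ns, _, nt = counts.shape
    folded = counts.reshape(ns, nv // period, period, nt).sum(axis=1)
    folded = folded + folded[_axial_mirror_indices(info)]
    return np.tile(folded, (1, nv // period, 1))


def build_normalization(plane_sinos, angles, info: ProjDataInfo,
                        cap_value: float | None = None,
                        tangential_trim: int | None = None) -> NormalizationSinogram:
    """Normalization factors from rotating-plane acquisitions.

    ``angles`` must be equally spaced over 180 degrees and jointly cover all
    views.  Bins with zero folded counts get ``cap_value`` (default: the
    largest finite factor).  ``tangential_trim`` restricts the useful FOV: bins
    outside the central ``tangential_trim`` positions are also set to the cap.
    Factors are rescaled to mean 1 over the hit bins.
    """
    plane_sinos = list(plane_sinos)
    angles = np.asarray(angles, dtype=np.float64)
    if len(plane_sinos) != angles.size or angles.size < 1:
        raise ValueError("need one sinogram per plane angle")
    if angles.size > 1:
        expected = angles[0] + np.arange(angles.size) * math.pi / angles.size
        if not np.allclose(np.sort(angles % math.pi), np.sort(expected % math.pi),
                           atol=1e-9):
            raise ValueError("plane angles must be equally spaced over 180 degrees")

    nv = info.num_views
    assembled = np.zeros(info.shape)
    covered = np.zeros(nv, dtype=bool)
    for pd, ang in zip(plane_sinos, angles):
        views = extract_orthogonal_views(pd, ang % math.pi, info,
                                         n_positions=angles.size)
        if covered[views].any():
            raise CoverageError("extracted view sets overlap")
        covered[views] = True
        assembled[:, views, :] = pd.counts[:, views, :]
    if not covered.all():
        raise CoverageError(
            f"{int((~covered).sum())} of {nv} views not covered by any position")

    folded = fold_symmetric(assembled, info)
    usable = np.ones(info.shape, dtype=bool)
    if tangential_trim is not None:
        t = np.arange(info.tang_min, info.tang_max + 1)
        lo, hi = -(tangential_trim // 2), tangential_trim - 1 - tangential_trim // 2
        usable &= ((t >= lo) & (t <= hi))[None, None, :]
    hit = (folded > 0) & usable
    if not hit.any():
        raise ValueError("no usable counts in the plane acquisitions")

    with np.errstate(divide="ignore"):
        factors = np.where(hit, 1.0 / np.where(hit, folded, 1.0), np.inf)
    finite_max = factors[hit].max()
    cap = finite_max if cap_value is None else float(cap_value)
    factors = np.where(hit, factors, cap)
    scale = factors[hit].mean()
    factors = factors / scale
    return NormalizationSinogram(
        factors=ProjData(info, factors),
        cap_value=float(cap / scale),  # post-rescale value stored at never-hit bins
        source_stats=float(folded[hit].mean()),
        hit=hit,
    )


def attenuation_sinogram(mu: VoxelImage, info: ProjDataInfo,
                         n_rays: int = 1) -> AttenuationSinogram:
    """exp(-line integral of mu) per bin, averaged over the ray bundle.

    ``mu`` is in 1/cm; traced path lengths are mm, hence the factor 0.1.
    """
    if np.any(mu.values < 0):
        raise ValueError("attenuation map must be non-negative")
    offs = ray_offsets(n_rays, info.spec.crystal_pitch_transaxial)
    acc = np.zeros(info.shape)
    for o in offs:
        line = _forward_array(mu, info, 1, offsets=np.array([o]))
        acc += np.exp(-0.1 * line)
    return AttenuationSinogram(ProjData(info, acc / n_rays))
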