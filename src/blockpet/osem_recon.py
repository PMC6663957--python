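"""Fully-3D OSEM with a factorized normalization x attenuation x geometry model.

The forward model for measured data q is  q = diag(a / n) X f  where X is the
ray-traced geometry operator, a the attenuation factors in (0, 1] and n the
normalization factors (inverted plane-source data, so detection efficiency is
1/n).  Scatter and randoms are zero.  A subiteration is one subset update;
subsets partition the views by index modulo the subset count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .projection_data import ProjData, ProjDataInfo
from .projectors import VoxelImage, _back_array, _forward_array

__all__ = [
    "ReconConfig",
    "make_subsets",
    "sensitivity_image",
    "osem_reconstruct",
    "poisson_loglik",
    "fov_cylinder_mask",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconConfig:
    n_subsets: int = 1
    n_subiterations: int = 1
    n_rays: int = 10
    initial_value: float = 1.0
    nonneg_floor: float = 1e-20

    def __post_init__(self):
        if self.n_subsets < 1 or self.n_subiterations < 1:
            raise ValueError("n_subsets and n_subiterations must be >= 1")
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")


def make_subsets(info: ProjDataInfo, n_subsets: int) -> list[np.ndarray]:
    """Interleaved view subsets: subset k holds views congruent to k mod n."""
    if info.num_views % n_subsets:
        raise ValueError(
            f"n_subsets ({n_subsets}) must divide num_views ({info.num_views})")
    return [np.arange(k, info.num_views, n_subsets) for k in range(n_subsets)]


def _bin_weights(info: ProjDataInfo, norm: ProjData | None,
                 attn: ProjData | None) -> np.ndarray | None:
    """Per-bin model weights a/n; None when no corrections apply."""
    if norm is None and attn is None:
        return None
    w = np.ones(info.shape)
    if attn is not None:
        w = w * attn.counts
    if norm is not None:
        w = w / norm.counts
    return w


def sensitivity_image(info: ProjDataInfo, subset: np.ndarray,
                      norm: ProjData | None, attn: ProjData | None,
                      n_rays: int, grid: VoxelImage) -> VoxelImage:
    """Back-projection of the subset's model weights: (diag(a/n) X)^T 1."""
    w = _bin_weights(info, norm, attn)
    if w is None:
        q = np.ones((info.num_sinograms, len(subset), info.num_tangential))
    else:
        q = np.ascontiguousarray(w[:, subset, :])
    return _back_array(q, info, n_rays, grid, views=subset)


def fov_cylinder_mask(grid: VoxelImage) -> np.ndarray:
    """Voxels inside the largest transaxial cylinder fitting the grid."""
    x, y, _ = grid.coordinate_grids()
    r = min(grid.half_extent[0], grid.half_extent[1])
    return np.broadcast_to(x ** 2 + y ** 2 <= r ** 2, grid.values.shape)


def poisson_loglik(q: np.ndarray, qhat: np.ndarray,
                   floor: float = 1e-20) -> float:
    """Poisson log-likelihood sum(q log qhat - qhat), constants dropped."""
    qhat = np.maximum(qhat, floor)
    return float(np.sum(np.where(q > 0, q * np.log(qhat), 0.0) - qhat))


def osem_reconstruct(q: ProjData, info: ProjDataInfo, cfg: ReconConfig,
                     norm: ProjData | None = None,
                     attn: ProjData | None = None,
                     grid: VoxelImage | None = None,
                     callback=None) -> VoxelImage:
    """Multiplicative OSEM updates over interleaved view subsets.

    ``grid`` provides the output geometry; the initial estimate is
    ``cfg.initial_value`` inside the transaxial FOV cylinder.  ``callback``
    (if given) receives (subiteration index, current VoxelImage) after each
    subset update.  Voxels never seen by a subset stay at zero.
    """
    if grid is None:
        raise ValueError("osem_reconstruct needs an output grid template")
    if np.any(~np.isfinite(q.counts)) or np.any(q.counts < 0):
        raise ValueError("measured data must be finite and non-negative")
    f = grid.like(np.where(fov_cylinder_mask(grid), cfg.initial_value, 0.0))
    if q.counts.sum() == 0:
        log.warning("osem_reconstruct: all-zero data, returning zero image")
        return grid.like(np.zeros_like(grid.values))

    subsets = make_subsets(info, cfg.n_subsets)
    w = _bin_weights(info, norm, attn)
    sens = [sensitivity_image(info, sub, norm, attn, cfg.n_rays, grid)
            for sub in subsets]
    for it in range(cfg.n_subiterations):
        k = it % cfg.n_subsets
        sub = subsets[k]
        fp = _forward_array(f, info, cfg.n_rays, views=sub)
        qs = q.counts[:, sub, :]
        if w is None:
            ratio = qs / np.maximum(fp, cfg.nonneg_floor)
        else:
            ws = w[:, sub, :]
            ratio = ws * qs / np.maximum(ws * fp, cfg.nonneg_floor)
        bp = _back_array(ratio, info, cfg.n_rays, grid, views=sub)
        s = sens[k].values
        with np.errstate(invalid="ignore", divide="ignore"):
            f = grid.like(np.where(s > 0, f.values / s * bp.values, 0.0))
        if callback is not None:
            callback(it, f)
    return f
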