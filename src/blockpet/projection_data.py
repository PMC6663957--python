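"""Sinogram bin parameterization and conversions bin <-> detector pair <-> LOR.

Bins are indexed by (segment, axial position, view, tangential position) with
span-1 axial sampling (no compression) and crystal-index-based tangential
coordinates (no arc correction).  With ``Nd`` detectors per ring and
``h = Nd // 2``:

    view           v = ((c1 + c2 + h + 1) mod Nd) // 2          (in [0, h))
    tangential     t = ((c1 - c2) mod Nd) - h                   (in (-h, h))
    segment        s = ring(first) - ring(second)
    axial position a = min(r1, r2)

where "first"/"second" is the canonical ordering of the transaxial pair: the
unique ordering whose (v, t) inverts back to itself through

    c1 = (v + floor(t / 2)) mod Nd
    c2 = (v - floor((t + 1) / 2) + h) mod Nd

Exactly-opposed crystals (c2 = c1 + h) map to t = 0.  Two detectors with the
same transaxial index (a purely axial LOR) have no tangential coordinate and
are rejected, as are pairs outside the trimmed tangential range or beyond the
maximum ring difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (DetectorMap, ScannerSpec, build_block_detector_map,
                       build_cylindrical_detector_map)

__all__ = [
    "Bin",
    "LOR",
    "ProjDataInfo",
    "ProjData",
    "bin_from_detector_pair",
    "detector_pair_from_bin",
    "lor_from_bin",
    "histogram_listmode",
    "num_sinograms",
]

log = logging.getLogger(__name__)

CYLINDRICAL = "cylindrical"
BLOCKS = "blocks-on-cylindrical"


@dataclass(frozen=True)
class Bin:
    segment: int
    axial_pos: int
    view: int
    tangential_pos: int


@dataclass(frozen=True)
class LOR:
    p1: np.ndarray
    p2: np.ndarray


def _default_num_tangential(detectors_per_ring: int) -> int:
    n = detectors_per_ring // 2
    return n if n % 2 == 0 else n - 1


@dataclass
class ProjDataInfo:
    """Dimensions and geometry mode of a 3D sinogram stack."""

    spec: ScannerSpec
    mode: str = BLOCKS
    max_ring_difference: int | None = None
    num_tangential: int | None = None
    detector_map: DetectorMap = field(default=None, repr=False)

    def __post_init__(self):
        if self.mode not in (CYLINDRICAL, BLOCKS):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.max_ring_difference is None:
            self.max_ring_difference = self.spec.num_rings - 1
        if not 0 <= self.max_ring_difference < self.spec.num_rings:
            raise ValueError("max_ring_difference out of range")
        if self.num_tangential is None:
            self.num_tangential = _default_num_tangential(self.spec.detectors_per_ring)
        if not 1 <= self.num_tangential <= self.spec.detectors_per_ring - 1:
            raise ValueError("num_tangential must be in [1, detectors_per_ring - 1]")
        if self.detector_map is None:
            build = (build_block_detector_map if self.mode == BLOCKS
                     else build_cylindrical_detector_map)
            self.detector_map = build(self.spec)
        elif self.detector_map.mode != self.mode:
            raise ValueError("detector_map mode does not match info mode")
        # segment order -R..+R; cumulative sinogram offsets per segment
        R = self.max_ring_difference
        nax = [self.spec.num_rings - abs(s) for s in range(-R, R + 1)]
        self._seg_offsets = np.concatenate([[0], np.cumsum(nax)])

    @property
    def num_views(self) -> int:
        return self.spec.detectors_per_ring // 2

    @property
    def tang_min(self) -> int:
        return -(self.num_tangential // 2)

    @property
    def tang_max(self) -> int:
        return self.num_tangential - 1 + self.tang_min

    @property
    def num_sinograms(self) -> int:
        return int(self._seg_offsets[-1])

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.num_sinograms, self.num_views, self.num_tangential)

    def segments(self) -> range:
        return range(-self.max_ring_difference, self.max_ring_difference + 1)

    def num_axial(self, segment: int) -> int:
        return self.spec.num_rings - abs(segment)

    def sinogram_index(self, segment, axial_pos):
        """Flat sinogram index of (segment, axial_pos); broadcasts."""
        s = np.asarray(segment)
        return self._seg_offsets[s + self.max_ring_difference] + np.asarray(axial_pos)

    def sinogram_rings(self) -> tuple[np.ndarray, np.ndarray]:
        """(r_first, r_second) per flat sinogram index, canonical ordering."""
        r1 = np.empty(self.num_sinograms, dtype=np.int64)
        r2 = np.empty(self.num_sinograms, dtype=np.int64)
        for s in self.segments():
            ax = np.arange(self.num_axial(s))
            idx = self.sinogram_index(s, ax)
            r1[idx] = ax + s if s >= 0 else ax
            r2[idx] = ax if s >= 0 else ax - s
        return r1, r2

    def copy_with(self, **kw) -> "ProjDataInfo":
        args = dict(spec=self.spec, mode=self.mode,
                    max_ring_difference=self.max_ring_difference,
                    num_tangential=self.num_tangential)
        args.update(kw)
        if "mode" in kw and "detector_map" not in kw:
            args["detector_map"] = None
        return ProjDataInfo(**args)


@dataclass
class ProjData:
    """Dense 3D sinogram stack, [sinogram, view, tangential]."""

    info: ProjDataInfo
    counts: np.ndarray
    n_rejected: int = 0

    def __post_init__(self):
        if self.counts.shape != self.info.shape:
            raise ValueError(
                f"counts shape {self.counts.shape} != info shape {self.info.shape}")

    @classmethod
    def zeros(cls, info: ProjDataInfo) -> "ProjData":
        return cls(info, np.zeros(info.shape, dtype=np.float64))

    def bin_index(self, b: Bin) -> tuple[int, int, int]:
        return (int(self.info.sinogram_index(b.segment, b.axial_pos)),
                b.view, b.tangential_pos - self.info.tang_min)

    def __getitem__(self, b: Bin) -> float:
        return float(self.counts[self.bin_index(b)])

    def total(self) -> float:
        return float(self.counts.sum())


# -- core index arithmetic (vectorized) -----------------------------------------

def _inverse_crystals(v, t, nd):
    h = nd // 2
    c1 = (v + t // 2) % nd
    c2 = (v - (t + 1) // 2 + h) % nd
    return c1, c2


def bin_arrays_from_detector_pairs(r1, c1, r2, c2, info: ProjDataInfo):
    """Vectorized binning.  Returns (segment, axial, view, tang, accepted).

    Pairs with equal transaxial index, tangential position outside the trimmed
    range, or ring difference beyond the maximum are flagged not-accepted; their
    other outputs are undefined.
    """
    nd = info.spec.detectors_per_ring
    h = nd // 2
    r1 = np.asarray(r1, dtype=np.int64)
    c1 = np.asarray(c1, dtype=np.int64)
    r2 = np.asarray(r2, dtype=np.int64)
    c2 = np.asarray(c2, dtype=np.int64)
    for r, c in ((r1, c1), (r2, c2)):
        if np.any((r < 0) | (r >= info.spec.num_rings)):
            raise IndexError("ring index out of range")
        if np.any((c < 0) | (c >= nd)):
            raise IndexError("crystal index out of range")
    r1, c1, r2, c2 = np.broadcast_arrays(r1, c1, r2, c2)

    v = ((c1 + c2 + h + 1) % nd) // 2
    t_a = (c1 - c2) % nd - h
    i1, i2 = _inverse_crystals(v, t_a, nd)
    use_a = (i1 == c1) & (i2 == c2)
    t = np.where(use_a, t_a, (c2 - c1) % nd - h)
    seg = np.where(use_a, r1 - r2, r2 - r1)
    axial = np.minimum(r1, r2)
    accepted = ((c1 != c2)
                & (np.abs(seg) <= info.max_ring_difference)
                & (t >= info.tang_min) & (t <= info.tang_max))
    return seg, axial, v, t, accepted


def bin_from_detector_pair(d1, d2, info: ProjDataInfo) -> Bin | None:
    """Sinogram bin of a detector pair, or None when the pair is rejected.

    ``d1``/``d2`` are (ring, crystal) tuples.
    """
    seg, ax, v, t, ok = bin_arrays_from_detector_pairs(
        d1[0], d1[1], d2[0], d2[1], info)
    if not ok:
        return None
    return Bin(int(seg), int(ax), int(v), int(t))


def detector_pair_from_bin(b: Bin, info: ProjDataInfo):
    """Exact inverse of :func:`bin_from_detector_pair` (canonical ordering)."""
    if not 0 <= b.view < info.num_views:
        raise ValueError(f"view {b.view} out of range")
    if not info.tang_min <= b.tangential_pos <= info.tang_max:
        raise ValueError(f"tangential_pos {b.tangential_pos} out of range")
    if abs(b.segment) > info.max_ring_difference:
        raise ValueError(f"segment {b.segment} out of range")
    if not 0 <= b.axial_pos < info.num_axial(b.segment):
        raise ValueError(f"axial_pos {b.axial_pos} out of range")
    c1, c2 = _inverse_crystals(b.view, b.tangential_pos, info.spec.detectors_per_ring)
    if b.segment >= 0:
        r1, r2 = b.axial_pos + b.segment, b.axial_pos
    else:
        r1, r2 = b.axial_pos, b.axial_pos - b.segment
    return (r1, int(c1)), (r2, int(c2))


def crystal_pair_tables(info: ProjDataInfo):
    """Canonical (c1, c2) for every (view, tangential) of the sinogram grid."""
    v = np.arange(info.num_views)[:, None]
    t = np.arange(info.tang_min, info.tang_max + 1)[None, :]
    return _inverse_crystals(v, t, info.spec.detectors_per_ring)


def lor_from_bin(b: Bin, info: ProjDataInfo) -> LOR:
    """Cartesian LOR endpoints of a bin, read from the info's detector map."""
    (r1, c1), (r2, c2) = detector_pair_from_bin(b, info)
    m = info.detector_map
    return LOR(m.position(r1, c1), m.position(r2, c2))


def histogram_listmode(events, info: ProjDataInfo) -> ProjData:
    """Histogram (ring1, crystal1, ring2, crystal2) coincidence records.

    Accepts any iterable of 4-tuples or an (n, 4) integer array.  Each accepted
    event increments exactly one bin; rejected (out-of-range) events are counted
    on the result and logged.
    """
    ev = np.asarray(list(events) if not isinstance(events, np.ndarray) else events)
    pd = ProjData.zeros(info)
    if ev.size == 0:
        return pd
    if ev.ndim != 2 or ev.shape[1] != 4:
        raise ValueError(f"malformed event records: expected (n, 4), got {ev.shape}")
    if not np.issubdtype(ev.dtype, np.integer):
        evi = ev.astype(np.int64)
        if np.any(evi != ev):
            bad = int(np.argwhere(np.any(evi != ev, axis=1))[0, 0])
            raise ValueError(f"malformed event record {bad}: non-integer indices")
        ev = evi
    seg, ax, v, t, ok = bin_arrays_from_detector_pairs(
        ev[:, 0], ev[:, 1], ev[:, 2], ev[:, 3], info)
    sino = info.sinogram_index(seg[ok], ax[ok])
    np.add.at(pd.counts, (sino, v[ok], t[ok] - info.tang_min), 1.0)
    pd.n_rejected = int(ev.shape[0] - ok.sum())
    if pd.n_rejected:
        log.info("histogram_listmode: rejected %d / %d events",
                 pd.n_rejected, ev.shape[0])
    return pd


def num_sinograms(info: ProjDataInfo) -> int:
    """Total number of (segment, axial) sinogram planes."""
    return info.num_sinograms
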