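"""Detector coordinate maps for polygonal block scanners and their cylindrical idealization.

A block scanner consists of rectangular crystal blocks laid flat on the faces of a
regular polygonal prism.  Crystal-level gaps (within a block) and block-level gaps
(between blocks) differ, so detector centers are *not* equally spaced in azimuth or z.
The cylindrical idealization places the same number of detectors at uniform azimuthal
and axial spacing on a cylinder of the same inner radius; remapping block data onto it
is the distortion this package quantifies.

Conventions
-----------
* z runs along the scanner axis, origin at the geometric center of the scanner.
* Transaxial crystal index increases counter-clockwise viewed from +z; crystal 0 is
  the first crystal of polygon side 0, whose face is centered on the +x axis.
* Ring index increases with +z.
* Detection positions sit at depth ``average_doi`` behind the crystal inner face,
  i.e. at radial distance ``inner_radius + average_doi`` along each face's outward
  normal for the block model, and on a cylinder of that radius for the cylindrical
  model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryError",
    "ScannerSpec",
    "DetectorMap",
    "build_block_detector_map",
    "build_cylindrical_detector_map",
    "detection_position",
    "demo_ring_scanner",
    "demo_block_scanner",
    "demo_fine_block_scanner",
]


class GeometryError(ValueError):
    """Raised when a scanner specification is geometrically impossible."""


@dataclass(frozen=True)
class ScannerSpec:
    """Full parameterization of a blocks-on-cylindrical scanner.

    ``inner_radius`` is measured from the axis to the crystal inner faces (the flat
    block faces are tangent to the circle of this radius).  ``crystal_size`` is
    (transaxial, axial, depth) in mm.  ``average_doi`` is the assumed detection
    depth inside the crystals, measured inward from the inner face; when ``None``
    it defaults to half the crystal depth.
    """

    name: str
    inner_radius: float
    n_sides: int
    n_blocks_transaxial: int
    n_blocks_axial: int
    n_crystals_per_block_transaxial: int
    n_crystals_per_block_axial: int
    crystal_size: tuple[float, float, float]
    crystal_gap_transaxial: float = 0.0
    crystal_gap_axial: float = 0.0
    block_gap_transaxial: float = 0.0
    block_gap_axial: float = 0.0
    average_doi: float | None = None

    def __post_init__(self):
        if self.n_sides < 3:
            raise GeometryError("polygon needs at least 3 sides")
        if self.n_blocks_transaxial <= 0 or self.n_blocks_transaxial % self.n_sides:
            raise GeometryError(
                f"n_blocks_transaxial ({self.n_blocks_transaxial}) must be a "
                f"positive multiple of n_sides ({self.n_sides})"
            )
        for v in (self.n_blocks_axial, self.n_crystals_per_block_transaxial,
                  self.n_crystals_per_block_axial):
            if v <= 0:
                raise GeometryError("counts must be positive")
        if min(self.crystal_size) <= 0 or self.inner_radius <= 0:
            raise GeometryError("dimensions must be positive")
        if any(g < 0 for g in (self.crystal_gap_transaxial, self.crystal_gap_axial,
                               self.block_gap_transaxial, self.block_gap_axial)):
            raise GeometryError("gaps must be non-negative")
        if self.average_doi is None:
            object.__setattr__(self, "average_doi", self.crystal_size[2] / 2.0)
        if not 0.0 <= self.average_doi <= self.crystal_size[2]:
            raise GeometryError("average_doi must lie within the crystal depth")
        if self.transaxial_footprint > self.side_length + 1e-9:
            raise GeometryError(
                f"blocks overflow polygon side: footprint "
                f"{self.transaxial_footprint:.6g} mm > side length "
                f"{self.side_length:.6g} mm"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def num_rings(self) -> int:
        return self.n_blocks_axial * self.n_crystals_per_block_axial

    @property
    def detectors_per_ring(self) -> int:
        return self.n_blocks_transaxial * self.n_crystals_per_block_transaxial

    @property
    def blocks_per_side(self) -> int:
        return self.n_blocks_transaxial // self.n_sides

    @property
    def crystals_per_side(self) -> int:
        return self.blocks_per_side * self.n_crystals_per_block_transaxial

    @property
    def side_length(self) -> float:
        return 2.0 * self.inner_radius * math.tan(math.pi / self.n_sides)

    @property
    def block_width_transaxial(self) -> float:
        n, c, g = (self.n_crystals_per_block_transaxial, self.crystal_size[0],
                   self.crystal_gap_transaxial)
        return n * c + (n - 1) * g

    @property
    def block_length_axial(self) -> float:
        n, c, g = (self.n_crystals_per_block_axial, self.crystal_size[1],
                   self.crystal_gap_axial)
        return n * c + (n - 1) * g

    @property
    def transaxial_footprint(self) -> float:
        """Total width of one side's block assembly along the face."""
        b = self.blocks_per_side
        return b * self.block_width_transaxial + (b - 1) * self.block_gap_transaxial

    @property
    def crystal_pitch_transaxial(self) -> float:
        return self.crystal_size[0] + self.crystal_gap_transaxial

    @property
    def crystal_pitch_axial(self) -> float:
        return self.crystal_size[1] + self.crystal_gap_axial

    @property
    def detection_radius(self) -> float:
        return self.inner_radius + self.average_doi

    def axial_crystal_centers(self) -> np.ndarray:
        """z coordinates of the ``num_rings`` crystal centers, centered on 0."""
        z = np.empty(self.num_rings)
        block_step = self.block_length_axial + self.block_gap_axial
        for r in range(self.num_rings):
            b, j = divmod(r, self.n_crystals_per_block_axial)
            z[r] = b * block_step + j * self.crystal_pitch_axial
        return z - z.mean()

    def transaxial_offsets(self) -> np.ndarray:
        """Tangential offsets of one side's crystal centers about the face center."""
        t = np.empty(self.crystals_per_side)
        block_step = self.block_width_transaxial + self.block_gap_transaxial
        for i in range(self.crystals_per_side):
            b, j = divmod(i, self.n_crystals_per_block_transaxial)
            t[i] = (b * block_step + self.crystal_size[0] / 2.0
                    + j * self.crystal_pitch_transaxial)
        return t - self.transaxial_footprint / 2.0

    def with_axial_blocks(self, n_blocks_axial: int) -> "ScannerSpec":
        """Copy of this spec with a different axial block count (desk-scale runs)."""
        return replace(self, n_blocks_axial=n_blocks_axial)


@dataclass(frozen=True)
class DetectorMap:
    """Dense (ring, crystal) -> Cartesian detection-position table.

    Positions are separable: ``xy[crystal]`` holds the transaxial coordinates and
    ``z[ring]`` the axial coordinate, because both models are prisms.
    """

    mode: str  # "cylindrical" | "blocks-on-cylindrical"
    spec: ScannerSpec
    xy: np.ndarray = field(repr=False)  # (detectors_per_ring, 2)
    z: np.ndarray = field(repr=False)  # (num_rings,)

    @property
    def positions(self) -> np.ndarray:
        """(num_rings, detectors_per_ring, 3) array of detection positions."""
        nr, nd = self.z.size, self.xy.shape[0]
        out = np.empty((nr, nd, 3))
        out[:, :, :2] = self.xy[None, :, :]
        out[:, :, 2] = self.z[:, None]
        return out

    def position(self, ring: int, crystal: int) -> np.ndarray:
        if not (0 <= ring < self.z.size):
            raise IndexError(f"ring {ring} out of range [0, {self.z.size})")
        if not (0 <= crystal < self.xy.shape[0]):
            raise IndexError(f"crystal {crystal} out of range [0, {self.xy.shape[0]})")
        return np.array([self.xy[crystal, 0], self.xy[crystal, 1], self.z[ring]])


def build_block_detector_map(spec: ScannerSpec) -> DetectorMap:
    """Lay the blocks flat on the polygon faces and tabulate detection positions.

    Each side's block assembly is centered on its face; detection positions are
    offset by ``average_doi`` along the face's outward normal.
    """
    offsets = spec.transaxial_offsets()
    radial = spec.detection_radius
    nd = spec.detectors_per_ring
    xy = np.empty((nd, 2))
    for s in range(spec.n_sides):
        phi = 2.0 * math.pi * s / spec.n_sides
        normal = np.array([math.cos(phi), math.sin(phi)])
        tangent = np.array([-math.sin(phi), math.cos(phi)])
        lo = s * spec.crystals_per_side
        xy[lo:lo + spec.crystals_per_side] = (radial * normal[None, :]
                                              + offsets[:, None] * tangent[None, :])
    return DetectorMap("blocks-on-cylindrical", spec, xy, spec.axial_crystal_centers())


def build_cylindrical_detector_map(spec: ScannerSpec) -> DetectorMap:
    """Idealized map: equal azimuthal steps at the detection radius, uniform rings.

    The ring planes are equally spaced with the same first/last-ring span as the
    block layout, so both maps cover the same axial extent.
    """
    nd = spec.detectors_per_ring
    phi = 2.0 * math.pi * np.arange(nd) / nd
    xy = spec.detection_radius * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    zb = spec.axial_crystal_centers()
    if spec.num_rings > 1:
        z = np.linspace(zb[0], zb[-1], spec.num_rings)
    else:
        z = np.zeros(1)
    return DetectorMap("cylindrical", spec, xy, z)


def detection_position(det_map: DetectorMap, ring: int, crystal: int) -> np.ndarray:
    """Pure lookup of a stored detection position."""
    return det_map.position(ring, crystal)


def nearest_cylindrical_detector(det_map: DetectorMap, x, y, z):
    """Nearest (ring, crystal) of a *cylindrical* map to Cartesian points.

    Used to remap true block-geometry detection positions onto the virtual
    cylindrical scanner.  Inputs broadcast; returns integer arrays.
    """
    if det_map.mode != "cylindrical":
        raise ValueError("nearest-detector lookup requires a cylindrical map")
    spec = det_map.spec
    nd = spec.detectors_per_ring
    phi = np.arctan2(y, x)
    crystal = np.round(phi / (2.0 * math.pi / nd)).astype(np.int64) % nd
    if spec.num_rings > 1:
        pitch = det_map.z[1] - det_map.z[0]
        ring = np.round((np.asarray(z) - det_map.z[0]) / pitch).astype(np.int64)
        ring = np.clip(ring, 0, spec.num_rings - 1)
    else:
        ring = np.zeros_like(crystal)
    return ring, crystal


# -- demo scanners --------------------------------------------------------------
# Three designs exercised throughout the test suite: a single-crystal-per-block
# ring scanner (block and cylindrical layouts coincide up to face flatness), a
# dodecagonal 8x8-block scanner, and a finer 16x16 variant.

def demo_ring_scanner() -> ScannerSpec:
    """180 detectors/ring, 41 rings, 2.2 mm uniform pitch, single-crystal blocks."""
    return ScannerSpec(
        name="ring-180",
        inner_radius=63.02,
        n_sides=180,
        n_blocks_transaxial=180,
        n_blocks_axial=41,
        n_crystals_per_block_transaxial=1,
        n_crystals_per_block_axial=1,
        crystal_size=(2.0, 2.0, 12.0),
        crystal_gap_transaxial=0.2,
        crystal_gap_axial=0.2,
        block_gap_transaxial=0.2,
        block_gap_axial=0.2,
    )


def demo_block_scanner() -> ScannerSpec:
    """Dodecagon, 24x2 blocks of 8x8 crystals of 2.1 mm, gaps 0.1/0.6 mm."""
    return ScannerSpec(
        name="dodecagon-8x8",
        inner_radius=67.75,
        n_sides=12,
        n_blocks_transaxial=24,
        n_blocks_axial=2,
        n_crystals_per_block_transaxial=8,
        n_crystals_per_block_axial=8,
        crystal_size=(2.1, 2.1, 12.0),
        crystal_gap_transaxial=0.1,
        crystal_gap_axial=0.1,
        block_gap_transaxial=0.6,
        block_gap_axial=0.6,
    )


def demo_fine_block_scanner() -> ScannerSpec:
    """Dodecagon, 24x2 blocks of 16x16 crystals of 1.0 mm, gaps 0.1/0.3 mm."""
    return ScannerSpec(
        name="dodecagon-16x16",
        inner_radius=67.0,
        n_sides=12,
        n_blocks_transaxial=24,
        n_blocks_axial=2,
        n_crystals_per_block_transaxial=16,
        n_crystals_per_block_axial=16,
        crystal_size=(1.0, 1.0, 10.0),
        crystal_gap_transaxial=0.1,
        crystal_gap_axial=0.1,
        block_gap_transaxial=0.3,
        block_gap_axial=0.3,
    )
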