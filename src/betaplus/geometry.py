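"""Linear DNA scoring geometry and the surrounding volumetric source.

The model is a straight (untwisted by default) double helix abstraction:
a cylinder of 100 base pairs, 34 nm long, 2.37 nm outer diameter.  Each
base pair occupies an axial slab of height ``rise_per_base``.  Within a
slab the cross-section is partitioned into

* two half-cylinder *base* sectors (r < base_diameter/2), one per strand;
* two quarter-cylinder *backbone* sectors in the annulus
  base_diameter/2 <= r < outer_diameter/2, centred at azimuth 0 deg
  (strand 0) and 180 deg (strand 1);
* the remaining half of the annulus, which is not a scoring volume.

Boundary convention: all intervals are half-open with the lower bound
inclusive (axial, radial and azimuthal).  Coordinates are in nm with the
DNA axis along z and the origin at the bottom slab face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from enum import Enum
from typing import Optional, Tuple

import numpy as np
import yaml

__all__ = [
    "Region",
    "VolumeID",
    "DNAGeometry",
    "SourceVolume",
    "build_geometry",
    "classify_point",
    "classify_points",
    "default_source",
    "sample_source_points",
    "isotropic_directions",
]


class Region(Enum):
    OUTSIDE = 0
    BACKBONE = 1
    BASE = 2


@dataclass(frozen=True)
class VolumeID:
    """Classification of a 3-D point into a scoring volume."""

    region: Region
    strand: Optional[int] = None  # 0 | 1, None outside
    base_index: Optional[int] = None  # [0, n_bases), None outside


@dataclass(frozen=True)
class DNAGeometry:
    """Dimensions of the linear DNA model (all lengths in nm)."""

    n_bases: int = 100
    total_length: float = 34.0
    outer_diameter: float = 2.37
    base_diameter: float = 1.0
    twist_per_base_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bases < 1:
            raise ValueError("n_bases must be >= 1")
        for name in ("total_length", "outer_diameter", "base_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.base_diameter < self.outer_diameter:
            raise ValueError("base_diameter must be smaller than outer_diameter")

    @property
    def rise_per_base(self) -> float:
        return self.total_length / self.n_bases

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def base_radius(self) -> float:
        return self.base_diameter / 2.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DNAGeometry":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DNAGeometry":
        return cls.from_dict(yaml.safe_load(text))


def build_geometry(**params) -> DNAGeometry:
    """Construct a validated :class:`DNAGeometry` (defaults are the
    100-bp / 34 nm / 2.37 nm / 1 nm model)."""
    return DNAGeometry(**params)


def classify_points(
    geom: DNAGeometry, points: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised classification of an (n, 3) array of points.

    Returns ``(region, strand, base_index)`` integer arrays; for points
    outside any scoring volume ``region == Region.OUTSIDE.value`` and
    strand / base_index are -1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    n = len(pts)
    region = np.zeros(n, dtype=np.int8)
    strand = np.full(n, -1, dtype=np.int64)
    base = np.full(n, -1, dtype=np.int64)

    k = np.floor(z / geom.rise_per_base).astype(np.int64)
    r = np.hypot(x, y)
    inside = (z >= 0) & (k < geom.n_bases) & (r < geom.outer_radius)
    # guard z == total_length edge where floor gives n_bases exactly
    if not np.any(inside):
        return region, strand, base

    phi = np.degrees(np.arctan2(y, x))  # (-180, 180]
    phi_eff = np.mod(phi - geom.twist_per_base_deg * k, 360.0)

    is_base = inside & (r < geom.base_radius)
    # base half-cylinders: strand 0 covers [-90, 90) deg, strand 1 the rest
    phi_b = np.mod(phi_eff + 90.0, 360.0)
    region[is_base] = Region.BASE.value
    strand[is_base] = np.where(phi_b[is_base] < 180.0, 0, 1)
    base[is_base] = k[is_base]

    annulus = inside & (r >= geom.base_radius)
    # backbone quarter-cylinders centred at 0 deg (strand 0) / 180 deg (strand 1)
    phi_q = np.mod(phi_eff + 45.0, 360.0)
    s0 = annulus & (phi_q < 90.0)
    s1 = annulus & (phi_q >= 180.0) & (phi_q < 270.0)
    for mask, s in ((s0, 0), (s1, 1)):
        region[mask] = Region.BACKBONE.value
        strand[mask] = s
        base[mask] = k[mask]
    return region, strand, base


def classify_point(geom: DNAGeometry, point) -> VolumeID:
    """Classify one 3-D point (nm) into its scoring volume."""
    region, strand, base = classify_points(geom, np.asarray(point, dtype=float))
    reg = Region(int(region[0]))
    if reg is Region.OUTSIDE:
        return VolumeID(reg)
    return VolumeID(reg, int(strand[0]), int(base[0]))


@dataclass(frozen=True)
class SourceVolume:
    """Cylindrical volumetric source coaxial with the DNA.

    ``z_min`` is the lower axial face in the DNA frame.  The default
    source (see :func:`default_source`) encloses the DNA model entirely.
    """

    radius: float
    length: float
    z_min: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("source dimensions must be positive")

    def encloses(self, geom: DNAGeometry) -> bool:
        return (
            self.radius >= geom.outer_radius
            and self.z_min <= 0
            and self.z_min + self.length >= geom.total_length
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SourceVolume":
        return cls(**d)


def default_source(geom: DNAGeometry) -> SourceVolume:
    """Default source: radius twice the DNA outer radius, extending one
    outer radius beyond each DNA end.  The source overlaps the scoring
    region — emission from inside the DNA volumes is permitted."""
    r = geom.outer_radius
    return SourceVolume(radius=2.0 * r, length=geom.total_length + 2.0 * r, z_min=-r)


def backbone_point(geom: DNAGeometry, strand: int, base_index: int) -> np.ndarray:
    """Center point (nm) of the backbone volume (strand, base_index).

    Useful for constructing event streams with known scoring outcomes.
    """
    if strand not in (0, 1):
        raise ValueError("strand must be 0 or 1")
    if not 0 <= base_index < geom.n_bases:
        raise ValueError("base_index out of range")
    r = 0.5 * (geom.base_radius + geom.outer_radius)
    phi = math.radians(180.0 * strand + geom.twist_per_base_deg * base_index)
    z = (base_index + 0.5) * geom.rise_per_base
    return np.array([r * math.cos(phi), r * math.sin(phi), z])


def sample_source_points(
    src: SourceVolume, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Uniform points in the source cylinder, shape (n, 3), nm."""
    u = rng.random(n)
    r = src.radius * np.sqrt(u)
    phi = rng.random(n) * 2.0 * math.pi
    z = src.z_min + rng.random(n) * src.length
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def isotropic_directions(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Unit vectors uniform on the sphere, shape (n, 3)."""
    cos_t = 1.0 - 2.0 * rng.random(n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = rng.random(n) * 2.0 * math.pi
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
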