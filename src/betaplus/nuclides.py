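"""Radionuclide decay data and elementary decay mathematics.

Energies on nuclide records are stored in keV (the unit in which beta
spectra are tabulated); dose calculations convert to joules at the point
of use. Times are seconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "RadionuclideData",
    "F18",
    "builtin_f18",
    "decay_constant",
    "activity_at",
    "register_nuclide",
    "get_nuclide",
    "nuclide_from_dict",
    "nuclide_from_yaml",
]

#: keV -> joule
KEV_TO_J = 1.602176634e-16
MINUTE = 60.0
HOUR = 3600.0


@dataclass(frozen=True)
class RadionuclideData:
    """Decay parameters of a beta-plus emitting radionuclide.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"F-18"``.
    half_life : float
        Physical half-life in seconds.
    branching_beta_plus : float
        Fraction of decays proceeding through positron emission, in [0, 1].
    mean_beta_energy : float
        Mean kinetic energy of the emitted positron spectrum, keV.
    max_beta_energy : float
        Endpoint (maximum) energy of the positron spectrum, keV.
    mean_range_water, max_range_water : float, optional
        CSDA-style ranges in water, mm.  Metadata only; not used in the
        dose calculation.
    """

    name: str
    half_life: float
    branching_beta_plus: float
    mean_beta_energy: float
    max_beta_energy: float
    mean_range_water: Optional[float] = None
    max_range_water: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError(f"half_life must be positive, got {self.half_life}")
        if not 0.0 <= self.branching_beta_plus <= 1.0:
            raise ValueError(
                f"branching_beta_plus must be in [0, 1], got {self.branching_beta_plus}"
            )
        if not self.mean_beta_energy < self.max_beta_energy:
            raise ValueError("mean_beta_energy must be below max_beta_energy")
        if self.mean_beta_energy <= 0:
            raise ValueError("mean_beta_energy must be positive")

    @property
    def decay_constant(self) -> float:
        """Decay constant lambda = ln(2) / half-life, in s^-1."""
        return math.log(2.0) / self.half_life

    def to_dict(self) -> dict:
        return asdict(self)


def decay_constant(nuclide: RadionuclideData) -> float:
    """Return the decay constant lambda = ln 2 / t_half in s^-1."""
    return nuclide.decay_constant


def activity_at(nuclide: RadionuclideData, a0_bq: float, t_s: float) -> float:
    """Activity A0 * exp(-lambda t) remaining at time ``t_s``.

    Accepts scalars or arrays for ``t_s``; negative times and negative
    initial activity are rejected.
    """
    if np.any(np.asarray(t_s) < 0):
        raise ValueError("time must be non-negative")
    if a0_bq < 0:
        raise ValueError("initial activity must be non-negative")
    return a0_bq * np.exp(-nuclide.decay_constant * np.asarray(t_s, dtype=float))


# The only nuclide shipped with validated values.  18F: t1/2 = 109.77 min,
# 96.73% beta+ branch, mean/max beta energy 249.8/633.5 keV, mean/max range
# in water 0.6/2.4 mm.
F18 = RadionuclideData(
    name="F-18",
    half_life=109.77 * MINUTE,
    branching_beta_plus=0.9673,
    mean_beta_energy=249.8,
    max_beta_energy=633.5,
    mean_range_water=0.6,
    max_range_water=2.4,
)


def builtin_f18() -> RadionuclideData:
    """Return the built-in fluorine-18 record."""
    return F18


_REGISTRY: dict[str, RadionuclideData] = {"f18": F18, "f-18": F18, "18f": F18}


def register_nuclide(nuclide: RadionuclideData, *aliases: str) -> None:
    """Add a user-supplied nuclide record to the lookup registry.

    Only 18F ships with validated values; records for other positron
    emitters (68Ga, 64Cu, 89Zr, ...) must be supplied by the user.
    """
    keys = [nuclide.name.lower()] + [a.lower() for a in aliases]
    for key in keys:
        _REGISTRY[key] = nuclide


def get_nuclide(name: str) -> RadionuclideData:
    """Look up a registered nuclide by name (case-insensitive)."""
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown nuclide {name!r}; registered: {sorted(set(_REGISTRY))}"
        ) from None


def nuclide_from_dict(d: dict) -> RadionuclideData:
    """Build a record from a mapping using the canonical field names."""
    fields = {
        "name",
        "half_life",
        "branching_beta_plus",
        "mean_beta_energy",
        "max_beta_energy",
        "mean_range_water",
        "max_range_water",
    }
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown nuclide fields: {sorted(unknown)}")
    return RadionuclideData(**d)


def nuclide_from_yaml(text: str) -> RadionuclideData:
    """Parse a YAML block into a :class:`RadionuclideData`."""
    return nuclide_from_dict(yaml.safe_load(text))
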