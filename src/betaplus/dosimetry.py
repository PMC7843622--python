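"""Decaying-source absorbed-dose calculation for in vitro irradiation.

The medium (a small volume of cell-culture medium spiked with a beta-plus
emitter) is treated as its own source and target: every positron deposits
its full kinetic energy locally (absorbed fraction 1), so the absorbed
dose is

    D = A_tilde * E_mean * kappa / m

where ``A_tilde`` is the cumulated activity (total number of decays over
the irradiation time T), ``E_mean`` the mean beta-plus energy in joules,
``kappa`` the beta-plus branching ratio, and ``m`` the medium mass in kg.
Annihilation photons are excluded: over a few-mL flask their interaction
probability is negligible and they escape (documented limitation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nuclides import KEV_TO_J, RadionuclideData

__all__ = [
    "IrradiationPlan",
    "DoseResult",
    "cumulated_activity",
    "absorbed_dose",
    "required_initial_activity",
    "dose_rate_profile",
    "activity_concentration",
]

#: water-equivalent medium density, kg/mL
WATER_DENSITY_KG_PER_ML = 1.0e-3


@dataclass(frozen=True)
class IrradiationPlan:
    """An in vitro irradiation: initial activity decaying in a medium.

    ``medium_mass`` defaults to ``medium_volume`` at unit density
    (water-equivalent culture medium).  If both are given they must agree
    within 1% unless ``allow_density_override`` is set.
    """

    nuclide: RadionuclideData
    a0_bq: float
    duration_s: float
    medium_volume_ml: Optional[float] = None
    medium_mass_kg: Optional[float] = None
    allow_density_override: bool = False

    def __post_init__(self) -> None:
        if self.a0_bq < 0:
            raise ValueError("initial activity must be non-negative")
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")
        if self.medium_volume_ml is None and self.medium_mass_kg is None:
            raise ValueError("give medium_volume_ml and/or medium_mass_kg")
        if self.medium_mass_kg is None:
            object.__setattr__(
                self, "medium_mass_kg", self.medium_volume_ml * WATER_DENSITY_KG_PER_ML
            )
        if not self.medium_mass_kg > 0:
            raise ValueError("medium mass must be positive")
        if self.medium_volume_ml is not None and not self.allow_density_override:
            implied = self.medium_volume_ml * WATER_DENSITY_KG_PER_ML
            if abs(self.medium_mass_kg - implied) > 0.01 * implied:
                raise ValueError(
                    "medium mass inconsistent with volume at unit density "
                    "(set allow_density_override=True for non-water media)"
                )


@dataclass(frozen=True)
class DoseResult:
    """Output of the absorbed-dose calculation."""

    cumulated_activity: float  # total decays (Bq*s)
    dose_gy: float
    initial_dose_rate_gy_s: float
    mean_dose_rate_gy_s: float

    def to_dict(self) -> dict:
        return {
            "cumulated_activity_decays": self.cumulated_activity,
            "dose_gy": self.dose_gy,
            "initial_dose_rate_gy_per_s": self.initial_dose_rate_gy_s,
            "mean_dose_rate_gy_per_s": self.mean_dose_rate_gy_s,
        }


def cumulated_activity(nuclide: RadionuclideData, a0_bq: float, t_s: float) -> float:
    """Cumulated activity A0 (1 - e^{-lambda T}) / lambda, in decays.

    The time integral of the exponentially decaying activity; tends to
    ``A0 / lambda`` as T -> infinity.
    """
    if a0_bq < 0:
        raise ValueError("initial activity must be non-negative")
    if not t_s > 0:
        raise ValueError("irradiation time must be positive")
    lam = nuclide.decay_constant
    return a0_bq * (-math.expm1(-lam * t_s)) / lam


def _dose_per_decay_gy(nuclide: RadionuclideData, mass_kg: float) -> float:
    """Absorbed dose per decay: E_mean[J] * kappa / m."""
    return nuclide.mean_beta_energy * KEV_TO_J * nuclide.branching_beta_plus / mass_kg


def absorbed_dose(plan: IrradiationPlan) -> DoseResult:
    """Evaluate the absorbed dose delivered by the plan.

    Dose scales linearly with A0; the mean dose rate is dose/duration by
    construction.
    """
    if plan.medium_mass_kg <= 0:
        raise ValueError("medium mass must be positive")
    a_tilde = cumulated_activity(plan.nuclide, plan.a0_bq, plan.duration_s)
    per_decay = _dose_per_decay_gy(plan.nuclide, plan.medium_mass_kg)
    dose = a_tilde * per_decay
    return DoseResult(
        cumulated_activity=a_tilde,
        dose_gy=dose,
        initial_dose_rate_gy_s=plan.a0_bq * per_decay,
        mean_dose_rate_gy_s=dose / plan.duration_s,
    )


def required_initial_activity(
    nuclide: RadionuclideData, target_dose_gy: float, t_s: float, mass_kg: float
) -> float:
    """Initial activity (Bq) delivering ``target_dose_gy`` over ``t_s``.

    Exact algebraic inverse of :func:`absorbed_dose`.
    """
    if not target_dose_gy > 0:
        raise ValueError("target dose must be positive")
    if not mass_kg > 0:
        raise ValueError("mass must be positive")
    lam = nuclide.decay_constant
    per_decay = _dose_per_decay_gy(nuclide, mass_kg)
    a_tilde = target_dose_gy / per_decay
    return a_tilde * lam / (-math.expm1(-lam * t_s))


def dose_rate_profile(plan: IrradiationPlan, times_s: Sequence[float]) -> np.ndarray:
    """Instantaneous dose rate Ddot(t) = A0 e^{-lambda t} E kappa / m, Gy/s.

    ``times_s`` must lie within [0, duration].
    """
    t = np.asarray(times_s, dtype=float)
    if np.any(t < 0) or np.any(t > plan.duration_s):
        raise ValueError("times must lie within [0, duration]")
    per_decay = _dose_per_decay_gy(plan.nuclide, plan.medium_mass_kg)
    return plan.a0_bq * np.exp(-plan.nuclide.decay_constant * t) * per_decay


def activity_concentration(plan: IrradiationPlan) -> float:
    """Initial activity concentration A0 / medium volume, in Bq/mL."""
    if plan.medium_volume_ml is None:
        raise ValueError("plan has no medium volume")
    return plan.a0_bq / plan.medium_volume_ml
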