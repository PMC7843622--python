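"""Clonogenic-assay reduction: survival fractions, LQ fits and RBE.

Survival fractions follow the standard clonogenic-assay definitions:
plating efficiency PE is the mean colonies/cells-seeded ratio of the
unirradiated controls, and SF(D) is the mean ratio at dose D divided by
PE.  The linear-quadratic model

    SF = exp(-(alpha * D + beta * D^2))

is fitted by weighted least squares in the log-survival domain (which
linearizes the model), with non-negativity constraints on alpha and beta
by default.  RBE at a stated survival level is the ratio of the
reference-arm dose to the test-arm dose producing that survival.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ColonyRecord",
    "SurvivalCurve",
    "LQFit",
    "RBEResult",
    "FitError",
    "survival_fractions",
    "fit_lq",
    "dose_at_sf",
    "rbe",
]


class FitError(ValueError):
    """Raised when a survival curve cannot support an LQ fit."""


@dataclass(frozen=True)
class ColonyRecord:
    """One replicate of a clonogenic assay plate."""

    arm: str
    dose_gy: float
    cells_seeded: int
    colonies: int
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.cells_seeded <= 0:
            raise ValueError("cells_seeded must be positive")
        if self.colonies < 0:
            raise ValueError("colonies must be non-negative")
        if self.colonies > self.cells_seeded:
            raise ValueError("colonies cannot exceed cells seeded")
        if self.dose_gy < 0:
            raise ValueError("dose must be non-negative")


@dataclass
class SurvivalCurve:
    """Survival fractions at each dose for one irradiation arm.

    ``below_detection`` marks doses where no colonies formed at all; the
    SF there is recorded as 0 and the point is excluded from log-domain
    fitting.
    """

    doses: np.ndarray
    sf: np.ndarray
    sf_err: np.ndarray
    arm: str = ""
    below_detection: np.ndarray = field(default=None)  # type: ignore[assignment]
    plating_efficiency: float = float("nan")

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.sf = np.asarray(self.sf, dtype=float)
        self.sf_err = np.asarray(self.sf_err, dtype=float)
        if self.below_detection is None:
            self.below_detection = np.zeros(self.doses.shape, dtype=bool)
        self.below_detection = np.asarray(self.below_detection, dtype=bool)
        if not (len(self.doses) == len(self.sf) == len(self.sf_err)):
            raise ValueError("doses, sf and sf_err must have equal length")


def survival_fractions(records: Sequence[ColonyRecord]) -> SurvivalCurve:
    """Reduce colony counts to a survival curve.

    Requires at least one 0 Gy control replicate.  The standard error of
    each SF combines the replicate scatter of the treated and control
    ratios in quadrature with a Poisson counting-error floor (colony
    counts are Poisson, so the SE across a handful of replicates can
    badly underestimate the counting error).
    """
    if not records:
        raise ValueError("no records")
    arms = {r.arm for r in records}
    if len(arms) > 1:
        raise ValueError(f"records span multiple arms: {sorted(arms)}")
    arm = records[0].arm

    by_dose: dict[float, list[ColonyRecord]] = {}
    for r in records:
        by_dose.setdefault(r.dose_gy, []).append(r)
    if 0.0 not in by_dose:
        raise ValueError("no 0 Gy control replicates in arm " + repr(arm))

    def _ratio_stats(recs: list[ColonyRecord]) -> tuple[float, float, int]:
        ratios = np.array([r.colonies / r.cells_seeded for r in recs])
        mean = float(ratios.mean())
        sem = float(ratios.std(ddof=1) / math.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
        total_colonies = sum(r.colonies for r in recs)
        return mean, sem, total_colonies

    pe, pe_sem, pe_colonies = _ratio_stats(by_dose[0.0])
    if pe <= 0:
        raise ValueError("controls formed no colonies; plating efficiency is zero")

    doses = sorted(by_dose)
    sf_list, err_list, below = [], [], []
    for d in doses:
        if d == 0.0:
            sf_list.append(1.0)
            err_list.append(0.0)
            below.append(False)
            continue
        mean, sem, total = _ratio_stats(by_dose[d])
        if total == 0:
            sf_list.append(0.0)
            err_list.append(float("nan"))
            below.append(True)
            continue
        sf = mean / pe
        # relative errors in quadrature; Poisson floor from pooled counts
        rel_rep = math.hypot(sem / mean, pe_sem / pe)
        rel_poisson = math.hypot(1.0 / math.sqrt(total), 1.0 / math.sqrt(pe_colonies))
        sf_list.append(sf)
        err_list.append(sf * max(rel_rep, rel_poisson))
        below.append(False)
    return SurvivalCurve(
        doses=np.array(doses),
        sf=np.array(sf_list),
        sf_err=np.array(err_list),
        arm=arm,
        below_detection=np.array(below),
        plating_efficiency=pe,
    )


@dataclass(frozen=True)
class LQFit:
    """Fitted linear-quadratic parameters.

    ``covariance`` is the 2x2 covariance matrix of (alpha, beta) from the
    weighted least-squares fit, treating the supplied SF standard errors
    as known (absolute) uncertainties.
    """

    alpha: float  # Gy^-1
    beta: float  # Gy^-2
    covariance: np.ndarray
    arm: str = ""

    @property
    def alpha_beta_ratio(self) -> float:
        """alpha/beta in Gy; +inf when beta is zero."""
        if self.beta == 0:
            return float("inf")
        return self.alpha / self.beta

    @property
    def alpha_beta_ratio_debiased(self) -> float:
        """Second-order (delta-method) bias-corrected alpha/beta.

        The plain ratio of two noisy estimates is biased upward (Jensen);
        the correction subtracts the leading-order term
        ``alpha var(beta)/beta^3 - cov(alpha, beta)/beta^2`` computed
        from the fit covariance.  Use this when averaging recovered
        ratios over many datasets.
        """
        if self.beta == 0:
            return float("inf")
        a, b = self.alpha, self.beta
        bias = -self.covariance[0, 1] / b**2 + a * self.covariance[1, 1] / b**3
        return a / b - bias

    def alpha_beta_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Delta-method confidence interval for alpha/beta."""
        if self.beta == 0:
            return (float("nan"), float("nan"))
        g = np.array([1.0 / self.beta, -self.alpha / self.beta**2])
        var = float(g @ self.covariance @ g)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(max(var, 0.0))
        r = self.alpha_beta_ratio
        return (r - half, r + half)

    def sf(self, dose_gy):
        """Predicted survival fraction at the given dose(s)."""
        d = np.asarray(dose_gy, dtype=float)
        return np.exp(-(self.alpha * d + self.beta * d * d))


def fit_lq(curve: SurvivalCurve, *, constrain: bool = True) -> LQFit:
    """Fit ln SF = -(alpha D + beta D^2) through the origin.

    Weighted least squares with weights 1/se^2 where se = sf_err/sf is
    the log-domain standard error; unweighted when errors are absent or
    zero (noiseless data).  alpha, beta >= 0 unless ``constrain=False``.
    """
    mask = (curve.doses > 0) & (curve.sf > 0) & ~curve.below_detection
    if np.any(curve.below_detection):
        warnings.warn(
            "below-detection survival points excluded from LQ fit", stacklevel=2
        )
    d = curve.doses[mask]
    if len(np.unique(d)) < 3:
        raise FitError("need at least 3 distinct positive doses with nonzero SF")
    y = -np.log(curve.sf[mask])
    se = curve.sf_err[mask] / curve.sf[mask]
    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se**2
        absolute_sigma = True
    else:
        w = np.ones_like(y)
        absolute_sigma = False
    X = np.column_stack([d, d * d])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    if constrain:
        res = optimize.lsq_linear(Xw, yw, bounds=(0.0, np.inf))
        coef = res.x
    else:
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    xtx = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise FitError("singular design matrix (degenerate dose grid)") from None
    if not absolute_sigma:
        dof = max(len(y) - 2, 1)
        s2 = float(((yw - Xw @ coef) ** 2).sum()) / dof
        cov = cov * s2
    return LQFit(alpha=float(coef[0]), beta=float(coef[1]), covariance=cov, arm=curve.arm)


def dose_at_sf(fit: LQFit, sf_level: float) -> float:
    """Dose (Gy) at which the fitted curve crosses ``sf_level``.

    Positive root of beta D^2 + alpha D + ln(sf_level) = 0; reduces to
    -ln(sf)/alpha for a pure exponential.
    """
    if not 0.0 < sf_level < 1.0:
        raise ValueError("sf_level must be in (0, 1)")
    loss = -math.log(sf_level)
    if fit.beta == 0.0:
        if fit.alpha == 0.0:
            raise ValueError("degenerate fit: alpha = beta = 0")
        return loss / fit.alpha
    return (-fit.alpha + math.sqrt(fit.alpha**2 + 4.0 * fit.beta * loss)) / (
        2.0 * fit.beta
    )


def _dose_at_sf_interp(curve: SurvivalCurve, sf_level: float) -> tuple[float, bool]:
    """Dose at sf_level by piecewise log-linear interpolation of the points.

    Returns (dose, extrapolated).
    """
    mask = (curve.sf > 0) & ~curve.below_detection
    d = curve.doses[mask]
    lnsf = np.log(curve.sf[mask])
    order = np.argsort(d)
    d, lnsf = d[order], lnsf[order]
    target = math.log(sf_level)
    extrapolated = target < lnsf.min() or target > lnsf.max()
    # interp over monotone-decreasing lnsf: flip to ascending for np.interp
    dose = float(np.interp(target, lnsf[::-1], d[::-1]))
    return dose, extrapolated


@dataclass(frozen=True)
class RBEResult:
    """Relative biological effectiveness at a stated survival level."""

    sf_level: float
    dose_reference_gy: float
    dose_test_gy: float
    rbe: float
    extrapolated: bool = False

    def to_dict(self) -> dict:
        return {
            "sf_level": self.sf_level,
            "dose_reference_gy": self.dose_reference_gy,
            "dose_test_gy": self.dose_test_gy,
            "rbe": self.rbe,
            "extrapolated": self.extrapolated,
        }


def rbe_confidence_interval(
    reference_fit: LQFit,
    test_fit: LQFit,
    sf_level: float = 0.5,
    level: float = 0.95,
) -> tuple[float, float]:
    """Delta-method CI for RBE from the two fit covariances.

    Propagates (alpha, beta) uncertainty of both independent arms
    through D(sf_level) ratios via numeric gradients.
    """
    p = np.array([reference_fit.alpha, reference_fit.beta, test_fit.alpha, test_fit.beta])

    def f(q: np.ndarray) -> float:
        ref = LQFit(q[0], q[1], reference_fit.covariance)
        tst = LQFit(q[2], q[3], test_fit.covariance)
        return dose_at_sf(ref, sf_level) / dose_at_sf(tst, sf_level)

    g = np.zeros(4)
    for i in range(4):
        h = max(1e-7, 1e-6 * abs(p[i]))
        q = p.copy()
        q[i] += h
        g[i] = (f(q) - f(p)) / h
    cov = np.zeros((4, 4))
    cov[:2, :2] = reference_fit.covariance
    cov[2:, 2:] = test_fit.covariance
    se = math.sqrt(max(float(g @ cov @ g), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    center = f(p)
    return (center - z * se, center + z * se)


def rbe(
    reference_fit: LQFit,
    test: Union[LQFit, SurvivalCurve],
    sf_level: float = 0.5,
    *,
    method: str = "fit",
) -> RBEResult:
    """RBE = D_reference(sf_level) / D_test(sf_level).

    The test arm may be an :class:`LQFit` (default route) or a
    :class:`SurvivalCurve` with ``method="interp"`` for piecewise
    log-linear interpolation between measured points (useful when the
    test curve is nearly exponential and an LQ fit is poor).  A result
    outside the measured range carries ``extrapolated=True``.
    """
    d_ref = dose_at_sf(reference_fit, sf_level)
    extrapolated = False
    if method == "fit":
        if isinstance(test, SurvivalCurve):
            test = fit_lq(test)
        d_test = dose_at_sf(test, sf_level)
    elif method == "interp":
        if not isinstance(test, SurvivalCurve):
            raise TypeError("method='interp' requires a SurvivalCurve test arm")
        d_test, extrapolated = _dose_at_sf_interp(test, sf_level)
        if extrapolated:
            warnings.warn("RBE at sf_level requires extrapolation", stacklevel=2)
    else:
        raise ValueError(f"unknown method {method!r}")
    if d_test <= 0:
        raise ValueError("test-arm dose at sf_level is non-positive")
    return RBEResult(
        sf_level=sf_level,
        dose_reference_gy=d_ref,
        dose_test_gy=d_test,
        rbe=d_ref / d_test,
        extrapolated=extrapolated,
    )
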