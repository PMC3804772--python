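"""K_D estimation from fluorescence-quench titrations.

A ligand that quenches the intrinsic tryptophan fluorescence of its
receptor reports site occupancy: the fractional occupancy is
a = ΔF/ΔF_max, and for single-site equilibrium binding

    1/a = K_D/[free ligand] + 1,

so a double-reciprocal plot of 1/a against 1/[free ligand] is a line with
slope K_D and intercept 1.  ΔF_max is itself obtained from the
double-reciprocal plot of 1/ΔF against 1/[ligand] (ΔF_max = 1/intercept),
using total ligand concentration as the first estimate of free ligand.
Observed fluorescence can first be corrected for the inner-filter effect:

    F_corrected = F_observed · 10^((A_ex + A_em)/2).

Reciprocal transforms amplify noise at low ligand; see the methods note
for the resulting caveats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .thermo import DomainError

__all__ = [
    "QuenchTitration",
    "OccupancyCurve",
    "KdEstimate",
    "correct_inner_filter",
    "estimate_dfmax",
    "estimate_kd",
]

logger = logging.getLogger("noscabind.quench")

#: Occupancies above 1 by more than this factor are dropped as inconsistent.
OCCUPANCY_TOL = 1e-9


class UnsaturableCurveError(ValueError):
    """Double-reciprocal intercept ≤ 0: the titration never saturates."""


class ConvergenceError(RuntimeError):
    """Iterative free-ligand refinement failed to converge; carries the trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class QuenchTitration:
    """One titration series of a fluorescent receptor with a quenching ligand.

    Parameters
    ----------
    ligand_total : array-like
        Total ligand concentrations, µM, including the zero point if
        ``f0`` is not given explicitly.
    f_observed : array-like
        Observed fluorescence, arbitrary units, one per concentration.
    receptor_total : float
        Receptor concentration in µM (tubulin assays typically use 2 µM).
    a_ex, a_em : array-like, optional
        Absorbances at the excitation/emission wavelengths per point, for
        inner-filter correction.
    f0 : float, optional
        Fluorescence at zero ligand; inferred from the ligand_total == 0
        point when omitted.
    """

    ligand_total: tuple[float, ...]
    f_observed: tuple[float, ...]
    receptor_total: float
    a_ex: tuple[float, ...] | None = None
    a_em: tuple[float, ...] | None = None
    f0: float | None = None

    def __post_init__(self) -> None:
        lig = np.asarray(self.ligand_total, dtype=float)
        f = np.asarray(self.f_observed, dtype=float)
        object.__setattr__(self, "ligand_total", tuple(lig))
        object.__setattr__(self, "f_observed", tuple(f))
        if lig.size != f.size:
            raise DomainError("ligand_total and f_observed lengths differ")
        if (lig < 0).any():
            raise DomainError("ligand concentrations must be >= 0")
        if (f <= 0).any():
            raise DomainError("observed fluorescence must be positive")
        if not (self.receptor_total > 0):
            raise DomainError(f"receptor_total must be positive, got {self.receptor_total}")
        for name in ("a_ex", "a_em"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                object.__setattr__(self, name, tuple(a))
                if a.size != lig.size:
                    raise DomainError(f"{name} length differs from ligand_total")
                if (a < 0).any():
                    raise DomainError(f"{name} contains negative absorbance")
        n_zero = int((lig == 0).sum())
        if self.f0 is None:
            if n_zero != 1:
                raise DomainError(
                    "f0 not given and the series does not contain exactly one "
                    f"zero-ligand point (found {n_zero})")
        elif not (self.f0 > 0):
            raise DomainError(f"f0 must be positive, got {self.f0}")

    @property
    def baseline(self) -> float:
        """Inner-filter-corrected fluorescence at zero ligand."""
        if self.f0 is not None:
            return float(self.f0)
        idx = list(self.ligand_total).index(0.0)
        return float(self.corrected_fluorescence()[idx])

    def corrected_fluorescence(self) -> np.ndarray:
        """Fluorescence after inner-filter correction (identity if no absorbances)."""
        f = np.asarray(self.f_observed, dtype=float)
        if self.a_ex is None and self.a_em is None:
            return f
        ax = np.asarray(self.a_ex, dtype=float) if self.a_ex is not None else np.zeros_like(f)
        am = np.asarray(self.a_em, dtype=float) if self.a_em is not None else np.zeros_like(f)
        return correct_inner_filter(f, ax, am)


@dataclass(frozen=True)
class OccupancyCurve:
    """Fractional-occupancy points derived from a titration."""

    ligand_free: tuple[float, ...]
    occupancy_a: tuple[float, ...]
    delta_f: tuple[float, ...]
    delta_f_max: float


@dataclass(frozen=True)
class KdEstimate:
    """A double-reciprocal K_D fit and its diagnostics.

    ``slope`` is K_D in µM; ``intercept`` should be ≈1 when the single-site
    model holds (it is exactly 1 when the constrained fit is used).
    """

    kd: float
    slope: float
    intercept: float
    r2_fit: float
    mode: str
    constrained_intercept: bool
    delta_f_max: float
    curve: OccupancyCurve
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd, "slope_uM": self.slope,
            "intercept": self.intercept, "r2_fit": self.r2_fit,
            "mode": self.mode, "constrained_intercept": self.constrained_intercept,
            "delta_f_max": self.delta_f_max, "n_iterations": self.n_iterations,
        }


def correct_inner_filter(f_observed, a_ex, a_em):
    """Inner-filter correction: F_obs · 10^((A_ex + A_em)/2).

    Scalar or array inputs; absorbances must be non-negative, so the
    corrected value is never below the observed one.
    """
    f = np.asarray(f_observed, dtype=float)
    ax = np.asarray(a_ex, dtype=float)
    am = np.asarray(a_em, dtype=float)
    if (ax < 0).any() or (am < 0).any():
        raise DomainError("absorbances must be >= 0")
    out = f * 10.0 ** ((ax + am) / 2.0)
    return float(out) if out.ndim == 0 else out


def _usable_points(titration: QuenchTitration) -> tuple[np.ndarray, np.ndarray]:
    """(ligand_total, ΔF) at nonzero ligand with positive quench.

    Points with ΔF ≤ 0 — noise at low ligand — are dropped with a warning,
    as is the zero-ligand baseline point (its reciprocal is undefined).
    """
    lig = np.asarray(titration.ligand_total, dtype=float)
    f = titration.corrected_fluorescence()
    delta_f = titration.baseline - f
    nonzero = lig > 0
    pos = delta_f > 0
    dropped = nonzero & ~pos
    if dropped.any():
        logger.warning("dropping %d point(s) with non-positive ΔF at ligand %s µM",
                       int(dropped.sum()), lig[dropped].tolist())
    keep = nonzero & pos
    return lig[keep], delta_f[keep]


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unweighted least-squares line fit; returns (slope, intercept, r²)."""
    X = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def estimate_dfmax(titration: QuenchTitration) -> float:
    """Maximum fluorescence change ΔF_max from the 1/ΔF vs 1/[ligand] line.

    Ordinary least squares of 1/ΔF on 1/[total ligand]; the fitted
    intercept is 1/ΔF_max.  For the ideal (no-depletion) single-site model
    this transform is exactly linear, so the estimate is exact on
    noiseless data.

    Raises
    ------
    UnsaturableCurveError
        Fitted intercept ≤ 0 (the quench does not saturate).
    ValueError
        Fewer than 3 usable points.
    """
    lig, delta_f = _usable_points(titration)
    if lig.size < 3:
        raise ValueError(f"need >= 3 nonzero-ligand points with positive ΔF, got {lig.size}")
    _, intercept, _ = _ols_line(1.0 / lig, 1.0 / delta_f)
    if intercept <= 0:
        raise UnsaturableCurveError(
            f"double-reciprocal intercept {intercept:.3g} <= 0; "
            "titration does not approach saturation")
    return 1.0 / intercept


def _fit_reciprocal(inv_free: np.ndarray, inv_a: np.ndarray,
                    constrained: bool) -> tuple[float, float, float]:
    """Fit 1/a = K_D·(1/[free]) + intercept; returns (slope, intercept, r²)."""
    if constrained:
        # intercept pinned at the model value 1; only the slope is free
        slope = float(np.sum((inv_a - 1.0) * inv_free) / np.sum(inv_free ** 2))
        yhat = slope * inv_free + 1.0
        ss_res = float(np.sum((inv_a - yhat) ** 2))
        ss_tot = float(np.sum((inv_a - np.mean(inv_a)) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        return slope, 1.0, r2
    return _ols_line(inv_free, inv_a)


def estimate_kd(titration: QuenchTitration, mode: str = "total-as-free",
                constrained_intercept: bool = False,
                delta_f_max: float | None = None,
                max_iterations: int = 100, rel_tol: float = 1e-6) -> KdEstimate:
    """Dissociation constant from the double-reciprocal occupancy fit.

    Occupancy a = ΔF/ΔF_max is regressed reciprocally: 1/a against
    1/[free ligand], whose slope is K_D (µM).

    Parameters
    ----------
    mode : {"total-as-free", "iterative-depletion"}
        ``total-as-free`` takes free ligand = total ligand (adequate when
        receptor ≪ K_D).  ``iterative-depletion`` alternates
        free = total − a·receptor with refitting until successive K_D
        estimates change by < ``rel_tol`` relative.
    constrained_intercept : bool
        Pin the reciprocal-fit intercept at its model value 1 and fit only
        the slope.
    delta_f_max : float, optional
        Known saturation amplitude; estimated via :func:`estimate_dfmax`
        when omitted.

    Raises
    ------
    ConvergenceError
        The depletion iteration failed to converge (trace attached).
    """
    if mode not in ("total-as-free", "iterative-depletion"):
        raise ValueError(f"unknown mode {mode!r}")
    if delta_f_max is None:
        delta_f_max = estimate_dfmax(titration)
    lig, delta_f = _usable_points(titration)
    if lig.size < 3:
        raise ValueError(f"need >= 3 usable points, got {lig.size}")

    a = delta_f / delta_f_max
    over = a > 1.0 + OCCUPANCY_TOL
    if over.any():
        logger.warning("dropping %d point(s) with occupancy > 1 (max %.4f); "
                       "data inconsistent with ΔF_max", int(over.sum()), float(a.max()))
        lig, delta_f, a = lig[~over], delta_f[~over], a[~over]
        if lig.size < 3:
            raise ValueError("fewer than 3 points remain after dropping occupancy > 1")
    a = np.minimum(a, 1.0)  # clamp the within-tolerance overshoot

    free = lig.copy()
    slope, intercept, r2 = _fit_reciprocal(1.0 / free, 1.0 / a, constrained_intercept)
    n_iter = 0
    if mode == "iterative-depletion":
        trace = [slope]
        for n_iter in range(1, max_iterations + 1):
            free = np.maximum(lig - a * titration.receptor_total, 1e-12)
            new_slope, intercept, r2 = _fit_reciprocal(
                1.0 / free, 1.0 / a, constrained_intercept)
            trace.append(new_slope)
            if abs(new_slope - slope) <= rel_tol * abs(slope):
                slope = new_slope
                break
            slope = new_slope
        else:
            raise ConvergenceError(
                f"K_D iteration did not converge in {max_iterations} steps", trace)

    if slope <= 0:
        raise UnsaturableCurveError(
            f"fitted K_D slope {slope:.3g} <= 0; data inconsistent with binding model")
    curve = OccupancyCurve(
        ligand_free=tuple(free), occupancy_a=tuple(a),
        delta_f=tuple(delta_f), delta_f_max=float(delta_f_max))
    return KdEstimate(
        kd=slope, slope=slope, intercept=intercept, r2_fit=r2, mode=mode,
        constrained_intercept=constrained_intercept,
        delta_f_max=float(delta_f_max), curve=curve, n_iterations=n_iter)
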