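"""Core domain types and the ΔG ↔ K_D thermodynamic conversions.

Binding free energy and the equilibrium dissociation constant are related by

    ΔG_bind = RT ln K_D        (K_D expressed in mol/L)

with R = 0.00199 kcal·mol⁻¹·K⁻¹ and T = 298 K by default.  K_D values are
carried in µM everywhere in this package, matching how tubulin-binding
affinities are tabulated in practice; the 1e-6 µM→M factor is applied only
inside the logarithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ThermoConstants",
    "EnergyComponents",
    "LIECoefficients",
    "AffinityRecord",
    "DEFAULT_CONSTANTS",
    "MICROMOLAR_TO_MOLAR",
    "dg_from_kd",
    "kd_from_dg",
    "validate_affinity_table",
]

#: Fixed µM → mol/L conversion used inside the logarithm.
MICROMOLAR_TO_MOLAR = 1e-6


class DomainError(ValueError):
    """Raised when an input violates a physical-domain precondition."""


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and temperature for the ΔG ↔ K_D relationship.

    Parameters
    ----------
    gas_constant_R : float
        In kcal·mol⁻¹·K⁻¹ (default 0.00199).
    temperature_T : float
        In kelvin (default 298).
    """

    gas_constant_R: float = 0.00199
    temperature_T: float = 298.0

    def __post_init__(self) -> None:
        if not (self.gas_constant_R > 0):
            raise DomainError(f"gas constant must be positive, got {self.gas_constant_R}")
        if not (self.temperature_T > 0):
            raise DomainError(f"temperature must be positive, got {self.temperature_T}")

    @property
    def rt(self) -> float:
        """R·T in kcal/mol."""
        return self.gas_constant_R * self.temperature_T


DEFAULT_CONSTANTS = ThermoConstants()


@dataclass(frozen=True)
class EnergyComponents:
    """Per-compound ensemble-average bound-minus-free interaction energies.

    The three terms are the van der Waals, electrostatic and cavity
    (surface-area) energies of the surface generalized Born continuum
    solvent model, each already differenced between the receptor-bound and
    free states of the ligand.  All in kcal/mol.
    """

    compound_id: str
    u_vdw: float
    u_elec: float
    u_cav: float

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise DomainError("compound_id must be nonempty")
        for name in ("u_vdw", "u_elec", "u_cav"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"{self.compound_id}: {name} must be finite, got {v}")

    def as_vector(self) -> tuple[float, float, float]:
        return (self.u_vdw, self.u_elec, self.u_cav)


@dataclass(frozen=True)
class LIECoefficients:
    """Coefficients (α, β, γ, intercept) of the empirical free-energy equation.

    ΔG_bind = α·⟨U_vdw⟩ + β·⟨U_elec⟩ + γ·⟨U_cav⟩ + intercept

    β and γ are stored signed — the fitted tubulin model has explicit
    negative values folded in (0.072, −0.006, −0.951).  α, β, γ are
    dimensionless; the intercept is in kcal/mol and defaults to 0 because
    the canonical fitted equation has no constant term.
    """

    alpha: float
    beta: float
    gamma: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "intercept"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v}")

    def as_array(self) -> tuple[float, ...]:
        return (self.alpha, self.beta, self.gamma, self.intercept)


#: The published tubulin-noscapinoid coefficients, rounded as reported.
PUBLISHED_COEFFICIENTS = LIECoefficients(alpha=0.072, beta=-0.006, gamma=-0.951)


@dataclass(frozen=True)
class AffinityRecord:
    """One compound's docking score, energies, affinity and free energies.

    All optional fields may be ``None`` (tables legitimately contain
    compounds whose K_D could not be measured).
    """

    compound_id: str
    glide_xp_score: float | None = None
    energy: EnergyComponents | None = None
    kd_mean: float | None = None
    kd_sd: float | None = None
    dg_experimental: float | None = None
    dg_predicted: float | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise DomainError("compound_id must be nonempty")
        if self.kd_mean is not None and not (self.kd_mean > 0):
            raise DomainError(f"{self.compound_id}: kd_mean must be positive, got {self.kd_mean}")
        if self.kd_sd is not None and self.kd_sd < 0:
            raise DomainError(f"{self.compound_id}: kd_sd must be >= 0, got {self.kd_sd}")


def dg_from_kd(kd: float, constants: ThermoConstants = DEFAULT_CONSTANTS,
               *, compound_id: str | None = None) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant in µM.

    Computes RT·ln(K_D in mol/L); negative for any K_D below 1 M and
    strictly increasing in K_D (weaker binders have less negative ΔG).

    Raises
    ------
    DomainError
        If ``kd`` is not strictly positive; the message names the compound
        when ``compound_id`` is given.
    """
    if not (kd > 0) or not math.isfinite(kd):
        who = f" for compound {compound_id!r}" if compound_id else ""
        raise DomainError(f"K_D must be a positive finite value{who}, got {kd}")
    return constants.rt * math.log(kd * MICROMOLAR_TO_MOLAR)


def kd_from_dg(dg: float, constants: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Dissociation constant in µM from a binding free energy in kcal/mol.

    Exact algebraic inverse of :func:`dg_from_kd`.
    """
    if not math.isfinite(dg):
        raise DomainError(f"ΔG must be finite, got {dg}")
    return math.exp(dg / constants.rt) / MICROMOLAR_TO_MOLAR


def validate_affinity_table(records: Sequence[AffinityRecord],
                            constants: ThermoConstants = DEFAULT_CONSTANTS,
                            tol: float = 0.0015) -> list[str]:
    """Cross-check stored experimental ΔG against RT·ln K_D per record.

    Returns the compound ids whose printed experimental ΔG disagrees with
    the value recomputed from the printed K_D by more than ``tol``
    (default ±0.0015 kcal/mol, covering last-digit rounding of values
    printed to 3 decimals).  Records missing either quantity are skipped.
    Also enforces compound-id uniqueness.
    """
    seen: set[str] = set()
    flagged: list[str] = []
    for rec in records:
        if rec.compound_id in seen:
            raise DomainError(f"duplicate compound_id {rec.compound_id!r} in table")
        seen.add(rec.compound_id)
        if rec.kd_mean is None or rec.dg_experimental is None:
            continue
        recomputed = dg_from_kd(rec.kd_mean, constants, compound_id=rec.compound_id)
        if abs(recomputed - rec.dg_experimental) > tol:
            flagged.append(rec.compound_id)
    return flagged
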