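"""Forward simulators for quench titrations and LIE training tables.

These generators produce inputs with the statistical structure the
analysis assumes — a single-site equilibrium binding isotherm for the
fluorescence assay and a linear energy model for the free-energy fit —
so every stage of the pipeline can be exercised against known ground
truth without instrument or docking output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .quench import QuenchTitration
from .lie import LIETrainingTable
from .thermo import EnergyComponents, LIECoefficients

__all__ = [
    "QuenchSimConfig",
    "LIESimConfig",
    "DEFAULT_LIGAND_GRID",
    "free_ligand_depletion",
    "simulate_quench_titration",
    "simulate_lie_table",
]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


#: Assay-like titration grid: 0–200 µM ligand against 2 µM receptor.
DEFAULT_LIGAND_GRID = (0.0, 10.0, 25.0, 50.0, 100.0, 150.0, 200.0)


@dataclass(frozen=True)
class QuenchSimConfig:
    """Ground truth and noise model for a simulated quench titration.

    ``noise_sd`` is the Gaussian standard deviation on fluorescence, in
    absolute arbitrary units, or as a fraction of ``f0`` when
    ``noise_relative`` is set.  The default amplitudes (f0 = 500,
    ΔF_max = 400 a.u., an 80% saturation quench) are calibrated so that
    replicate K_D estimates under 1%-of-f0 noise scatter like the
    experiment-to-experiment SDs the assay reports.  ``binding_model`` chooses between the
    ideal isotherm (free ligand = total) and the depletion model, which
    solves the single-site mass balance exactly.  With ``extinction_ex``
    / ``extinction_em`` nonzero, Beer-Lambert absorbance columns
    proportional to total ligand are emitted.
    """

    kd_true: float
    delta_f_max_true: float = 400.0
    f0: float = 500.0
    receptor_total: float = 2.0
    ligand_grid: tuple[float, ...] = DEFAULT_LIGAND_GRID
    noise_sd: float = 0.0
    noise_relative: bool = False
    binding_model: str = "ideal"
    extinction_ex: float = 0.0
    extinction_em: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.kd_true > 0):
            raise ConfigError(f"kd_true must be positive, got {self.kd_true}")
        if not (0 < self.delta_f_max_true <= self.f0):
            raise ConfigError("delta_f_max_true must lie in (0, f0]")
        if any(l < 0 for l in self.ligand_grid):
            raise ConfigError("ligand_grid entries must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.binding_model not in ("ideal", "depletion"):
            raise ConfigError(f"unknown binding_model {self.binding_model!r}")
        if not (self.receptor_total > 0):
            raise ConfigError("receptor_total must be positive")

    @property
    def noise_sd_absolute(self) -> float:
        return self.noise_sd * self.f0 if self.noise_relative else self.noise_sd


@dataclass(frozen=True)
class LIESimConfig:
    """Ground truth for a simulated LIE training table.

    Covariate ranges default to the spans of tabulated tubulin-noscapinoid
    energy components: u_vdw ∈ [−66, −46], u_elec ∈ [7, 130],
    u_cav ∈ [0.4, 2.1] kcal/mol.
    """

    coeffs_true: LIECoefficients
    n_compounds: int = 20
    u_vdw_range: tuple[float, float] = (-66.0, -46.0)
    u_elec_range: tuple[float, float] = (7.0, 130.0)
    u_cav_range: tuple[float, float] = (0.4, 2.1)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 4:
            raise ConfigError(f"n_compounds must be >= 4, got {self.n_compounds}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name in ("u_vdw_range", "u_elec_range", "u_cav_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be an increasing interval")


def free_ligand_depletion(ligand_total: np.ndarray, kd: float,
                          receptor_total: float) -> np.ndarray:
    """Exact free-ligand concentration under single-site mass balance.

    Solves L_total = L_free + R_total·L_free/(K_D + L_free), i.e. the
    quadratic L_free² + (K_D + R − L_total)·L_free − K_D·L_total = 0,
    taking the positive root in a numerically stable form.
    """
    lt = np.asarray(ligand_total, dtype=float)
    b = kd + receptor_total - lt
    # positive root of x^2 + b x - kd*lt = 0 via the stable quadratic formula
    disc = np.sqrt(b * b + 4.0 * kd * lt)
    return 0.5 * (-b + disc)


def simulate_quench_titration(config: QuenchSimConfig) -> QuenchTitration:
    """Generate one titration from the single-site quench model.

    Occupancy is a = L/(K_D + L) with L = total ligand (ideal model) or
    the exact mass-balance free concentration (depletion model);
    fluorescence is F = f0 − a·ΔF_max plus Gaussian noise.  Reproducible
    given the config's seed.
    """
    rng = np.random.default_rng(config.seed)
    lig = np.asarray(config.ligand_grid, dtype=float)
    if config.binding_model == "depletion":
        free = free_ligand_depletion(lig, config.kd_true, config.receptor_total)
    else:
        free = lig
    a = free / (config.kd_true + free)
    f_true = config.f0 - a * config.delta_f_max_true
    noise = rng.normal(0.0, config.noise_sd_absolute, size=lig.size) \
        if config.noise_sd_absolute > 0 else np.zeros(lig.size)
    f_obs = f_true + noise
    if (f_obs <= 0).any():
        raise ConfigError("noise drove simulated fluorescence non-positive; "
                          "reduce noise_sd or raise f0")
    a_ex = a_em = None
    if config.extinction_ex > 0 or config.extinction_em > 0:
        a_ex = tuple(config.extinction_ex * lig)
        a_em = tuple(config.extinction_em * lig)
        f_obs = f_obs / 10.0 ** ((np.asarray(a_ex) + np.asarray(a_em)) / 2.0)
    return QuenchTitration(
        ligand_total=tuple(lig), f_observed=tuple(f_obs),
        receptor_total=config.receptor_total, a_ex=a_ex, a_em=a_em,
        f0=None if 0.0 in config.ligand_grid else config.f0)


def simulate_lie_table(config: LIESimConfig) -> LIETrainingTable:
    """Generate a training table from known coefficients plus Gaussian noise.

    Covariates are drawn uniformly from the configured ranges; the
    response is the exact linear form plus N(0, noise_sd²).
    """
    rng = np.random.default_rng(config.seed)
    u_vdw = rng.uniform(*config.u_vdw_range, size=config.n_compounds)
    u_elec = rng.uniform(*config.u_elec_range, size=config.n_compounds)
    u_cav = rng.uniform(*config.u_cav_range, size=config.n_compounds)
    c = config.coeffs_true
    dg = (c.alpha * u_vdw + c.beta * u_elec + c.gamma * u_cav + c.intercept)
    if config.noise_sd > 0:
        dg = dg + rng.normal(0.0, config.noise_sd, size=config.n_compounds)
    rows = tuple(
        (EnergyComponents(f"sim{i:03d}", float(u_vdw[i]), float(u_elec[i]),
                          float(u_cav[i])), float(dg[i]))
        for i in range(config.n_compounds))
    return LIETrainingTable(rows=rows, provenance=f"simulated(seed={config.seed})")
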