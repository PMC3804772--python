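"""Fitting and evaluating the linear interaction energy (LIE) model.

The empirical model expresses binding free energy as a weighted sum of
ensemble-average bound-minus-free energy terms,

    ΔG_bind = α·⟨U_vdw⟩ + β·⟨U_elec⟩ + γ·⟨U_cav⟩ (+ intercept),

and is calibrated by ordinary least squares against experimentally
measured free energies of a training set.  The default fit carries no
intercept, matching the canonical form of the fitted equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .thermo import DomainError, EnergyComponents, LIECoefficients

__all__ = [
    "LIETrainingTable",
    "FitReport",
    "AnovaResult",
    "fit_lie",
    "predict_dg",
    "loo_predictions",
    "pearson_r2",
    "anova_oneway_from_summary",
]

#: Relative singular-value cutoff below which the design is declared singular.
RANK_TOL = 1e-10

_COLUMN_NAMES = ("u_vdw", "u_elec", "u_cav", "intercept")


class SingularDesignError(ValueError):
    """Covariate matrix is rank-deficient; message lists collinear columns."""


class TableSizeError(ValueError):
    """Too few training rows for the number of coefficients requested."""


@dataclass(frozen=True)
class LIETrainingTable:
    """Training rows: energy components paired with experimental ΔG (kcal/mol)."""

    rows: tuple[tuple[EnergyComponents, float], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [e.compound_id for e, _ in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DomainError(f"duplicate compound ids in training table: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def design_matrix(self) -> np.ndarray:
        return np.array([e.as_vector() for e, _ in self.rows], dtype=float)

    @property
    def dg_experimental(self) -> np.ndarray:
        return np.array([dg for _, dg in self.rows], dtype=float)

    @property
    def compound_ids(self) -> list[str]:
        return [e.compound_id for e, _ in self.rows]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "LIETrainingTable":
        """Build from a frame with columns compound_id, u_vdw, u_elec, u_cav,
        and an experimental-ΔG column named either dg_experimental or
        experimental_dg."""
        dg_col = "dg_experimental" if "dg_experimental" in df.columns else "experimental_dg"
        rows = tuple(
            (EnergyComponents(str(r["compound_id"]), float(r["u_vdw"]),
                              float(r["u_elec"]), float(r["u_cav"])),
             float(r[dg_col]))
            for _, r in df.iterrows()
        )
        return cls(rows=rows, provenance=provenance)


@dataclass(frozen=True)
class FitReport:
    """Result of a LIE least-squares fit."""

    coefficients: LIECoefficients
    r2_train: float
    rmse: float
    residuals: tuple[float, ...]
    n: int
    compound_ids: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        c = self.coefficients
        return {
            "alpha": c.alpha, "beta": c.beta, "gamma": c.gamma,
            "intercept": c.intercept,
            "r2_train": self.r2_train, "rmse": self.rmse, "n": self.n,
            "residuals": dict(zip(self.compound_ids, self.residuals)),
        }

    def summary(self) -> str:
        c = self.coefficients
        lines = [
            "LIE fit report",
            f"  n = {self.n}",
            f"  alpha     = {c.alpha: .6f}",
            f"  beta      = {c.beta: .6f}",
            f"  gamma     = {c.gamma: .6f}",
            f"  intercept = {c.intercept: .6f}",
            f"  R2(train) = {self.r2_train:.3f}",
            f"  RMSE      = {self.rmse:.4f} kcal/mol",
        ]
        return "\n".join(lines)


def _design(table: LIETrainingTable, include_intercept: bool) -> np.ndarray:
    X = table.design_matrix
    if include_intercept:
        X = np.column_stack([X, np.ones(len(X))])
    return X


def _check_rank(X: np.ndarray, include_intercept: bool) -> None:
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] <= RANK_TOL * sv[0]:
        # identify which columns participate in the near-null space
        _, _, vt = np.linalg.svd(X)
        null = np.abs(vt[-1]) > 1e-6
        names = [_COLUMN_NAMES[i] if not include_intercept or i < 3 else "intercept"
                 for i in range(X.shape[1])]
        collinear = [n for n, flag in zip(names, null) if flag]
        raise SingularDesignError(
            f"covariate matrix is rank-deficient; collinear columns: {collinear}")


def fit_lie(table: LIETrainingTable, include_intercept: bool = False) -> FitReport:
    """Ordinary-least-squares fit of the LIE coefficients.

    Minimizes Σ(ΔG_exp − ΔG_pred)² over (α, β, γ) — and the intercept when
    ``include_intercept`` is on; otherwise the intercept is fixed at 0.
    ``r2_train`` is the squared Pearson correlation between fitted and
    experimental ΔG, the statistic conventionally reported for such models.

    Raises
    ------
    TableSizeError
        Fewer than 4 rows (5 with intercept).
    SingularDesignError
        Rank-deficient covariates, with the collinear columns named.
    """
    p = 4 if include_intercept else 3
    if len(table) < p + 1:
        raise TableSizeError(
            f"need at least {p + 1} rows to fit {p} coefficients, got {len(table)}")
    X = _design(table, include_intercept)
    _check_rank(X, include_intercept)
    y = table.dg_experimental
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coeffs = LIECoefficients(
        alpha=float(beta[0]), beta=float(beta[1]), gamma=float(beta[2]),
        intercept=float(beta[3]) if include_intercept else 0.0)
    yhat = X @ beta
    resid = y - yhat
    return FitReport(
        coefficients=coeffs,
        r2_train=pearson_r2(yhat, y),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        residuals=tuple(float(r) for r in resid),
        n=len(table),
        compound_ids=tuple(table.compound_ids),
    )


def predict_dg(coeffs: LIECoefficients, energy: EnergyComponents) -> float:
    """Predicted ΔG_bind (kcal/mol) for one compound's energy components."""
    return (coeffs.alpha * energy.u_vdw + coeffs.beta * energy.u_elec
            + coeffs.gamma * energy.u_cav + coeffs.intercept)


def loo_predictions(table: LIETrainingTable, include_intercept: bool = False) -> dict[str, float]:
    """Leave-one-out ΔG predictions, keyed by compound id.

    For each row the model is refit on the remaining rows and the held-out
    compound is predicted.  Diagnostic for over-fitting and for probing how
    a published predicted-ΔG column was derived.
    """
    p = 4 if include_intercept else 3
    if len(table) < p + 2:
        raise TableSizeError(
            f"leave-one-out needs at least {p + 2} rows, got {len(table)}")
    out: dict[str, float] = {}
    for i, (energy, _) in enumerate(table.rows):
        subset = LIETrainingTable(
            rows=table.rows[:i] + table.rows[i + 1:], provenance=table.provenance)
        rep = fit_lie(subset, include_intercept=include_intercept)
        out[energy.compound_id] = predict_dg(rep.coefficients, energy)
    return out


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of two equal-length series.

    Symmetric in its arguments and invariant to affine rescaling of either
    series.  Raises on series shorter than 3 or with zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def anova_oneway_from_summary(means: Sequence[float], sds: Sequence[float],
                              ns: Sequence[int]) -> AnovaResult:
    """One-way ANOVA F statistic from per-group summary statistics.

    Uses the standard decomposition: between-group sum of squares from the
    group means about the grand (weighted) mean, within-group sum of
    squares from Σ(nᵢ−1)·sdᵢ².

    Raises
    ------
    ValueError
        Fewer than 2 groups, any n < 2, negative sd, or the fully
        degenerate case of zero within-group variance with equal means.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = means.size
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    if sds.size != k or ns.size != k:
        raise ValueError("means, sds and ns must have equal lengths")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("standard deviations must be >= 0")
    n_total = int(ns.sum())
    grand = float(np.sum(ns * means) / n_total)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds ** 2))
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("F undefined: zero variance within and between groups")
        f = float("inf")
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(f_statistic=f, df_between=df_b, df_within=df_w, p_value=p)
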