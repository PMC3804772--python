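"""Delimited-table readers/writers and run configuration.

CSV with a header row is the canonical dialect; TSV is accepted on read.
The compound-table schema is::

    compound_id, glide_xp_score, u_vdw, u_elec, u_cav,
    predicted_dg, kd_mean, kd_sd, experimental_dg

with empty cells for unmeasured quantities.  Titration tables carry
``ligand_total_uM, f_observed`` plus optional ``a_ex, a_em`` columns.
"""

from __future__ import annotations

import dataclasses
import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .quench import QuenchTitration
from .thermo import AffinityRecord, DomainError, EnergyComponents, ThermoConstants

__all__ = [
    "COMPOUND_COLUMNS",
    "RunConfig",
    "read_compound_table",
    "write_compound_table",
    "records_to_dataframe",
    "read_titration",
    "write_titration",
]

COMPOUND_COLUMNS = ("compound_id", "glide_xp_score", "u_vdw", "u_elec", "u_cav",
                    "predicted_dg", "kd_mean", "kd_sd", "experimental_dg")

TITRATION_COLUMNS = ("ligand_total_uM", "f_observed", "a_ex", "a_em")


def _read_delimited(source) -> pd.DataFrame:
    """Read CSV (canonical) or TSV, sniffing the separator."""
    return pd.read_csv(source, sep=None, engine="python")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_compound_table(source: str | Path | _io.IOBase) -> list[AffinityRecord]:
    """Parse a compound table into validated :class:`AffinityRecord` rows."""
    df = _read_delimited(source)
    missing = {"compound_id"} - set(df.columns)
    if missing:
        raise DomainError(f"compound table missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        cid = str(row["compound_id"])
        energy = None
        if all(c in df.columns and _opt(row[c]) is not None
               for c in ("u_vdw", "u_elec", "u_cav")):
            energy = EnergyComponents(cid, float(row["u_vdw"]),
                                      float(row["u_elec"]), float(row["u_cav"]))
        records.append(AffinityRecord(
            compound_id=cid,
            glide_xp_score=_opt(row.get("glide_xp_score")),
            energy=energy,
            kd_mean=_opt(row.get("kd_mean")),
            kd_sd=_opt(row.get("kd_sd")),
            dg_experimental=_opt(row.get("experimental_dg")),
            dg_predicted=_opt(row.get("predicted_dg")),
        ))
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise DomainError("duplicate compound ids in table")
    return records


def records_to_dataframe(records: Sequence[AffinityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "compound_id": r.compound_id,
            "glide_xp_score": r.glide_xp_score,
            "u_vdw": r.energy.u_vdw if r.energy else None,
            "u_elec": r.energy.u_elec if r.energy else None,
            "u_cav": r.energy.u_cav if r.energy else None,
            "predicted_dg": r.dg_predicted,
            "kd_mean": r.kd_mean,
            "kd_sd": r.kd_sd,
            "experimental_dg": r.dg_experimental,
        })
    return pd.DataFrame(rows, columns=list(COMPOUND_COLUMNS))


def write_compound_table(records: Sequence[AffinityRecord],
                         path: str | Path) -> None:
    """Canonical CSV serialization (stable across read→write round trips)."""
    records_to_dataframe(records).to_csv(path, index=False)


def read_titration(source: str | Path | _io.IOBase, receptor_total: float,
                   f0: float | None = None) -> QuenchTitration:
    """Parse a titration table; receptor concentration comes from config."""
    df = _read_delimited(source)
    required = {"ligand_total_uM", "f_observed"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"titration table missing columns: {sorted(missing)}")
    a_ex = tuple(df["a_ex"].astype(float)) if "a_ex" in df.columns else None
    a_em = tuple(df["a_em"].astype(float)) if "a_em" in df.columns else None
    return QuenchTitration(
        ligand_total=tuple(df["ligand_total_uM"].astype(float)),
        f_observed=tuple(df["f_observed"].astype(float)),
        receptor_total=receptor_total, a_ex=a_ex, a_em=a_em, f0=f0)


def write_titration(titration: QuenchTitration, path: str | Path) -> None:
    data = {"ligand_total_uM": titration.ligand_total,
            "f_observed": titration.f_observed}
    if titration.a_ex is not None:
        data["a_ex"] = titration.a_ex
    if titration.a_em is not None:
        data["a_em"] = titration.a_em
    pd.DataFrame(data).to_csv(path, index=False)


_RUNCONFIG_KEYS = {
    "gas_constant_R", "temperature_T", "include_intercept", "assay_mode",
    "constrained_intercept", "receptor_total", "f0", "output", "log_level",
    "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run options shared by the CLI subcommands."""

    gas_constant_R: float = 0.00199
    temperature_T: float = 298.0
    include_intercept: bool = False
    assay_mode: str = "total-as-free"
    constrained_intercept: bool = False
    receptor_total: float = 2.0
    f0: float | None = None
    output: str | None = None
    log_level: str = "WARNING"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay_mode not in ("total-as-free", "iterative-depletion"):
            raise DomainError(f"unknown assay_mode {self.assay_mode!r}")
        # constants validated by construction
        ThermoConstants(self.gas_constant_R, self.temperature_T)

    @property
    def constants(self) -> ThermoConstants:
        return ThermoConstants(self.gas_constant_R, self.temperature_T)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML mapping; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise DomainError("config file must contain a mapping")
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
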