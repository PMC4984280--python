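"""Delimited-text readers/writers and run-configuration parsing.

Interchange formats are deliberately plain: UTF-8 comma-separated values
with '.' decimal for tables, YAML for the run configuration and JSON for
parameter bundles.  Configuration keys mirror the operational variable
names (V, phi_V, V_S, C_S_MC, C_S_MR, Y_max, m_S, k_d); unknown keys are
rejected so that typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .energetics import MaintenanceProfile, PirtParameters
from .feed import MixingVesselFeed
from .simulator import ReactorConfig

__all__ = [
    "ParseError",
    "read_timeseries",
    "write_timeseries",
    "RunConfig",
    "read_run_config",
]

RETENTOSTAT_COLUMNS = [
    "t_h",
    "C_X_gL",
    "viable_fraction",
    "C_S_feed_gL",
    "glycogen_g_per_g",
    "trehalose_g_per_g",
]
CHEMOSTAT_COLUMNS = ["D_per_h", "C_S_in_gL", "C_X_gL", "C_S_residual_gL"]


class ParseError(ValueError):
    """Raised for malformed delimited-text inputs."""


def read_timeseries(
    path, columns, time_column: str | None = "t_h"
) -> pd.DataFrame:
    """Read and validate a CSV table.

    Checks that the file is non-empty, that every schema column is
    present, that all cells are numeric and that ``time_column`` (when
    given and present) is strictly increasing.  Errors name the
    offending columns or file lines (header = line 1).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty input file") from None
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if raw.empty:
        raise ParseError(f"{path}: header only, no data rows")
    out = {}
    for col in columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or converted.isna().any():
            lines = [int(i) + 2 for i in converted.index[converted.isna()]]
            raise ParseError(
                f"{path}: non-numeric or missing values in column {col!r} "
                f"at line(s) {lines}"
            )
        out[col] = converted.to_numpy(dtype=float)
    df = pd.DataFrame(out)
    if time_column and time_column in df.columns:
        t = df[time_column].to_numpy()
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            lines = [int(i) + 3 for i in bad]
            raise ParseError(
                f"{path}: column {time_column!r} not strictly increasing "
                f"at line(s) {lines}"
            )
    return df


def write_timeseries(df: pd.DataFrame, path) -> None:
    """Write a table as UTF-8 CSV with stable formatting (round-trips)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class ChemostatSection:
    m_S: float = 0.0100
    Y_max: float = 0.584
    D_levels: tuple = (0.025, 0.05, 0.075, 0.10)
    replicates: int = 2


@dataclass(frozen=True)
class RetentostatSection:
    m_S: float = 0.0031
    k_d: float = 6e-5
    t_end: float = 600.0
    enabled: bool = True


@dataclass(frozen=True)
class NoiseSection:
    cv: float = 0.03
    viability_sd: float = 0.005


@dataclass(frozen=True)
class MaintenanceSection:
    m_S_high: float = 0.0100
    m_S_low: float = 0.0031
    mu_mid: float = 0.045
    steepness: float = 200.0
    enabled: bool = True

    def profile(self) -> MaintenanceProfile | None:
        if not self.enabled:
            return None
        return MaintenanceProfile(
            m_S_high=self.m_S_high,
            m_S_low=self.m_S_low,
            mu_mid=self.mu_mid,
            steepness=self.steepness,
        )


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of reactor, feed, truth and noise settings."""

    reactor: ReactorConfig = ReactorConfig()
    feed: MixingVesselFeed = MixingVesselFeed()
    chemostat: ChemostatSection = ChemostatSection()
    retentostat: RetentostatSection = RetentostatSection()
    maintenance: MaintenanceSection = MaintenanceSection()
    noise: NoiseSection = NoiseSection()
    seed: int = 0

    @property
    def chemostat_pirt(self) -> PirtParameters:
        return PirtParameters(m_S=self.chemostat.m_S, Y_max=self.chemostat.Y_max)

    @property
    def retentostat_pirt(self) -> PirtParameters:
        return PirtParameters(m_S=self.retentostat.m_S, Y_max=self.chemostat.Y_max)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_SECTIONS = {
    "reactor": ReactorConfig,
    "feed": MixingVesselFeed,
    "chemostat": ChemostatSection,
    "retentostat": RetentostatSection,
    "maintenance": MaintenanceSection,
    "noise": NoiseSection,
}


def _build_section(cls, data: dict, name: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ParseError(f"unknown key(s) {sorted(unknown)} in section {name!r}")
    if "D_levels" in data:
        data = {**data, "D_levels": tuple(data["D_levels"])}
    return cls(**data)


def read_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ParseError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise ParseError(f"{path}: section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return RunConfig(**kwargs)
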