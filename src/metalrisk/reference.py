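"""Domain types and packaged reference constants.

This module holds the toxicological reference values (oral reference doses,
cancer slope factors, maximum residue levels), the default adult ingestion
scenario, the instrument detection limits, and the packaged study tables of
group-level element concentrations in sheep and goat muscle and liver.

All downstream stages (deterministic risk, Monte Carlo, chemometrics) consume
these types; nothing else in the package hard-codes a toxicological constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

ELEMENTS: tuple[str, ...] = ("Cd", "Pb", "Ni", "Co", "Se", "Cu", "Fe", "Mg", "Mn", "Zn")
TOXIC_ELEMENTS: frozenset[str] = frozenset({"Cd", "Pb", "Ni"})
TISSUES: tuple[str, ...] = ("muscle", "liver")
SPECIES: tuple[str, ...] = ("sheep", "goat")
SEXES: tuple[str, ...] = ("female", "male")

DAYS_PER_YEAR = 365


class ConfigurationError(ValueError):
    """Raised when a reference bundle override names an unknown key."""


def element_category(symbol: str) -> str:
    """Return 'toxic' for Cd/Pb/Ni, 'essential' for the rest."""
    if symbol not in ELEMENTS:
        raise ConfigurationError(f"unknown element symbol: {symbol!r}")
    return "toxic" if symbol in TOXIC_ELEMENTS else "essential"


@dataclass(frozen=True)
class GroupKey:
    """One of the 8 study groups: species x sex x tissue."""

    species: str
    sex: str
    tissue: str

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species: {self.species!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex: {self.sex!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue: {self.tissue!r}")


@dataclass(frozen=True)
class ToxReference:
    """Per-element toxicological constants.

    rfd : oral reference dose, mg/kg-bw/day (None where not established).
    csf : oral cancer slope factor, per (mg/kg-bw/day); only Pb, Cd, Ni.
    mrl_muscle, mrl_liver : maximum residue levels, mg/kg tissue.
    """

    element: str
    rfd: Optional[float] = None
    csf: Optional[float] = None
    mrl_muscle: Optional[float] = None
    mrl_liver: Optional[float] = None
    mrl_source: Optional[str] = None

    def mrl_for(self, tissue: str) -> Optional[float]:
        if tissue == "muscle":
            return self.mrl_muscle
        if tissue == "liver":
            return self.mrl_liver
        raise ValueError(f"unknown tissue: {tissue!r}")


@dataclass(frozen=True)
class ExposureParams:
    """Adult ingestion scenario.

    ir_muscle : meat ingestion rate, kg/day (3.14 kg/year / 365 by default).
    ir_liver  : liver ingestion rate, kg/day.
    bw        : body weight, kg.
    ef        : exposure frequency, days/year.
    ed        : exposure duration, years.
    at        : averaging time, days.  With the defaults ef*ed == at, so the
                hazard quotient reduces exactly to EDI/RfD.
    """

    ir_muscle: float = 3.14 / DAYS_PER_YEAR
    ir_liver: float = 0.002
    bw: float = 70.0
    ef: float = 365.0
    ed: float = 70.0
    at: float = 25550.0

    def __post_init__(self) -> None:
        for name in ("ir_muscle", "ir_liver", "bw", "ef", "ed", "at"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ExposureParams.{name} must be positive")

    def ir_for(self, tissue: str) -> float:
        if tissue == "muscle":
            return self.ir_muscle
        if tissue == "liver":
            return self.ir_liver
        raise ValueError(f"unknown tissue: {tissue!r}")


class LodTable(dict):
    """element symbol -> limit of detection, mg/kg (converted from ppb)."""

    @classmethod
    def from_ppb(cls, ppb: Mapping[str, float]) -> "LodTable":
        # ppb is ug/kg for tissue; concentrations elsewhere are mg/kg.
        return cls({el: v / 1000.0 for el, v in ppb.items()})


def _load_bundle_yaml() -> dict:
    text = resources.files("metalrisk.data").joinpath("reference.yaml").read_text()
    return yaml.safe_load(text)


def load_reference_bundle(
    overrides: Optional[Mapping] = None,
) -> tuple[dict[str, ToxReference], ExposureParams, LodTable]:
    """Load the packaged constants, optionally overriding named values.

    ``overrides`` may contain exposure fields (``bw``, ``ef``, ``ed``, ``at``,
    ``ir_muscle``, ``ir_liver``), or nested maps ``rfd``/``csf``/``lod_ppb``
    keyed by element symbol.  Unknown keys raise :class:`ConfigurationError`.

    Returns (tox table keyed by element, exposure defaults, LOD table).
    """
    raw = _load_bundle_yaml()
    rfd = dict(raw["rfd"])
    csf = dict(raw["csf"])
    mrl = {el: dict(v) for el, v in raw["mrl"].items()}
    lod_ppb = dict(raw["lod_ppb"])
    exposure = dict(raw["exposure"])

    exp_kwargs = {
        "ir_muscle": exposure["ir_muscle_kg_per_year"] / DAYS_PER_YEAR,
        "ir_liver": exposure["ir_liver"],
        "bw": float(exposure["bw"]),
        "ef": float(exposure["ef"]),
        "ed": float(exposure["ed"]),
        "at": float(exposure["at"]),
    }

    if overrides:
        for key, value in overrides.items():
            if key in exp_kwargs:
                exp_kwargs[key] = float(value)
            elif key in ("rfd", "csf", "lod_ppb"):
                table = {"rfd": rfd, "csf": csf, "lod_ppb": lod_ppb}[key]
                for el, v in value.items():
                    if el not in ELEMENTS:
                        raise ConfigurationError(
                            f"override {key}[{el!r}]: unknown element"
                        )
                    table[el] = float(v)
            else:
                raise ConfigurationError(f"unknown override key: {key!r}")

    tox = {
        el: ToxReference(
            element=el,
            rfd=rfd.get(el),
            csf=csf.get(el),
            mrl_muscle=mrl.get(el, {}).get("muscle"),
            mrl_liver=mrl.get(el, {}).get("liver"),
            mrl_source=mrl.get(el, {}).get("source"),
        )
        for el in ELEMENTS
    }
    return tox, ExposureParams(**exp_kwargs), LodTable.from_ppb(lod_ppb)


def study_fixture() -> pd.DataFrame:
    """The packaged study tables as a tidy frame of group summaries.

    One row per (species, sex, tissue, element): 8 groups x 10 elements =
    80 cells.  Non-detect cells (Cd and Co in muscle everywhere; Pb in sheep
    muscle) carry ``censored=True`` with value and sd missing.
    """
    text = resources.files("metalrisk.data").joinpath("study_concentrations.csv")
    with resources.as_file(text) as path:
        df = pd.read_csv(path, dtype={"value": str})
    censored = df["value"].str.strip().str.upper() == "ND"
    df["censored"] = censored
    df["value"] = pd.to_numeric(df["value"].where(~censored), errors="raise")
    df["sd"] = pd.to_numeric(df["sd"], errors="coerce")
    df["n"] = df["n"].astype(int)
    return df


# Hazard quotients as published in the study's summary risk table, used as
# an independent cross-check of HI aggregation (several cells differ from
# recomputation via the printed group means; see docs/methods.md).
PUBLISHED_HQ_TABLE: dict[str, dict[str, float]] = {
    "liver": {
        "Cd": 0.0049,
        "Ni": 0.00139,
        "Pb": 0.006,
        "Co": 0.0004,
        "Se": 0.017,
        "Fe": 0.0103,
        "Mn": 0.0019,
        "Cu": 0.028,
        "Zn": 0.016,
    },
    "muscle": {
        "Ni": 0.009,
        "Pb": 0.015,
        "Se": 0.070,
        "Fe": 0.02261,
        "Mn": 0.0018,
        "Cu": 0.0330,
        "Zn": 0.051,
    },
}
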