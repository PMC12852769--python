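"""Reading and writing concentration tables with explicit censoring semantics.

Input CSVs are tidy: one row per measurement (or per group summary) with
columns ``species, sex, tissue, element, value`` and optional ``sd, n,
sample_id``.  The single censoring token is ``ND`` (case-insensitive) in the
value column; censored rows resolve their limit of detection from the
packaged LOD table unless an explicit ``lod`` column is present.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import json
import math

import pandas as pd

from .reference import ELEMENTS, GroupKey, LodTable


class IngestError(ValueError):
    """Malformed input row; the message carries the 1-based data row number."""


ND_POLICIES = ("zero", "half_lod", "lod")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One element measurement on one sample, or one group summary.

    ``censored`` rows have no value and carry the detection limit instead.
    Group summaries carry ``sd`` and ``n``; per-sample rows carry a
    ``sample_id``.
    """

    group: GroupKey
    element: str
    value: Optional[float] = None
    censored: bool = False
    lod: Optional[float] = None
    n: Optional[int] = None
    sd: Optional[float] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.censored:
            if self.value is not None:
                raise ValueError("censored record must not carry a value")
        else:
            if self.value is None or self.value < 0:
                raise ValueError("uncensored record needs a nonnegative value")
        if self.sd is not None:
            if self.sd < 0:
                raise ValueError("sd must be nonnegative")
            if self.n is not None and self.n < 2:
                raise ValueError("sd requires n >= 2")


def read_concentrations(path, lod_table: LodTable) -> list[ConcentrationRecord]:
    """Parse a tidy concentration CSV into records.

    ``ND`` values become censored records with the LOD filled from
    ``lod_table``.  Unknown element symbols, negative values, or otherwise
    malformed rows raise :class:`IngestError` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"species", "sex", "tissue", "element", "value"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"missing required columns: {sorted(missing)}")

    records: list[ConcentrationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            element = str(row.element).strip()
            if element not in ELEMENTS:
                raise ValueError(f"unknown element symbol {element!r}")
            group = GroupKey(
                species=str(row.species).strip(),
                sex=str(row.sex).strip(),
                tissue=str(row.tissue).strip(),
            )
            raw = str(row.value).strip()
            censored = raw.upper() == "ND"
            value = None if censored else float(raw)
            if value is not None and value < 0:
                raise ValueError(f"negative concentration {value}")

            def _opt_float(name: str) -> Optional[float]:
                v = getattr(row, name, None)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    return None
                s = str(v).strip()
                return float(s) if s and s.lower() != "nan" else None

            lod = _opt_float("lod")
            if censored and lod is None:
                lod = lod_table.get(element)
                if lod is None:
                    raise ValueError(f"no LOD available for censored {element}")
            n_raw = _opt_float("n")
            sample_id = getattr(row, "sample_id", None)
            if sample_id is not None and (
                not isinstance(sample_id, str) or not sample_id.strip()
            ):
                sample_id = None
            records.append(
                ConcentrationRecord(
                    group=group,
                    element=element,
                    value=value,
                    censored=censored,
                    lod=lod,
                    n=int(n_raw) if n_raw is not None else None,
                    sd=_opt_float("sd"),
                    sample_id=sample_id,
                )
            )
        except (ValueError, TypeError) as exc:
            raise IngestError(f"row {i}: {exc}") from exc
    return records


def resolve_censored(
    records: Iterable[ConcentrationRecord], policy: str = "zero"
) -> list[ConcentrationRecord]:
    """Substitute numeric values for censored records.

    Policies: ``zero`` (default, non-detect treated as absent), ``half_lod``
    (LOD/2), ``lod`` (full detection limit).  Uncensored rows pass through
    unchanged; the ``censored`` flag is retained so provenance survives.
    """
    if policy not in ND_POLICIES:
        raise ValueError(f"unknown ND policy {policy!r}; choose from {ND_POLICIES}")
    out: list[ConcentrationRecord] = []
    for rec in records:
        if not rec.censored:
            out.append(rec)
            continue
        if rec.lod is None:
            raise ValueError(
                f"censored record {rec.group}/{rec.element} has no LOD to resolve"
            )
        value = {"zero": 0.0, "half_lod": rec.lod / 2.0, "lod": rec.lod}[policy]
        out.append(
            ConcentrationRecord(
                group=rec.group,
                element=rec.element,
                value=value,
                censored=False,
                lod=rec.lod,
                n=rec.n,
                sd=rec.sd,
                sample_id=rec.sample_id,
            )
        )
    return out


def records_to_frame(records: Iterable[ConcentrationRecord]) -> pd.DataFrame:
    """Tidy frame mirroring the input CSV schema (ND for censored cells)."""
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.group.species,
                "sex": r.group.sex,
                "tissue": r.group.tissue,
                "element": r.element,
                "value": "ND" if r.censored else repr(float(r.value)),
                "sd": r.sd,
                "n": r.n,
                "lod": r.lod,
                "sample_id": r.sample_id,
            }
        )
    return pd.DataFrame(rows)


def write_records(records: Iterable[ConcentrationRecord], path) -> None:
    """Write records as CSV, round-trip stable through read_concentrations."""
    records_to_frame(records).to_csv(path, index=False)


def write_report(results: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a risk or Monte Carlo report table.

    CSV preserves all numeric fields at full stored precision (floats are
    emitted via ``repr``).  JSON nests rows per tissue with per-element ILCR
    and HQ entries plus an HI row, matching the study's summary-table layout.
    Report metadata notes that concentrations are treated as mg/kg as given
    (wet/dry basis unspecified upstream).
    """
    if format == "csv":
        out = results.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(
                    lambda v: repr(float(v)) if pd.notna(v) else "")
        out.to_csv(path, index=False)
    elif format == "json":
        payload: dict = {
            "metadata": {
                "concentration_basis": "mg/kg as reported (wet/dry unspecified)"
            },
            "tissues": {},
        }
        if "tissue" in results.columns:
            for tissue, sub in results.groupby("tissue"):
                entry: dict = {"elements": {}, "HI": None}
                for _, row in sub.iterrows():
                    el = row.get("element")
                    if pd.isna(el) or el is None:
                        continue
                    entry["elements"][el] = {
                        k: (None if pd.isna(row[k]) else row[k])
                        for k in row.index
                        if k not in ("tissue", "element")
                    }
                if "hi" in sub.columns and sub["hi"].notna().any():
                    entry["HI"] = float(sub["hi"].dropna().iloc[0])
                payload["tissues"][tissue] = entry
        else:
            payload["rows"] = results.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> pd.DataFrame:
    """Read back a CSV report written by :func:`write_report`.

    Uses the round-trip float parser so all stored digits survive.
    """
    return pd.read_csv(path, float_precision="round_trip")


def load_study_records() -> list[ConcentrationRecord]:
    """The packaged study group summaries as ConcentrationRecords."""
    from importlib import resources

    from .reference import load_reference_bundle

    _, _, lod_table = load_reference_bundle()
    src = resources.files("metalrisk.data").joinpath("study_concentrations.csv")
    with resources.as_file(src) as path:
        return read_concentrations(path, lod_table)
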