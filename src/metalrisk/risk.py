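"""Deterministic exposure and risk computation.

Implements the standard USEPA dietary risk chain for a single ingestion
route:

    EDI  = IR * C / BW                       (mg/kg-bw/day)
    HQ   = (EF * ED * IR * C) / (RfD * BW * AT)
    HI   = sum of HQ over elements in one tissue
    ILCR = EDI * CSF

With the default adult scenario (EF=365 d/y, ED=70 y, AT=25550 d) the
product EF*ED equals AT exactly, so HQ reduces to EDI/RfD.

ILCR is banded per USEPA practice: below 1e-6 negligible, above 1e-4
unacceptable, the closed interval between them acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .ingest import ConcentrationRecord, resolve_censored
from .reference import ExposureParams, ToxReference

NEGLIGIBLE_THRESHOLD = 1e-6
UNACCEPTABLE_THRESHOLD = 1e-4

_BAND_ORDER = {"negligible": 0, "acceptable": 1, "unacceptable": 2}


class RiskUndefinedError(ValueError):
    """HQ requested without an RfD, or ILCR without a CSF."""


@dataclass(frozen=True)
class RiskResult:
    """Per-element deterministic risk for one tissue."""

    label: str
    tissue: str
    element: str
    concentration: float
    edi: float
    hq: Optional[float] = None
    ilcr: Optional[float] = None
    hq_rank: Optional[int] = None


@dataclass(frozen=True)
class TissueRisk:
    """All per-element results for one tissue plus their hazard index."""

    tissue: str
    results: tuple[RiskResult, ...]
    hi: float


def compute_edi(c: float, ir: float, bw: float) -> float:
    """Estimated daily intake, IR*C/BW, mg/kg-bw/day."""
    if c < 0:
        raise ValueError(f"concentration must be nonnegative, got {c}")
    if ir <= 0 or bw <= 0:
        raise ValueError("ingestion rate and body weight must be positive")
    return ir * c / bw


def compute_hq(
    c: float, params: ExposureParams, ir: float, rfd: Optional[float]
) -> float:
    """Hazard quotient (EF*ED*IR*C)/(RfD*BW*AT).

    Raises :class:`RiskUndefinedError` when the element has no reference
    dose (Mg), rather than returning a number.
    """
    if rfd is None:
        raise RiskUndefinedError("HQ undefined for element without an RfD")
    if rfd <= 0:
        raise ValueError("rfd must be positive")
    if c < 0:
        raise ValueError(f"concentration must be nonnegative, got {c}")
    if params.ef * params.ed == params.at:
        # chronic-exposure identity: the time terms cancel exactly, so
        # evaluate via EDI to keep HQ == EDI/RfD bit-for-bit
        return compute_edi(c, ir, params.bw) / rfd
    return (params.ef * params.ed * ir * c) / (rfd * params.bw * params.at)


def compute_ilcr(edi: float, csf: Optional[float]) -> float:
    """Incremental lifetime cancer risk, EDI*CSF."""
    if csf is None:
        raise RiskUndefinedError("ILCR undefined for element without a CSF")
    if csf <= 0:
        raise ValueError("csf must be positive")
    if edi < 0:
        raise ValueError("edi must be nonnegative")
    return edi * csf


def aggregate_hi(hqs: Iterable[Optional[float]]) -> float:
    """Hazard index: exact sum of the present HQ values (None skipped)."""
    return sum(h for h in hqs if h is not None)


def classify_risk(ilcr: float) -> str:
    """USEPA band: negligible (<1e-6), acceptable ([1e-6, 1e-4]), else unacceptable."""
    if ilcr < 0:
        raise ValueError("ilcr must be nonnegative")
    if ilcr < NEGLIGIBLE_THRESHOLD:
        return "negligible"
    if ilcr <= UNACCEPTABLE_THRESHOLD:
        return "acceptable"
    return "unacceptable"


def band_order(band: str) -> int:
    return _BAND_ORDER[band]


def screen_mrl(record: ConcentrationRecord, tox: ToxReference) -> str:
    """Compare one measurement with its tissue-matched maximum residue level.

    Returns ``exceeds`` on a strict exceedance, ``compliant`` at or below the
    limit (limits are maxima, so equality complies), ``no_limit`` when no MRL
    is packaged for the element/tissue.  Censored records are compliant by
    construction: a non-detect cannot exceed a limit above the LOD.
    """
    mrl = tox.mrl_for(record.group.tissue)
    if mrl is None:
        return "no_limit"
    value = 0.0 if record.censored else record.value
    return "exceeds" if value > mrl else "compliant"


def pool_groups(
    records: Iterable[ConcentrationRecord],
    weights: str = "equal",
    nd_policy: str = "zero",
) -> pd.DataFrame:
    """Pooled mean concentration per (tissue, element) across the groups.

    ``equal`` weights each group summary the same; ``by_n`` weights by the
    per-group sample count (identical under the balanced n=20 design).
    Censored records enter at the value implied by ``nd_policy``.
    """
    if weights not in ("equal", "by_n"):
        raise ValueError(f"unknown weighting {weights!r}")
    resolved = resolve_censored(list(records), policy=nd_policy)
    rows = [
        {
            "tissue": r.group.tissue,
            "element": r.element,
            "value": r.value,
            "n": r.n if r.n is not None else 1,
        }
        for r in resolved
    ]
    if not rows:
        raise ValueError("no records to pool")
    df = pd.DataFrame(rows)

    def _pool(sub: pd.DataFrame) -> float:
        if weights == "equal":
            return sub["value"].mean()
        return (sub["value"] * sub["n"]).sum() / sub["n"].sum()

    pooled = (
        df.groupby(["tissue", "element"], sort=True)
        .apply(_pool, include_groups=False)
        .rename("concentration")
        .reset_index()
    )
    return pooled


def tissue_risk(
    records: Iterable[ConcentrationRecord],
    tox_table: Mapping[str, ToxReference],
    params: ExposureParams,
    tissue: str,
    weights: str = "equal",
    nd_policy: str = "zero",
    label: str = "pooled",
) -> TissueRisk:
    """Full deterministic risk table for one tissue from pooled records.

    Elements without an RfD (Mg) get no HQ and do not enter HI; elements
    without a CSF get no ILCR.  HQ ranks are dense within the tissue,
    largest HQ first, ties broken alphabetically by element symbol.
    """
    pooled = pool_groups(records, weights=weights, nd_policy=nd_policy)
    pooled = pooled[pooled["tissue"] == tissue]
    if pooled.empty:
        raise ValueError(f"no records for tissue {tissue!r}")
    ir = params.ir_for(tissue)

    results = []
    for _, row in pooled.iterrows():
        el = row["element"]
        c = float(row["concentration"])
        tox = tox_table[el]
        edi = compute_edi(c, ir, params.bw)
        hq = (
            compute_hq(c, params, ir, tox.rfd) if tox.rfd is not None else None
        )
        ilcr = compute_ilcr(edi, tox.csf) if tox.csf is not None else None
        results.append(
            RiskResult(
                label=label, tissue=tissue, element=el,
                concentration=c, edi=edi, hq=hq, ilcr=ilcr,
            )
        )

    ranked = sorted(
        (r for r in results if r.hq is not None),
        key=lambda r: (-r.hq, r.element),
    )
    rank_of = {r.element: i + 1 for i, r in enumerate(ranked)}
    results = [
        RiskResult(
            label=r.label, tissue=r.tissue, element=r.element,
            concentration=r.concentration, edi=r.edi, hq=r.hq, ilcr=r.ilcr,
            hq_rank=rank_of.get(r.element),
        )
        for r in results
    ]
    hi = aggregate_hi(r.hq for r in results)
    return TissueRisk(tissue=tissue, results=tuple(results), hi=hi)


def risk_table(tissue_risks: Iterable[TissueRisk]) -> pd.DataFrame:
    """Flatten TissueRisk objects into a report frame (one HI row per tissue)."""
    rows = []
    for tr in tissue_risks:
        for r in tr.results:
            rows.append(
                {
                    "tissue": r.tissue,
                    "element": r.element,
                    "concentration": r.concentration,
                    "edi": r.edi,
                    "hq": r.hq,
                    "ilcr": r.ilcr,
                    "risk_band": classify_risk(r.ilcr) if r.ilcr is not None else None,
                    "hq_rank": r.hq_rank,
                    "hi": tr.hi,
                }
            )
    return pd.DataFrame(rows)
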