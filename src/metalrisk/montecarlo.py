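"""Distribution fitting and Monte Carlo propagation of exposure uncertainty.

Candidate concentration models (lognormal, Weibull, scaled beta, normal) are
fitted by maximum likelihood and ranked by the Anderson–Darling statistic
(a Kolmogorov–Smirnov p-value is reported alongside for reference).  The
selected distributions are propagated through the hazard-quotient and
cancer-risk equations by simple Monte Carlo: each iteration draws one
concentration per element, elements independent by default, with the hazard
index formed as the per-iteration sum of hazard quotients.

Random-number streams are derived per element from one root seed, so adding
or removing an element never perturbs the draws of the others.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import ExposureParams, ToxReference
from .risk import classify_risk

FIT_FAMILIES = ("lognormal", "weibull", "beta_scaled", "normal")
MIN_FIT_SAMPLES = 8

# free parameters per family (fixed bounds/locations excluded)
_N_PARAMS = {"lognormal": 2, "weibull": 2, "beta_scaled": 2, "normal": 2, "point": 0}


class FitError(ValueError):
    """Sample unsuitable for distribution fitting."""


@dataclass(frozen=True)
class FittedDistribution:
    """A fitted concentration model plus its goodness of fit."""

    family: str
    parameters: dict
    gof_statistic: float  # Anderson–Darling A^2
    gof_pvalue: float     # Kolmogorov–Smirnov p-value (reference)
    n_fit: int
    _dist: object = field(compare=False, repr=False, default=None)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.parameters["value"], dtype=float)
        return np.asarray(self._dist.ppf(rng.uniform(size=size)), dtype=float)

    def mean(self) -> float:
        if self.family == "point":
            return float(self.parameters["value"])
        return float(self._dist.mean())


def point_mass(value: float) -> FittedDistribution:
    """Degenerate distribution for a fixed (e.g. censored-to-zero) value."""
    if value < 0:
        raise ValueError("point mass must be nonnegative")
    return FittedDistribution(
        family="point", parameters={"value": float(value)},
        gof_statistic=0.0, gof_pvalue=1.0, n_fit=1,
    )


def anderson_darling(samples: np.ndarray, cdf) -> float:
    """Anderson–Darling A^2 for an arbitrary fitted CDF.

    A^2 = -n - (1/n) * sum_i (2i-1) [ln F(x_(i)) + ln(1 - F(x_(n+1-i)))].
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    f = np.clip(cdf(x), 1e-300, 1 - 1e-12)
    i = np.arange(1, n + 1)
    s = np.sum((2 * i - 1) * (np.log(f) + np.log1p(-f[::-1])))
    return float(-n - s / n)


def _fit_family(family: str, x: np.ndarray):
    """MLE fit; returns (frozen dist, parameter dict)."""
    if family == "lognormal":
        s, loc, scale = stats.lognorm.fit(x, floc=0)
        return stats.lognorm(s=s, loc=0, scale=scale), {
            "mu": math.log(scale), "sigma": s}
    if family == "weibull":
        c, loc, scale = stats.weibull_min.fit(x, floc=0)
        return stats.weibull_min(c=c, loc=0, scale=scale), {
            "shape": c, "scale": scale}
    if family == "beta_scaled":
        # finite support with a 5% margin to avoid boundary singularities;
        # for data touching zero the margin is taken on the sample range
        xmin, xmax = float(x.min()), float(x.max())
        if xmin > 0:
            lo, hi = 0.95 * xmin, 1.05 * xmax
        else:
            span = xmax - xmin
            lo, hi = xmin - 0.05 * span, xmax + 0.05 * span
        a, b, loc, scale = stats.beta.fit(x, floc=lo, fscale=hi - lo)
        return stats.beta(a=a, b=b, loc=lo, scale=hi - lo), {
            "alpha": a, "beta": b, "lower": lo, "upper": hi}
    if family == "normal":
        loc, scale = stats.norm.fit(x)
        return stats.norm(loc=loc, scale=scale), {"mean": loc, "sd": scale}
    raise FitError(f"unknown family {family!r}")


def fit_candidates(
    samples: Sequence[float], families: Iterable[str] = FIT_FAMILIES
) -> list[FittedDistribution]:
    """Fit each requested family by MLE and rank by goodness of fit.

    Ranking is by ascending Anderson–Darling statistic, ties broken by fewer
    free parameters then family name.  Requires at least 8 finite,
    non-degenerate samples; nonpositive samples cause the positive-support
    families (lognormal, Weibull) to be skipped with a warning.
    """
    x = np.asarray(list(samples), dtype=float)
    if len(x) < MIN_FIT_SAMPLES or not np.all(np.isfinite(x)):
        raise FitError(
            f"need >= {MIN_FIT_SAMPLES} finite samples to fit; for degenerate "
            "or tiny samples use point_mass()"
        )
    if np.ptp(x) == 0:
        raise FitError("sample is constant; use point_mass() instead")

    fits: list[FittedDistribution] = []
    for family in families:
        if family not in FIT_FAMILIES:
            raise FitError(f"unknown family {family!r}")
        if family in ("lognormal", "weibull") and x.min() <= 0:
            warnings.warn(
                f"skipping {family}: sample has nonpositive values", stacklevel=2
            )
            continue
        dist, params = _fit_family(family, x)
        a2 = anderson_darling(x, dist.cdf)
        ks_p = float(stats.kstest(x, dist.cdf).pvalue)
        fits.append(FittedDistribution(
            family=family, parameters=params, gof_statistic=a2,
            gof_pvalue=ks_p, n_fit=len(x), _dist=dist,
        ))
    fits.sort(key=lambda f: (f.gof_statistic, _N_PARAMS[f.family], f.family))
    return fits


@dataclass(frozen=True)
class MCSummary:
    """Summary statistics of one simulated risk quantity."""

    quantity: str  # "HQ(El)", "ILCR(El)", or "HI"
    tissue: str
    n_iter: int
    seed: int
    mean: float
    sd: float
    percentiles: dict  # {5: ..., 50: ..., 95: ...}


def _element_rng(seed: int, element: str) -> np.random.Generator:
    # per-element child stream: stable across element-set changes
    key = int.from_bytes(element.encode("ascii"), "little")
    return np.random.default_rng([seed, key])


def _summarize(quantity: str, tissue: str, draws: np.ndarray,
               n_iter: int, seed: int) -> MCSummary:
    if draws.max() == draws.min():
        # point mass: exact moments, no float noise from the summation
        v = float(draws[0])
        return MCSummary(quantity=quantity, tissue=tissue, n_iter=n_iter,
                         seed=seed, mean=v, sd=0.0,
                         percentiles={5: v, 50: v, 95: v})
    pct = np.percentile(draws, [5, 50, 95])
    return MCSummary(
        quantity=quantity, tissue=tissue, n_iter=n_iter, seed=seed,
        mean=float(draws.mean()), sd=float(draws.std(ddof=1)) if n_iter > 1 else 0.0,
        percentiles={5: float(pct[0]), 50: float(pct[1]), 95: float(pct[2])},
    )


def propagate(
    fitted: Mapping[str, FittedDistribution],
    params: ExposureParams,
    tox_table: Mapping[str, ToxReference],
    tissue: str,
    n_iter: int = 10_000,
    seed: int = 0,
) -> list[MCSummary]:
    """Monte Carlo propagation of concentration uncertainty into HQ/HI/ILCR.

    Each iteration draws one concentration per element (independent element
    streams derived from ``seed``), truncates negative draws at zero, and
    evaluates the risk equations.  Returns summaries for HQ and ILCR per
    element (where RfD/CSF exist) plus the HI distribution.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not any(
        tox_table[el].rfd is not None or tox_table[el].csf is not None
        for el in fitted
    ):
        raise ValueError("no fitted element has an RfD or CSF; nothing to propagate")

    ir = params.ir_for(tissue)
    summaries: list[MCSummary] = []
    hq_total = np.zeros(n_iter)
    any_hq = False
    for el in sorted(fitted):
        rng = _element_rng(seed, el)
        c = np.clip(fitted[el].sample(rng, n_iter), 0.0, None)
        tox = tox_table[el]
        edi = ir * c / params.bw
        if tox.rfd is not None:
            # same evaluation order as risk.compute_hq, so point-mass
            # propagation reproduces the deterministic value exactly
            if params.ef * params.ed == params.at:
                hq = edi / tox.rfd
            else:
                hq = (params.ef * params.ed * ir * c) / (
                    tox.rfd * params.bw * params.at)
            hq_total += hq
            any_hq = True
            summaries.append(_summarize(f"HQ({el})", tissue, hq, n_iter, seed))
        if tox.csf is not None:
            ilcr = edi * tox.csf
            summaries.append(_summarize(f"ILCR({el})", tissue, ilcr, n_iter, seed))
    if any_hq:
        summaries.append(_summarize("HI", tissue, hq_total, n_iter, seed))
    return summaries


def mc_report(summaries: Sequence[MCSummary]) -> pd.DataFrame:
    """Report rows: mean and 95th percentile per quantity, with the USEPA
    band of the 95th-percentile ILCR for cancer-risk rows."""
    if not summaries:
        raise ValueError("no summaries to report")
    rows = []
    for s in summaries:
        band = None
        if s.quantity.startswith("ILCR"):
            band = classify_risk(s.percentiles[95])
        rows.append({
            "quantity": s.quantity,
            "tissue": s.tissue,
            "n_iter": s.n_iter,
            "mean": s.mean,
            "sd": s.sd,
            "p5": s.percentiles[5],
            "p50": s.percentiles[50],
            "p95": s.percentiles[95],
            "risk_band_p95": band,
        })
    return pd.DataFrame(rows)
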