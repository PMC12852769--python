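"""Synthetic per-animal concentration cohorts.

The packaged study reports only group summaries (mean ± SD for 4 sex-species
groups x 2 tissues x 10 elements, n = 20 animals per group).  This module
generates per-sample datasets with that structure so every downstream stage
— censoring handling, risk pooling, distribution fitting, Monte Carlo, and
chemometrics — can be exercised end to end without external data.

Marginals are moment-matched to the target (mean, sd); inter-element
dependence, when requested, is induced by a Gaussian copula: a latent
multivariate normal draw is mapped through the standard normal CDF and then
through each element's marginal quantile function.  Pearson correlations
realized after the marginal transform are attenuated relative to the latent
correlation, so tests validate against empirical estimates, not the latent
target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .ingest import ConcentrationRecord
from .reference import ELEMENTS, GroupKey, LodTable, load_reference_bundle

FAMILIES = ("lognormal", "weibull", "normal_truncated")

# Two-block source structure planted for chemometric validation: one block
# of geogenic/terrestrial elements, one of anthropogenic ones.  Loading 0.88
# gives within-block pairwise correlations of 0.88^2 ~ 0.77.  The two latent
# factors are mildly anti-correlated (-0.3), so cross-block correlations sit
# near -0.23: distinct from both the within-block signal and the independent
# noise elements, which lets a 2-cluster dendrogram cut separate the blocks.
TERRESTRIAL_BLOCK = ("Cu", "Cd", "Fe", "Co", "Mn")
ANTHROPOGENIC_BLOCK = ("Pb", "Ni", "Zn")
_BLOCK_LOADING = 0.88
_FACTOR_CORRELATION = -0.3

# Nominal element scales (mg/kg) for the planted cohort, of the same order
# as the packaged study means pooled over tissues.
_NOMINAL_SCALE = {
    "Cd": 0.06, "Pb": 0.28, "Ni": 0.86, "Co": 0.09, "Se": 2.2,
    "Cu": 20.0, "Fe": 170.0, "Mg": 590.0, "Mn": 3.8, "Zn": 103.0,
}
_NOMINAL_CV = 0.2


class CohortSpecError(ValueError):
    """Invalid cohort specification (bad moments or correlation matrix)."""


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    targets maps (GroupKey, element) -> (mean, sd) in mg/kg; censor_cells
    lists (GroupKey, element) pairs emitted as non-detects regardless of the
    draw.  ``correlation`` is an element x element latent correlation matrix
    (symmetric, unit diagonal, PSD) over ``elements`` order.
    """

    groups: dict = field(default_factory=dict)  # GroupKey -> n
    targets: dict = field(default_factory=dict)  # (GroupKey, el) -> (mean, sd)
    family: str = "lognormal"
    censor_cells: set = field(default_factory=set)
    correlation: Optional[np.ndarray] = None
    elements: Sequence[str] = ELEMENTS
    seed: int = 0

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise CohortSpecError(f"unknown family {self.family!r}")
        for (gk, el), (mean, sd) in self.targets.items():
            if sd < 0:
                raise CohortSpecError(f"negative sd for {gk}/{el}")
            if mean <= 0 and sd > 0:
                raise CohortSpecError(f"sd > 0 with nonpositive mean for {gk}/{el}")
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            p = len(self.elements)
            if r.shape != (p, p):
                raise CohortSpecError("correlation matrix shape mismatch")
            if not np.allclose(r, r.T, atol=1e-12):
                raise CohortSpecError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-12):
                raise CohortSpecError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise CohortSpecError("correlation matrix is not positive semi-definite")


def default_cohort_spec(seed: int = 0, n: int = 20, family: str = "lognormal") -> CohortSpec:
    """CohortSpec reproducing the packaged study design (8 groups, n=20)."""
    from .reference import study_fixture

    df = study_fixture()
    groups: dict = {}
    targets: dict = {}
    censor: set = set()
    for _, row in df.iterrows():
        gk = GroupKey(row["species"], row["sex"], row["tissue"])
        groups[gk] = n
        if row["censored"]:
            censor.add((gk, row["element"]))
        else:
            sd = float(row["sd"]) if not math.isnan(row["sd"]) else 0.0
            targets[(gk, row["element"])] = (float(row["value"]), sd)
    return CohortSpec(groups=groups, targets=targets, family=family,
                      censor_cells=censor, seed=seed)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched lognormal (mu, sigma): mu = ln(m^2/sqrt(m^2+s^2))."""
    m2, s2 = mean * mean, sd * sd
    mu = math.log(m2 / math.sqrt(m2 + s2))
    sigma = math.sqrt(math.log(1.0 + s2 / m2))
    return mu, sigma


def _weibull_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Weibull (shape k, scale lam) via the CV equation."""
    cv2 = (sd / mean) ** 2

    def f(k: float) -> float:
        g1 = special.gamma(1 + 1 / k)
        g2 = special.gamma(1 + 2 / k)
        return g2 / (g1 * g1) - 1 - cv2

    k = optimize.brentq(f, 0.05, 200.0)
    lam = mean / special.gamma(1 + 1 / k)
    return k, lam


def _marginal(family: str, mean: float, sd: float):
    """Frozen scipy distribution moment-matched to (mean, sd)."""
    if family == "lognormal":
        mu, sigma = _lognormal_params(mean, sd)
        return stats.lognorm(s=sigma, scale=math.exp(mu))
    if family == "weibull":
        k, lam = _weibull_params(mean, sd)
        return stats.weibull_min(c=k, scale=lam)
    if family == "normal_truncated":
        # Truncation at 0 with untruncated moment matching; negligible bias
        # for the packaged targets (mean >> sd).
        a = (0.0 - mean) / sd
        return stats.truncnorm(a=a, b=np.inf, loc=mean, scale=sd)
    raise CohortSpecError(f"unknown family {family!r}")


def generate_cohort(spec: CohortSpec, lod_table: Optional[LodTable] = None) -> list[ConcentrationRecord]:
    """Draw a per-sample cohort according to ``spec``.

    Each group yields n samples x len(elements) records.  Cells listed in
    censor_cells, and draws falling below the element's detection limit, are
    emitted as censored records (no value, LOD attached).  Degenerate targets
    (sd = 0) yield constant values.  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    if lod_table is None:
        _, _, lod_table = load_reference_bundle()
    rng = np.random.default_rng(spec.seed)
    elements = list(spec.elements)
    p = len(elements)

    chol = None
    if spec.correlation is not None:
        r = np.asarray(spec.correlation, dtype=float)
        # eigenvalue-based factor tolerates PSD (singular) matrices
        w, v = np.linalg.eigh(r)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    records: list[ConcentrationRecord] = []
    counter = 0
    for gk in spec.groups:
        n = spec.groups[gk]
        if chol is not None:
            z = rng.standard_normal((n, p)) @ chol.T
            u = stats.norm.cdf(z)
        else:
            u = rng.uniform(size=(n, p))
        for i in range(n):
            counter += 1
            sample_id = f"S{counter:03d}"
            for j, el in enumerate(elements):
                lod = lod_table.get(el)
                if (gk, el) in spec.censor_cells:
                    records.append(ConcentrationRecord(
                        group=gk, element=el, censored=True, lod=lod,
                        sample_id=sample_id))
                    continue
                if (gk, el) not in spec.targets:
                    continue
                mean, sd = spec.targets[(gk, el)]
                if sd == 0.0:
                    value = mean
                else:
                    value = float(_marginal(spec.family, mean, sd).ppf(u[i, j]))
                if lod is not None and value < lod:
                    records.append(ConcentrationRecord(
                        group=gk, element=el, censored=True, lod=lod,
                        sample_id=sample_id))
                else:
                    records.append(ConcentrationRecord(
                        group=gk, element=el, value=value, lod=lod,
                        sample_id=sample_id))
    return records


def planted_source_cohort(n: int, seed: int = 0) -> list[ConcentrationRecord]:
    """Cohort with a planted two-source structure for chemometric tests.

    Two latent factors drive the element concentrations: factor 1 loads
    (0.88) on the terrestrial block {Cu, Cd, Fe, Co, Mn}, factor 2 on the
    anthropogenic block {Pb, Ni, Zn}; Se and Mg are independent noise.
    Within-block pairwise correlations are ~0.77 in expectation; the factors
    are mildly anti-correlated so cross-block correlations are ~-0.23
    (magnitude below 0.3).  Latents map to concentrations affinely (mean
    scale with 20% CV), preserving Pearson correlations exactly up to rare
    clipping at zero.
    """
    if n < 10:
        raise ValueError("planted_source_cohort requires n >= 10")
    rng = np.random.default_rng(seed)
    f1 = rng.standard_normal(n)
    g = rng.standard_normal(n)
    f2 = _FACTOR_CORRELATION * f1 + math.sqrt(1.0 - _FACTOR_CORRELATION**2) * g
    resid = math.sqrt(1.0 - _BLOCK_LOADING**2)

    latent = {}
    for el in ELEMENTS:
        eps = rng.standard_normal(n)
        if el in TERRESTRIAL_BLOCK:
            latent[el] = _BLOCK_LOADING * f1 + resid * eps
        elif el in ANTHROPOGENIC_BLOCK:
            latent[el] = _BLOCK_LOADING * f2 + resid * eps
        else:  # Se, Mg: independent
            latent[el] = eps

    gk = GroupKey("sheep", "female", "muscle")
    records: list[ConcentrationRecord] = []
    for i in range(n):
        sample_id = f"S{i + 1:03d}"
        for el in ELEMENTS:
            scale = _NOMINAL_SCALE[el]
            value = scale * (1.0 + _NOMINAL_CV * float(latent[el][i]))
            value = max(value, 1e-9 * scale)  # clip: latent below -5 sd
            records.append(ConcentrationRecord(
                group=gk, element=el, value=value, sample_id=sample_id))
    return records
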