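"""Source identification: correlation, PCA, and hierarchical clustering.

Elements sharing an origin (geogenic soil uptake vs anthropogenic inputs
such as traffic, industry, and agrochemicals) co-vary across animals.  This
module quantifies that structure three ways: a Pearson correlation matrix
with the conventional strength bands (r > 0.7 strong, 0.5–0.7 moderate),
PCA on the correlation matrix (standardized columns), and agglomerative
clustering of elements using 1 - r as the dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .ingest import ConcentrationRecord

DISTANCES = ("one_minus_r", "euclidean_standardized")
LINKAGES = ("average", "ward", "complete")


def records_to_matrix(
    records: Iterable[ConcentrationRecord],
    nd_policy: str = "zero",
) -> pd.DataFrame:
    """Pivot per-sample records into a samples x elements matrix.

    Samples are keyed by (group, sample_id); element columns are sorted
    alphabetically for deterministic downstream ordering.  Censored cells
    enter at the value implied by ``nd_policy``.
    """
    from .ingest import resolve_censored

    resolved = resolve_censored(list(records), policy=nd_policy)
    rows = [
        {
            "sample": (r.group.species, r.group.sex, r.group.tissue,
                       r.sample_id or ""),
            "element": r.element,
            "value": r.value,
        }
        for r in resolved
    ]
    df = pd.DataFrame(rows).pivot_table(
        index="sample", columns="element", values="value", aggfunc="first"
    )
    return df.sort_index(axis=1)


def band_of(r: float) -> str:
    """Correlation strength band on signed r: strong > 0.7, moderate in
    [0.5, 0.7], weak otherwise.  Exhaustive and mutually exclusive on
    [-1, 1]."""
    if r > 0.7:
        return "strong"
    if 0.5 <= r <= 0.7:
        return "moderate"
    return "weak"


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Pearson matrix with per-pair strength bands."""

    r: pd.DataFrame       # symmetric, unit diagonal
    n: int                # paired observations
    bands: pd.DataFrame   # same shape, entries strong/moderate/weak

    def pair(self, a: str, b: str) -> tuple[float, str]:
        return float(self.r.loc[a, b]), str(self.bands.loc[a, b])


def _drop_constant_columns(x: pd.DataFrame) -> pd.DataFrame:
    variances = x.var(axis=0, ddof=1)
    constant = variances[variances == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping zero-variance element columns: {constant}", stacklevel=3
        )
        x = x.drop(columns=constant)
    return x


def pearson_matrix(samples: pd.DataFrame) -> CorrelationResult:
    """Pearson correlations between element columns.

    Requires >= 3 samples; zero-variance columns are dropped with a warning.
    """
    if len(samples) < 3:
        raise ValueError("pearson_matrix requires at least 3 samples")
    x = _drop_constant_columns(samples)
    r = x.corr(method="pearson")
    bands = r.map(band_of)
    return CorrelationResult(r=r, n=len(x), bands=bands)


@dataclass(frozen=True)
class PcaResult:
    """Correlation-matrix PCA of the element concentrations.

    loadings are eigenvector * sqrt(eigenvalue) (columns PC1, PC2, ...);
    explained_variance_pct sums to 100 over all components; scores are the
    sample coordinates.  Sign convention: each component's largest-magnitude
    loading is positive.
    """

    loadings: pd.DataFrame
    explained_variance_pct: np.ndarray
    scores: pd.DataFrame
    standardized: bool


def run_pca(samples: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of the samples x elements matrix.

    With ``standardize`` (default) columns are scaled to zero mean and unit
    variance, i.e. PCA of the correlation matrix — the convention for
    variables on incommensurate scales.
    """
    if len(samples) < 3 or samples.shape[1] < 2:
        raise ValueError("run_pca requires >= 3 samples and >= 2 elements")
    x = _drop_constant_columns(samples) if standardize else samples
    elements = list(x.columns)
    values = x.to_numpy(dtype=float)
    values = values - values.mean(axis=0)
    if standardize:
        values = values / values.std(axis=0, ddof=1)

    n_comp = min(values.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(values)
    # loadings scaled by sqrt(eigenvalue): correlations of variables with PCs
    eigvals = pca.explained_variance_
    loadings = pca.components_.T * np.sqrt(eigvals)

    # fix eigenvector signs: largest-magnitude loading positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    pct = 100.0 * pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=elements, columns=cols),
        explained_variance_pct=pct,
        scores=pd.DataFrame(scores, index=x.index, columns=cols),
        standardized=standardize,
    )


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative clustering of elements.

    merges is the scipy linkage matrix (pairs + heights); leaves are element
    labels in dendrogram order.
    """

    merges: np.ndarray
    labels: tuple[str, ...]
    leaf_order: tuple[str, ...]
    distance: str
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster label per element at a k-cluster cut."""
        assignments = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))


def run_hca(
    samples: pd.DataFrame,
    distance: str = "one_minus_r",
    linkage: str = "average",
) -> ClusterTree:
    """Hierarchical clustering of element columns.

    ``one_minus_r`` (default) clusters by correlation similarity, the natural
    notion for source apportionment; ``euclidean_standardized`` clusters on
    z-scored concentration profiles.  Columns are processed in alphabetical
    order so equal-height merges resolve deterministically.
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}; choose from {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if samples.shape[1] < 3:
        raise ValueError("run_hca requires at least 3 elements")

    x = samples[sorted(samples.columns)]
    labels = tuple(x.columns)
    if distance == "one_minus_r":
        r = x.corr(method="pearson").to_numpy()
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry
        condensed = squareform(d, checks=False)
    else:
        z = (x - x.mean()) / x.std(ddof=1)
        profiles = z.to_numpy().T  # elements x samples
        diff = profiles[:, None, :] - profiles[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        condensed = squareform(d, checks=False)

    merges = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(merges)
    return ClusterTree(
        merges=merges,
        labels=labels,
        leaf_order=tuple(labels[i] for i in order),
        distance=distance,
        linkage=linkage,
    )


def correlation_report(result: CorrelationResult) -> pd.DataFrame:
    """Long-form upper-triangle listing of pairs, r, and band."""
    rows = []
    cols = list(result.r.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r, band = result.pair(a, b)
            rows.append({"element_a": a, "element_b": b, "r": r,
                         "n": result.n, "band": band})
    return pd.DataFrame(rows)
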