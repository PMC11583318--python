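"""Survey-level statistics over censored multi-element concentration tables.

Locations carry triplicate parallel preparations; multivariate analyses
(PCA, Ward clustering) work on per-location means of standardized number
concentrations, with elements that are censored nearly everywhere excluded
(values below the detection limit are never imputed by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import chi2
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "SurveyTable",
    "PcaResult",
    "GroupEllipse",
    "Dendrogram",
    "summarize",
    "zscore",
    "pca",
    "ward_cluster",
]


@dataclass
class SurveyTable:
    """Element x (location x parallel) concentrations with censoring metadata.

    ``number`` and ``mass`` are DataFrames indexed by (location, parallel)
    with one column per element; ``metadata`` is indexed by location and holds
    ``classification`` (anthropogenic / farm / natural), ``season``,
    ``sampling_month`` and ``shell_length``; ``lod_number`` / ``lod_mass`` are
    per-element detection limits on the same concentration scales.
    """

    number: pd.DataFrame
    mass: pd.DataFrame
    metadata: pd.DataFrame
    lod_number: pd.Series
    lod_mass: pd.Series

    VALID_CLASSES = ("anthropogenic", "farm", "natural")

    def __post_init__(self) -> None:
        bad = set(self.metadata["classification"]) - set(self.VALID_CLASSES)
        if bad:
            raise ValueError(f"unknown classification(s): {sorted(bad)}")

    @property
    def elements(self) -> list[str]:
        return list(self.number.columns)

    @property
    def locations(self) -> list[str]:
        return list(self.metadata.index)

    def values(self, quantity: str = "number") -> pd.DataFrame:
        if quantity not in ("number", "mass"):
            raise ValueError("quantity must be 'number' or 'mass'")
        return self.number if quantity == "number" else self.mass

    def lod(self, quantity: str = "number") -> pd.Series:
        return self.lod_number if quantity == "number" else self.lod_mass

    def censored(self, quantity: str = "number") -> pd.DataFrame:
        """Per-(location, parallel) mask: True where the value is below LOD."""
        return self.values(quantity).lt(self.lod(quantity), axis=1)

    def location_means(self, quantity: str = "number") -> pd.DataFrame:
        """Mean of the parallels per location (the dot plotted per location)."""
        return self.values(quantity).groupby(level="location").mean()

    def location_censored(self, quantity: str = "number") -> pd.DataFrame:
        """True where the location mean is not above the LOD."""
        return ~self.location_means(quantity).gt(self.lod(quantity), axis=1)


def summarize(table: SurveyTable) -> pd.DataFrame:
    """Per-element mean, min-max, and percent of locations above the LOD.

    Means, minima and maxima are taken over the uncensored location means
    (parallels averaged first); ``%>Ld`` counts the locations whose mean
    exceeds the detection limit, out of all locations. Elements censored at
    every location get an undefined (NaN) mean and ``%>Ld = 0``.
    """
    rows = {}
    n_loc = len(table.locations)
    for quantity in ("number", "mass"):
        means = table.location_means(quantity)
        cens = table.location_censored(quantity)
        kept = means.where(~cens)
        rows[f"{quantity}_mean"] = kept.mean()
        rows[f"{quantity}_min"] = kept.min()
        rows[f"{quantity}_max"] = kept.max()
        rows[f"{quantity}_pct_above_lod"] = 100.0 * (~cens).sum() / n_loc
    out = pd.DataFrame(rows)
    out.index.name = "element"
    return out


def zscore(matrix: pd.DataFrame, censored: pd.DataFrame | None = None,
           max_censored_fraction: float = 1.0) -> pd.DataFrame:
    """Standardize each element column to mean 0, sample SD 1.

    Columns that are fully censored, censored in more than
    ``max_censored_fraction`` of rows, or have zero variance are dropped with
    a warning; remaining censored cells are left as-is (the multivariate
    entry points control exclusion/imputation).
    """
    out = matrix.copy()
    if censored is not None:
        frac = censored.reindex(columns=out.columns).mean()
        if max_censored_fraction >= 1.0:
            drop = frac[frac >= 1.0].index
        else:
            drop = frac[frac > max_censored_fraction].index
        if len(drop):
            warnings.warn(f"dropping censored column(s): {list(drop)}", stacklevel=2)
            out = out.drop(columns=list(drop))
    sd = out.std(ddof=1)
    zero_var = sd[(sd == 0) | sd.isna()].index
    if len(zero_var):
        warnings.warn(f"dropping zero-variance column(s): {list(zero_var)}", stacklevel=2)
        out = out.drop(columns=list(zero_var))
        sd = sd.drop(list(zero_var))
    return (out - out.mean()) / sd


@dataclass(frozen=True)
class GroupEllipse:
    """95% confidence ellipse of a group centroid in a score plane."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation_deg: float
    level: float = 0.95
    n: int = 0


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # components x elements, orthonormal rows
    scores: pd.DataFrame  # locations x components
    explained_variance_ratio: np.ndarray
    ellipses: dict[str, GroupEllipse] = field(default_factory=dict)
    rank_limited: bool = False

    def separating_component(self, groups: pd.Series, group: str) -> int:
        """Index of the component that best separates ``group`` from the rest.

        Separation is the absolute difference of group-mean scores scaled by
        the pooled score SD on that component.
        """
        g = groups.reindex(self.scores.index)
        inside = self.scores[g == group]
        outside = self.scores[g != group]
        sd = self.scores.std(ddof=1).replace(0.0, np.nan)
        sep = ((inside.mean() - outside.mean()) / sd).abs()
        return int(np.nanargmax(sep.to_numpy()))


def _mean_ellipse(points: np.ndarray, level: float = 0.95) -> GroupEllipse:
    """Bivariate-normal confidence ellipse of the mean of ``points`` (n x 2)."""
    n = len(points)
    center = points.mean(axis=0)
    if n < 2:
        return GroupEllipse(center=tuple(center), semi_axes=(0.0, 0.0),
                            orientation_deg=0.0, level=level, n=n)
    cov = np.cov(points, rowvar=False) / n  # covariance of the mean
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    scale = chi2.ppf(level, df=2)
    axes = np.sqrt(scale * evals)
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return GroupEllipse(center=(float(center[0]), float(center[1])),
                        semi_axes=(float(axes[0]), float(axes[1])),
                        orientation_deg=angle, level=level, n=n)


def pca(standardized: pd.DataFrame, groups: pd.Series | None = None,
        level: float = 0.95) -> PcaResult:
    """PCA of a standardized location-mean concentration matrix.

    Eigendecomposition of the covariance of the (already standardized) matrix;
    scores are the projections of the locations, loadings the orthonormal
    element weights. When groups are given, each group receives a 95%
    confidence ellipse of its centroid in the (PC1, PC2) plane, from the
    within-group score covariance scaled by 1/n_group.
    """
    n, p = standardized.shape
    if n < 3:
        raise ValueError("PCA requires >= 3 locations")
    if p < 2:
        raise ValueError("PCA requires >= 2 elements")
    rank_limited = p > n
    if rank_limited:
        warnings.warn(
            f"more elements ({p}) than locations ({n}); rank-limited PCA",
            stacklevel=2,
        )
    model = _SkPCA(n_components=min(n, p))
    score_values = model.fit_transform(standardized.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(score_values.shape[1])]
    loadings = pd.DataFrame(model.components_, index=comp_names,
                            columns=standardized.columns)
    scores = pd.DataFrame(score_values, index=standardized.index, columns=comp_names)
    ellipses: dict[str, GroupEllipse] = {}
    if groups is not None:
        g = groups.reindex(standardized.index)
        for name in g.dropna().unique():
            pts = scores.loc[g == name, ["PC1", "PC2"]].to_numpy()
            ellipses[str(name)] = _mean_ellipse(pts, level=level)
    return PcaResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        ellipses=ellipses,
        rank_limited=rank_limited,
    )


@dataclass
class Dendrogram:
    """Ward merge sequence (scipy linkage convention) with leaf labels.

    Heights follow the square-root convention of Ward's minimal
    sum-of-squares-increase criterion on Euclidean distances: merging two
    singletons a and b happens at height ||a - b|| = sqrt(2 * delta_SSQ).
    """

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Nested-parenthesis text form with merge heights as branch lengths."""
        n = len(self.labels)

        def node(i: int, parent_h: float) -> str:
            if i < n:
                return f"{self.labels[i]}:{parent_h:.6g}"
            row = self.linkage[i - n]
            h = row[2]
            left = node(int(row[0]), h / 2)
            right = node(int(row[1]), h / 2)
            return f"({left},{right}):{max(parent_h - h, 0.0) / 2:.6g}"

        top = len(self.linkage) - 1
        row = self.linkage[top]
        h = row[2]
        return f"({node(int(row[0]), h / 2)},{node(int(row[1]), h / 2)});"


def ward_cluster(standardized: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering by Ward's minimal SSQ-increase criterion.

    Works on Euclidean distances between the standardized rows; each merge is
    the pair of clusters whose union increases the total within-cluster sum of
    squares the least, and heights are reported on the square-root scale (see
    :class:`Dendrogram`).
    """
    if standardized.shape[0] < 2:
        raise ValueError("clustering requires >= 2 rows")
    labels = [str(x) for x in standardized.index]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate row labels")
    linkage = hierarchy.linkage(standardized.to_numpy(), method="ward")
    return Dendrogram(linkage=linkage, labels=labels)
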