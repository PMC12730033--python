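"""Genotype dissimilarity matrices: Mahalanobis D2 and standardized Euclidean.

The generalized Mahalanobis distance between two genotype mean vectors is
D2 = d' W^-1 d, with d the trait-mean difference and W the pooled residual
covariance of *means* (residual covariance divided by the replication k, the
default here, so that the univariate case lands on the ANOVA F scale; the
raw residual covariance is available via ``on_means=False``). The
standardized Euclidean distance operates on trait means scaled to mean 0,
variance 1; the "mean" variant divides the squared distance by the number of
traits before taking the root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PhenotypeTable

__all__ = [
    "DistanceMatrix",
    "PooledCovariance",
    "standardize",
    "pooled_residual_covariance",
    "mahalanobis_d2",
    "standardized_euclidean",
]

#: condition number above which W is treated as numerically singular
COND_LIMIT = 1e10


@dataclass
class DistanceMatrix:
    """Symmetric genotype x genotype dissimilarity matrix."""

    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = (v + v.T) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metric: str = "custom"):
        return cls(list(frame.index.astype(str)), frame.to_numpy(float), metric)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


@dataclass
class PooledCovariance:
    """Pooled within-genotype (residual) covariance across traits, E/df_r."""

    traits: list[str]
    matrix: np.ndarray
    df_r: int
    k: float  #: replicates per genotype, for the means-scale conversion

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        self.matrix = (m + m.T) / 2.0

    @property
    def of_means(self) -> np.ndarray:
        """Residual covariance of genotype means (matrix / k)."""
        return self.matrix / self.k


def standardize(means: pd.DataFrame) -> pd.DataFrame:
    """Scale each trait column to mean 0, variance 1 (sample variance, n-1).

    Raises on constant columns: a zero-variance trait carries no divergence
    information and silently dividing by ~0 would dominate every distance.
    """
    means = means.astype(float)
    sd = means.std(ddof=1)
    bad = sd[(sd == 0) | sd.isna()].index.tolist()
    if bad:
        raise ValueError(f"zero-variance trait column(s): {bad}")
    return (means - means.mean()) / sd


def pooled_residual_covariance(
    table: PhenotypeTable, traits: list[str] | None = None
) -> PooledCovariance:
    """Pooled within-genotype covariance from replicate-level data.

    Sums within-genotype centered cross-products over genotypes and divides
    by the residual degrees of freedom sum_g (k_g - 1). Its diagonal equals
    each trait's residual mean square QMr. Genotype x replicate rows missing
    any requested trait are dropped (complete-case) with a logged count.
    """
    traits = traits if traits is not None else table.traits
    wide = table.data[table.data["trait"].isin(traits)].pivot(
        index=["genotype", "replicate"], columns="trait", values="value"
    )[traits]
    n_before = len(wide)
    wide = wide.dropna()
    dropped = n_before - len(wide)
    if dropped:
        warnings.warn(
            f"pooled covariance: dropped {dropped} incomplete genotype x "
            "replicate row(s)",
            stacklevel=2,
        )
    cross = np.zeros((len(traits), len(traits)))
    df_r = 0
    for _, grp in wide.groupby(level="genotype"):
        if len(grp) < 2:
            continue
        centered = grp.to_numpy(float) - grp.to_numpy(float).mean(axis=0)
        cross += centered.T @ centered
        df_r += len(grp) - 1
    if df_r < 1:
        raise ValueError("no residual degrees of freedom for pooled covariance")
    return PooledCovariance(
        traits=list(traits), matrix=cross / df_r, df_r=df_r, k=table.k
    )


def _inverse(w: np.ndarray) -> np.ndarray:
    if np.linalg.cond(w) > COND_LIMIT:
        warnings.warn(
            "pooled covariance is near-singular; using pseudo-inverse",
            stacklevel=3,
        )
        return np.linalg.pinv(w)
    return np.linalg.inv(w)


def _resolve_w(
    cov: PooledCovariance | np.ndarray, on_means: bool
) -> np.ndarray:
    if isinstance(cov, PooledCovariance):
        return cov.of_means if on_means else cov.matrix
    return np.asarray(cov, float)


def mahalanobis_d2(
    means: pd.DataFrame,
    cov: PooledCovariance | np.ndarray,
    on_means: bool = True,
) -> DistanceMatrix:
    """Generalized Mahalanobis D2 between all genotype mean vectors.

    Parameters
    ----------
    means
        Genotype x trait matrix of replicate means (raw scale; D2 is
        invariant to any nonsingular linear recoding of traits, so
        standardization is unnecessary here).
    cov
        Pooled residual covariance (``PooledCovariance``; divided by k when
        ``on_means``), or a plain weight matrix W used as given.
    """
    w = _resolve_w(cov, on_means)
    x = means.to_numpy(float)
    if w.shape[0] != x.shape[1]:
        raise ValueError("covariance dimension does not match trait count")
    w_inv = _inverse(w)
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, w_inv, diff)
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(
        labels=list(means.index.astype(str)), values=d2, metric="mahalanobis_d2"
    )


def standardized_euclidean(
    means: pd.DataFrame, mean_variant: bool = False
) -> DistanceMatrix:
    """Euclidean distance on standardized trait means.

    With ``mean_variant`` the squared distance is divided by the number of
    traits before the square root (the "standardized mean Euclidean
    distance" of the plant-breeding literature).
    """
    z = standardize(means).to_numpy(float)
    diff = z[:, None, :] - z[None, :, :]
    sq = (diff**2).sum(axis=2)
    if mean_variant:
        sq = sq / z.shape[1]
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        labels=list(means.index.astype(str)),
        values=d,
        metric="std_mean_euclidean" if mean_variant else "std_euclidean",
    )
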