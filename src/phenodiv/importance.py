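"""Relative trait importance: Singh's D2 decomposition and canonical variates.

Singh's criterion decomposes the total generalized Mahalanobis divergence
over all genotype pairs into per-trait components: with difference vector d
and weight matrix W^-1, each pair's D2 = d' W^-1 d splits exactly into
components d_j * (W^-1 d)_j, and the trait totals S_j over all pairs sum to
the total D2 (conservation). With correlated traits individual components can
be negative; they are reported signed here, with percentages over the signed
total, and a warning names the traits concerned (report layers conventionally
floor small negatives to 0 for display).

Canonical variate analysis solves the generalized eigenproblem of the
between-genotype covariance in the metric of the pooled within (residual)
covariance, via the symmetric Cholesky reduction. The leading variates are
the trait combinations that maximally separate genotypes relative to
residual noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import (
    COND_LIMIT,
    PooledCovariance,
    _inverse,
    _resolve_w,
    standardize,
)

__all__ = ["ContributionTable", "CanonicalVariates", "singh_contribution",
           "canonical_variates"]


@dataclass
class ContributionTable:
    """Per-trait absolute (S_j) and percentage contribution to total D2."""

    table: pd.DataFrame  #: columns S_j, percent; index = trait
    total_d2: float  #: sum of D2 over all genotype pairs

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def percent(self, trait: str) -> float:
        return float(self.table.loc[trait, "percent"])

    def display_percent(self, floor_negative: bool = True) -> pd.Series:
        """Percentages for reporting; small negative components floored at 0."""
        p = self.table["percent"].copy()
        if floor_negative:
            p = p.clip(lower=0.0)
        return p


@dataclass
class CanonicalVariates:
    """Eigen-structure of the between/within genotype covariance problem."""

    eigenvalues: np.ndarray  #: descending
    percent: np.ndarray
    cumulative_percent: np.ndarray
    coefficients: pd.DataFrame  #: trait weighting coefficients, one column per variate
    scores: pd.DataFrame  #: genotype scores on each variate

    @property
    def n_for_90pct(self) -> int:
        """Number of leading variates needed to pass 90% cumulative variation."""
        return int(np.searchsorted(self.cumulative_percent, 90.0) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "percent": self.percent,
                "cumulative_percent": self.cumulative_percent,
            },
            index=[f"CV{i + 1}" for i in range(len(self.eigenvalues))],
        )


def singh_contribution(
    means: pd.DataFrame,
    cov: PooledCovariance | np.ndarray,
    on_means: bool = True,
) -> ContributionTable:
    """Singh's relative contribution of each trait to the total divergence.

    Uses the same genotype means and pooled covariance as the D2 matrix;
    S_j = sum over pairs (i < i') of d_j * (W^-1 d)_j, so sum_j S_j equals
    the sum of all pairwise D2 exactly.
    """
    w = _resolve_w(cov, on_means)
    x = means.to_numpy(float)
    traits = list(means.columns)
    if w.shape[0] != len(traits):
        raise ValueError("covariance dimension does not match trait count")
    w_inv = _inverse(w)
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diffs = x[iu] - x[ju]  # (n_pairs, n_traits)
    components = diffs * (diffs @ w_inv)  # d_j * (W^-1 d)_j per pair
    s_j = components.sum(axis=0)
    total = float(s_j.sum())
    if total == 0:
        raise ValueError("total divergence is zero; contributions undefined")
    percent = 100.0 * s_j / total
    negative = [t for t, s in zip(traits, s_j) if s < 0]
    if negative:
        warnings.warn(
            f"negative Singh components for trait(s) {negative} "
            "(correlated traits); reported signed",
            stacklevel=2,
        )
    table = pd.DataFrame({"S_j": s_j, "percent": percent}, index=pd.Index(traits, name="trait"))
    return ContributionTable(table=table, total_d2=total)


def canonical_variates(
    means: pd.DataFrame, cov: PooledCovariance
) -> CanonicalVariates:
    """Canonical variate analysis of genotype means.

    Both matrices are taken to the standardized-mean scale (traits scaled to
    mean 0, variance 1 across genotypes, as is customary before multivariate
    divergence procedures): the between matrix B is the covariance of the
    standardized genotype means and the within matrix W is the pooled
    residual covariance of means rescaled by the same trait SDs. The
    eigenproblem W^-1 B is solved through the symmetric reduction
    L^-1 B L^-T with W = L L^T for numerical stability; eigenvector signs
    follow the convention that the largest-magnitude loading is positive.
    """
    traits = list(means.columns)
    sd = means.std(ddof=1).to_numpy(float)
    if np.any(sd == 0):
        raise ValueError("zero-variance trait; canonical analysis undefined")
    z = standardize(means)
    b = np.cov(z.to_numpy(float), rowvar=False)
    b = np.atleast_2d(b)
    w = cov.of_means / np.outer(sd, sd)
    if np.linalg.cond(w) > COND_LIMIT:
        raise np.linalg.LinAlgError(
            "within-genotype covariance is singular (collinear traits)"
        )
    chol = np.linalg.cholesky(w)
    linv = np.linalg.inv(chol)
    sym = linv @ b @ linv.T
    eigval, u = np.linalg.eigh((sym + sym.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    vectors = linv.T @ u[:, order]
    # sign convention: largest |loading| positive per variate
    for col in range(vectors.shape[1]):
        j = int(np.argmax(np.abs(vectors[:, col])))
        if vectors[j, col] < 0:
            vectors[:, col] *= -1.0
    percent = 100.0 * eigval / eigval.sum()
    cumulative = np.cumsum(percent)
    names = [f"CV{i + 1}" for i in range(len(eigval))]
    coefficients = pd.DataFrame(vectors, index=pd.Index(traits, name="trait"),
                                columns=names)
    scores = pd.DataFrame(
        z.to_numpy(float) @ vectors, index=means.index, columns=names
    )
    return CanonicalVariates(
        eigenvalues=eigval,
        percent=percent,
        cumulative_percent=cumulative,
        coefficients=coefficients,
        scores=scores,
    )
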