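"""Scott-Knott clustering of treatment means.

Partitions the sorted genotype means into non-overlapping homogeneous groups
by recursively choosing, at each node, the contiguous two-way split that
maximizes the between-group sum of squares B0 and testing it with the
likelihood-ratio-style statistic

    lambda = pi / (2 (pi - 2)) * B0 / sigma0_sq

where sigma0_sq = (sum_i (ybar_i - ybar)^2 + df_r * s_ybar^2) / (g + df_r),
s_ybar^2 = QMr / k is the variance of a treatment mean, and lambda is
referred to a chi-square with nu = g / (pi - 2) (fractional) degrees of
freedom. A node splits iff lambda exceeds the chi-square quantile at the
chosen significance level; otherwise it becomes a final group. Because the
search is over contiguous splits of the sorted means, the resulting groups
never interleave, which is what lets them be reported as simple letter codes
('a' for the highest-mean group, 'b' next, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ScottKnottResult", "SplitRecord", "scott_knott", "best_split"]

_PI_FACTOR = math.pi / (2.0 * (math.pi - 2.0))


@dataclass(frozen=True)
class SplitRecord:
    """Diagnostics for one tested node of the recursion."""

    members: tuple[str, ...]  #: genotypes at the node, descending mean order
    split_after: int  #: size of the left (higher-mean) part of the best split
    B0: float
    sigma0_sq: float
    lam: float
    chi2_crit: float
    nu: float
    split: bool


@dataclass
class ScottKnottResult:
    """Letter grouping of genotype means for one trait."""

    trait: str
    means: pd.Series  #: genotype means, descending
    groups: pd.Series  #: letter per genotype, aligned with ``means``
    alpha: float
    splits: list[SplitRecord] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return self.groups.nunique()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "group": self.groups})


def _group_letter(i: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa' (agronomy letter convention)."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("a") + rem) + letters
    return letters


def best_split(means: np.ndarray) -> tuple[int, float]:
    """Maximize B0 over the g-1 contiguous splits of descending-sorted means.

    Returns ``(left_size, B0)``; ties in B0 are broken by the smallest left
    size, for determinism. B0 for a split into parts of sizes k1, k2 is
    T1^2/k1 + T2^2/k2 - (T1+T2)^2/(k1+k2) with T the part totals.
    """
    g = len(means)
    if g < 2:
        raise ValueError("need at least two means to split")
    total = means.sum()
    cum = np.cumsum(means)[:-1]  # left totals for left sizes 1..g-1
    sizes = np.arange(1, g)
    b0 = cum**2 / sizes + (total - cum) ** 2 / (g - sizes) - total**2 / g
    best = int(np.argmax(b0))  # argmax returns the first (smallest) maximizer
    return int(sizes[best]), float(b0[best])


def _partition(
    means: np.ndarray,
    labels: list[str],
    s_ybar_sq: float,
    df_r: int,
    alpha: float,
    records: list[SplitRecord],
) -> list[list[str]]:
    g = len(means)
    if g < 2:
        return [labels]
    left_size, b0 = best_split(means)
    sigma0_sq = (((means - means.mean()) ** 2).sum() + df_r * s_ybar_sq) / (g + df_r)
    lam = _PI_FACTOR * b0 / sigma0_sq if sigma0_sq > 0 else math.inf
    nu = g / (math.pi - 2.0)
    crit = float(stats.chi2.ppf(1.0 - alpha, nu))
    split = bool(lam > crit)
    records.append(
        SplitRecord(
            members=tuple(labels),
            split_after=left_size,
            B0=b0,
            sigma0_sq=sigma0_sq,
            lam=lam,
            chi2_crit=crit,
            nu=nu,
            split=split,
        )
    )
    if not split:
        return [labels]
    left = _partition(
        means[:left_size], labels[:left_size], s_ybar_sq, df_r, alpha, records
    )
    right = _partition(
        means[left_size:], labels[left_size:], s_ybar_sq, df_r, alpha, records
    )
    return left + right


def scott_knott(
    means: pd.Series | dict[str, float],
    QMr: float,
    df_r: int,
    k: float,
    alpha: float = 0.05,
    trait: str = "",
) -> ScottKnottResult:
    """Scott-Knott grouping of per-genotype means.

    Parameters
    ----------
    means
        Genotype -> replicate-mean value for the trait.
    QMr, df_r
        Residual mean square and degrees of freedom from the trait's ANOVA.
    k
        Replicates per genotype; the variance of a mean is QMr/k.
    alpha
        Significance level for each chi-square split test (default 5%).

    Notes
    -----
    Fractional chi-square degrees of freedom g/(pi-2) are used directly —
    rounding them changes split decisions near the threshold. Genotypes tied
    on the mean are ordered by label for reproducibility.
    """
    if QMr < 0:
        raise ValueError("QMr must be non-negative")
    if df_r < 1:
        raise ValueError("df_r must be at least 1")
    means = pd.Series(dict(means) if not isinstance(means, pd.Series) else means)
    means.index = means.index.astype(str)
    # descending means; ties broken by genotype label
    order = sorted(means.index, key=lambda gname: (-means[gname], gname))
    sorted_means = means.loc[order].astype(float)
    records: list[SplitRecord] = []
    groups = _partition(
        sorted_means.to_numpy(),
        list(sorted_means.index),
        QMr / k,
        df_r,
        alpha,
        records,
    )
    letters = pd.Series(index=sorted_means.index, dtype=object)
    for i, members in enumerate(groups):
        letters.loc[members] = _group_letter(i)
    return ScottKnottResult(
        trait=trait, means=sorted_means, groups=letters, alpha=alpha, splits=records
    )
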