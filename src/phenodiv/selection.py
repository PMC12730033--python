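"""Genotype-ideotype distance selection index.

An ideotype is an idealized trait-target vector; genotypes are ranked by
their (weighted) Euclidean distance to it on the standardized-mean scale,
and the closest fraction is selected. By default the ideotype takes, per
trait, the best *observed* genotype mean in the desired direction (the
convention of the plant-breeding selection-index tradition); explicit
targets may override individual traits for ex-ante ideotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import standardize

__all__ = ["IdeotypeSpec", "SelectionResult", "build_ideotype",
           "genotype_ideotype_index"]


@dataclass(frozen=True)
class IdeotypeSpec:
    """Per-trait selection directions, optional targets and weights.

    ``directions`` maps trait -> ``"higher_is_better"`` or
    ``"lower_is_better"``; ``targets`` (raw trait scale) override the
    observed optimum; ``weights`` (>= 0) scale each trait's squared
    deviation, default 1.
    """

    directions: dict[str, str]
    targets: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait, direction in self.directions.items():
            if direction not in {"higher_is_better", "lower_is_better"}:
                raise ValueError(f"bad direction for {trait!r}: {direction}")
        for trait, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for {trait!r}")

    def direction(self, trait: str) -> str:
        try:
            return self.directions[trait]
        except KeyError:
            raise KeyError(f"no selection direction declared for trait {trait!r}")

    def weight(self, trait: str) -> float:
        return float(self.weights.get(trait, 1.0))


@dataclass
class SelectionResult:
    """Ranking of genotypes by distance to the ideotype."""

    distances: pd.Series  #: genotype -> distance, ascending
    n_sel: int
    ideotype_z: pd.Series  #: the standardized ideotype vector

    @property
    def selected(self) -> list[str]:
        return list(self.distances.index[: self.n_sel])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "distance": self.distances,
                "rank": np.arange(1, len(self.distances) + 1),
            }
        )
        frame["selected"] = frame["rank"] <= self.n_sel
        return frame


def build_ideotype(means: pd.DataFrame, spec: IdeotypeSpec) -> pd.Series:
    """The ideotype on the standardized scale of the observed means.

    Per trait: the best observed genotype mean in the declared direction, or
    the explicit target when one is given; either way the value is mapped
    through the same standardization as the genotype means.
    """
    mu = means.mean()
    sd = means.std(ddof=1)
    ideal_raw = {}
    for trait in means.columns:
        if trait in spec.targets:
            ideal_raw[trait] = float(spec.targets[trait])
        elif spec.direction(trait) == "higher_is_better":
            ideal_raw[trait] = float(means[trait].max())
        else:
            ideal_raw[trait] = float(means[trait].min())
    ideal = pd.Series(ideal_raw)[means.columns]
    return (ideal - mu) / sd


def genotype_ideotype_index(
    means: pd.DataFrame,
    spec: IdeotypeSpec,
    n_sel: int | None = None,
    selection_fraction: float = 0.30,
) -> SelectionResult:
    """Rank genotypes by weighted Euclidean distance to the ideotype.

    Distances are computed between standardized genotype mean vectors and
    the standardized ideotype; rows are sorted ascending (rank 1 = closest),
    ties broken by genotype label. ``n_sel`` defaults to
    ``round(selection_fraction * n_genotypes)`` (at least 1).
    """
    z = standardize(means)
    ideal_z = build_ideotype(means, spec)
    w = np.array([spec.weight(t) for t in means.columns], float)
    diff = z.to_numpy(float) - ideal_z.to_numpy(float)
    dist = np.sqrt((w * diff**2).sum(axis=1))
    series = pd.Series(dist, index=z.index.astype(str), name="distance")
    # deterministic ordering: distance, then label
    order = sorted(series.index, key=lambda gname: (series[gname], gname))
    series = series.loc[order]
    if n_sel is None:
        n_sel = max(1, round(selection_fraction * len(series)))
    if not 1 <= n_sel <= len(series):
        raise ValueError("n_sel out of range")
    return SelectionResult(distances=series, n_sel=int(n_sel), ideotype_z=ideal_z)
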