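"""Core data containers for balanced-trial phenotype data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PhenotypeTable"]


@dataclass
class PhenotypeTable:
    """Balanced genotype x replicate x trait observations.

    Wraps a tidy DataFrame with columns ``genotype, replicate, trait, value``
    from a completely randomized design with ``k`` replicates per genotype.
    Missing cells (NaN values) are tolerated on construction and flagged; how
    they are handled is decided per analysis.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"genotype", "replicate", "trait", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(["genotype", "replicate", "trait"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicated genotype/replicate/trait cells"
            )
        if len(self.genotypes) < 2:
            raise ValueError("need at least 2 genotypes")
        if self.k < 2:
            raise ValueError("need at least 2 replicates per genotype")

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "PhenotypeTable":
        """Build from a wide frame: genotype, replicate + one column per trait."""
        tidy = wide.melt(
            id_vars=["genotype", "replicate"], var_name="trait", value_name="value"
        )
        return cls(tidy)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].astype(str).unique())

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.data["trait"]))

    @property
    def k(self) -> int:
        """Replicates per genotype (modal replicate count over all cells)."""
        counts = self.data.groupby(["genotype", "trait"])["value"].size()
        return int(counts.mode().iloc[0])

    def trait_values(self, trait: str, dropna: bool = False) -> pd.DataFrame:
        """Observations for one trait: columns genotype, replicate, value."""
        if trait not in set(self.data["trait"]):
            raise KeyError(f"unknown trait {trait!r}")
        sub = self.data.loc[self.data["trait"] == trait,
                            ["genotype", "replicate", "value"]]
        if dropna:
            sub = sub.dropna(subset=["value"])
        return sub.copy()

    def is_balanced(self, trait: str) -> bool:
        sub = self.trait_values(trait, dropna=True)
        per_gen = sub.groupby("genotype")["value"].size()
        return bool(per_gen.nunique() == 1 and (per_gen >= 2).all())

    def genotype_means(self, traits: list[str] | None = None) -> pd.DataFrame:
        """Genotype x trait matrix of replicate means (NaN cells ignored)."""
        traits = traits if traits is not None else self.traits
        sub = self.data[self.data["trait"].isin(traits)]
        means = (
            sub.pivot_table(
                index="genotype", columns="trait", values="value", aggfunc="mean"
            )
            .reindex(columns=traits)
            .sort_index()
        )
        means.index = means.index.astype(str)
        return means

    def complete_cases(self, traits: list[str] | None = None) -> pd.DataFrame:
        """Genotype x replicate rows complete across the requested traits."""
        traits = traits if traits is not None else self.traits
        wide = self.data[self.data["trait"].isin(traits)].pivot(
            index=["genotype", "replicate"], columns="trait", values="value"
        )[traits]
        return wide.dropna()

    def to_wide(self) -> pd.DataFrame:
        wide = self.data.pivot(
            index=["genotype", "replicate"], columns="trait", values="value"
        )[self.traits]
        return wide.reset_index()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PhenotypeTable({len(self.genotypes)} genotypes x k={self.k} "
            f"replicates, {len(self.traits)} traits)"
        )
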