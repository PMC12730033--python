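"""Model/Results interface for the full phenotypic-diversity analysis.

`DiversityTrial` wraps a balanced genotype x replicate x trait table;
``fit()`` runs the per-trait ANOVA and genetic-parameter estimation and
returns a :class:`DiversityResults` carrying the estimates and exposing the
multivariate stages (Scott-Knott mean grouping, Mahalanobis D2 and
standardized Euclidean divergence, Tocher and UPGMA/Mojena clustering,
Singh trait contributions, canonical variates and genotype-ideotype
selection) as methods, the way a statsmodels results object hangs
post-estimation analyses off the fit.

Typical use::

    trial = DiversityTrial.from_dataframe(tidy_df)
    res = trial.fit()
    print(res.summary())
    res.tocher()                 # Tocher groups on D2
    res.mojena_cut()             # UPGMA dendrogram cut
    res.select(ideotype_spec)    # genotype-ideotype ranking
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import pandas as pd

from . import anova as _anova
from . import cluster as _cluster
from . import distance as _distance
from . import importance as _importance
from . import scottknott as _sk
from . import selection as _selection
from .data import PhenotypeTable

__all__ = ["DiversityTrial", "DiversityResults"]


class DiversityTrial:
    """A balanced completely-randomized diversity trial, ready to fit.

    Parameters
    ----------
    table
        The replicate-level phenotype observations.
    on_missing
        Passed to the per-trait ANOVA: ``"error"`` (strict balance) or
        ``"drop"`` (exclude missing cells with a warning; needed when e.g.
        mean germination time is undefined for a replicate with no
        germination).
    """

    def __init__(self, table: PhenotypeTable, on_missing: str = "error") -> None:
        self.table = table
        self.on_missing = on_missing

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        genotype_col: str = "genotype",
        replicate_col: str = "replicate",
        trait_col: str = "trait",
        value_col: str = "value",
        on_missing: str = "error",
    ) -> "DiversityTrial":
        """Build from a tidy DataFrame, renaming columns as needed."""
        renamed = data.rename(
            columns={
                genotype_col: "genotype",
                replicate_col: "replicate",
                trait_col: "trait",
                value_col: "value",
            }
        )
        return cls(PhenotypeTable(renamed), on_missing=on_missing)

    @classmethod
    def from_wide(cls, wide: pd.DataFrame, on_missing: str = "error"):
        """Build from a wide frame (genotype, replicate + trait columns)."""
        return cls(PhenotypeTable.from_wide(wide), on_missing=on_missing)

    def fit(self, alpha: float = 0.05) -> "DiversityResults":
        """Per-trait ANOVA and genetic parameters over all traits."""
        anovas = {
            trait: _anova.anova_crd(self.table, trait, on_missing=self.on_missing)
            for trait in self.table.traits
        }
        params = {t: _anova.genetic_parameters(a) for t, a in anovas.items()}
        return DiversityResults(
            model=self, alpha=alpha, anovas=anovas, params=params
        )


@dataclass
class DiversityResults:
    """Fitted genetic parameters plus the downstream multivariate analyses."""

    model: DiversityTrial
    alpha: float
    anovas: dict[str, _anova.AnovaResult]
    params: dict[str, _anova.GeneticParameters]

    # ---------------------------------------------------------------- tables
    @cached_property
    def genetic_parameters(self) -> pd.DataFrame:
        """One row per trait: mean squares, significance and estimates."""
        rows = []
        for trait, a in self.anovas.items():
            gp = self.params[trait]
            rows.append(
                {
                    "trait": trait,
                    "QMg": a.QMg,
                    "QMr": a.QMr,
                    "sig": a.significance,
                    "F": a.F,
                    "p": a.p,
                    "grand_mean": a.grand_mean,
                    **gp.as_dict(),
                }
            )
        return pd.DataFrame(rows).set_index("trait")

    @property
    def traits(self) -> list[str]:
        return list(self.anovas)

    @cached_property
    def genotype_means(self) -> pd.DataFrame:
        return self.model.table.genotype_means(self.traits)

    @cached_property
    def pooled_covariance(self) -> _distance.PooledCovariance:
        return _distance.pooled_residual_covariance(self.model.table, self.traits)

    # ------------------------------------------------------------ univariate
    def scott_knott(self, trait: str, alpha: float | None = None) -> _sk.ScottKnottResult:
        """Scott-Knott letter grouping of one trait's genotype means."""
        a = self.anovas[trait]
        means = (
            self.model.table.trait_values(trait, dropna=True)
            .groupby("genotype")["value"]
            .mean()
        )
        return _sk.scott_knott(
            means,
            QMr=a.QMr,
            df_r=a.df_r,
            k=a.k,
            alpha=self.alpha if alpha is None else alpha,
            trait=trait,
        )

    def scott_knott_table(self, alpha: float | None = None) -> pd.DataFrame:
        """Letter groupings for every trait, long format."""
        frames = []
        for trait in self.traits:
            res = self.scott_knott(trait, alpha=alpha)
            frame = res.to_frame().reset_index(names="genotype")
            frame.insert(0, "trait", trait)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    # ---------------------------------------------------------- multivariate
    def distance_matrix(self, metric: str = "mahalanobis_d2") -> _distance.DistanceMatrix:
        """Genotype dissimilarities: ``mahalanobis_d2``, ``std_euclidean``
        or ``std_mean_euclidean``."""
        if metric == "mahalanobis_d2":
            return _distance.mahalanobis_d2(self.genotype_means, self.pooled_covariance)
        if metric == "std_euclidean":
            return _distance.standardized_euclidean(self.genotype_means)
        if metric == "std_mean_euclidean":
            return _distance.standardized_euclidean(
                self.genotype_means, mean_variant=True
            )
        raise ValueError(f"unknown metric {metric!r}")

    def tocher(self, metric: str = "mahalanobis_d2") -> _cluster.TocherGroups:
        return _cluster.tocher(self.distance_matrix(metric))

    def upgma(self, metric: str = "std_euclidean") -> _cluster.MergeTree:
        return _cluster.upgma(self.distance_matrix(metric))

    def mojena_cut(
        self, c: float = 1.25, metric: str = "std_euclidean"
    ) -> _cluster.MojenaCut:
        return _cluster.mojena_cut(self.upgma(metric), c=c)

    def singh_contribution(self) -> _importance.ContributionTable:
        return _importance.singh_contribution(
            self.genotype_means, self.pooled_covariance
        )

    def canonical_variates(self) -> _importance.CanonicalVariates:
        return _importance.canonical_variates(
            self.genotype_means, self.pooled_covariance
        )

    def select(
        self,
        spec: _selection.IdeotypeSpec,
        n_sel: int | None = None,
        selection_fraction: float = 0.30,
    ) -> _selection.SelectionResult:
        return _selection.genotype_ideotype_index(
            self.genotype_means, spec, n_sel=n_sel,
            selection_fraction=selection_fraction,
        )

    # -------------------------------------------------------------- plotting
    def plot_dendrogram(
        self, c: float = 1.25, metric: str = "std_euclidean", ax=None
    ):
        """UPGMA dendrogram with the Mojena cutoff drawn as a dashed line."""
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy

        tree = self.upgma(metric)
        cut = _cluster.mojena_cut(tree, c=c)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        hierarchy.dendrogram(
            tree.linkage, labels=tree.labels, color_threshold=cut.cutoff, ax=ax
        )
        ax.axhline(cut.cutoff, linestyle="--", color="grey")
        ax.set_ylabel(f"fusion height ({metric})")
        ax.set_title(
            f"UPGMA, Mojena cutoff {cut.cutoff:.2f} -> {cut.n_groups} groups"
        )
        return ax

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        """Plain-text per-trait genetic-parameter table (2-decimal display)."""
        gp = self.genetic_parameters
        header = (
            f"{'trait':<8}{'QMg':>12}{'QMr':>12}{'sig':>5}{'h2%':>8}"
            f"{'Ve':>10}{'Vg':>10}{'CVg/CVe':>9}{'CV%':>8}"
        )
        lines = [
            "Phenotypic diversity trial: genetic parameters",
            f"genotypes: {len(self.genotype_means)}   replicates (k): "
            f"{self.model.table.k}   traits: {len(self.traits)}",
            "-" * len(header),
            header,
            "-" * len(header),
        ]
        for trait, row in gp.iterrows():
            lines.append(
                f"{trait:<8}{row.QMg:>12.2f}{row.QMr:>12.2f}{row.sig:>5}"
                f"{row.h2_pct:>8.2f}{row.Ve:>10.2f}{row.Vg:>10.2f}"
                f"{row['CVg/CVe']:>9.2f}{row.CV_pct:>8.2f}"
            )
        lines.append("-" * len(header))
        return "\n".join(lines)
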