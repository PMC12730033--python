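"""One-way CRD ANOVA and genetic-parameter estimators for balanced trials.

The variance decomposition for a completely randomized design with ``g``
genotypes and ``k`` replicates per genotype gives the genotype and residual
mean squares (QMg, QMr). On the scale of treatment means, the classical
moment estimators are

    Vf = QMg / k            (phenotypic variance of genotype means)
    Ve = QMr / k            (environmental variance of genotype means)
    Vg = (QMg - QMr) / k    (genetic variance; truncated at 0)

from which the broad-sense repeatability h2 = Vg / Vf, the genetic and
environmental coefficients of variation CVg = 100*sqrt(Vg)/mean and
CVe = 100*sqrt(QMr)/mean, and their ratio follow. CVe deliberately uses the
residual standard deviation sqrt(QMr), not sqrt(QMr/k): this is the
experiment CV convention of plant-breeding software, and the CVg/CVe ratio is
then algebraically sqrt(Vg)/sqrt(QMr), independent of the grand mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import PhenotypeTable

__all__ = ["AnovaResult", "GeneticParameters", "anova_crd", "genetic_parameters"]


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA summary for a single trait."""

    trait: str
    QMg: float
    QMr: float
    df_g: int
    df_r: int
    F: float
    p: float
    grand_mean: float
    k: float  #: replicates per genotype (mean replication if cells dropped)

    @property
    def significance(self) -> str:
        """Star code: ``**`` p<=0.01, ``*`` 0.01<p<=0.05, ``ns`` otherwise."""
        if self.p <= 0.01:
            return "**"
        if self.p <= 0.05:
            return "*"
        return "ns"


@dataclass(frozen=True)
class GeneticParameters:
    """Genetic-parameter estimates for a single trait (mean scale)."""

    trait: str
    Vf: float
    Ve: float
    Vg: float
    h2_pct: float
    CVg_pct: float
    CVe_pct: float
    ratio: float
    CV_pct: float
    Vg_raw: float  #: untruncated (QMg - QMr)/k, kept for diagnostics

    def as_dict(self) -> dict[str, float]:
        return {
            "Vf": self.Vf,
            "Ve": self.Ve,
            "Vg": self.Vg,
            "h2_pct": self.h2_pct,
            "CVg_pct": self.CVg_pct,
            "CVe_pct": self.CVe_pct,
            "CVg/CVe": self.ratio,
            "CV_pct": self.CV_pct,
        }


def anova_crd(
    table: PhenotypeTable, trait: str, on_missing: str = "error"
) -> AnovaResult:
    """One-way completely-randomized-design ANOVA for one trait.

    Parameters
    ----------
    table
        Replicate-level observations.
    trait
        Trait to analyse.
    on_missing
        ``"error"`` (default) rejects any trait with missing cells or unequal
        replication; ``"drop"`` removes missing cells and computes the exact
        unequal-n one-way ANOVA, with a warning (the genetic-parameter ``k``
        is then the mean replication).

    Raises
    ------
    ValueError
        Unbalanced data under ``on_missing="error"``, fewer than 2 genotypes
        with >= 2 replicates, or zero residual degrees of freedom.
    """
    if on_missing not in {"error", "drop"}:
        raise ValueError("on_missing must be 'error' or 'drop'")
    sub = table.trait_values(trait)
    n_missing = int(sub["value"].isna().sum())
    if n_missing and on_missing == "error":
        raise ValueError(
            f"trait {trait!r} has {n_missing} missing cell(s); design unbalanced "
            "(pass on_missing='drop' to exclude them explicitly)"
        )
    sub = sub.dropna(subset=["value"])
    sizes = sub.groupby("genotype")["value"].size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"genotype(s) {bad} have fewer than 2 replicates for {trait!r}")
    if sizes.nunique() > 1 and on_missing == "error":
        raise ValueError(f"unequal replication for trait {trait!r}: {dict(sizes)}")
    if n_missing:
        warnings.warn(
            f"trait {trait!r}: dropped {n_missing} missing cell(s); "
            "unequal-n one-way ANOVA used",
            stacklevel=2,
        )

    groups = [grp.to_numpy(float) for _, grp in sub.groupby("genotype")["value"]]
    g = len(groups)
    if g < 2:
        raise ValueError("ANOVA needs at least two genotypes")
    n_total = sum(len(x) for x in groups)
    grand = float(sub["value"].mean())
    ssg = float(sum(len(x) * (x.mean() - grand) ** 2 for x in groups))
    sse = float(sum(((x - x.mean()) ** 2).sum() for x in groups))
    df_g = g - 1
    df_r = n_total - g
    if df_r < 1:
        raise ValueError("zero residual degrees of freedom")
    qmg = ssg / df_g
    qmr = sse / df_r
    if qmr > 0:
        f_stat = qmg / qmr
        p = float(stats.f.sf(f_stat, df_g, df_r))
    else:
        f_stat = math.inf if qmg > 0 else 0.0
        p = 0.0 if qmg > 0 else 1.0
    return AnovaResult(
        trait=trait,
        QMg=qmg,
        QMr=qmr,
        df_g=df_g,
        df_r=df_r,
        F=f_stat,
        p=p,
        grand_mean=grand,
        k=n_total / g,
    )


def genetic_parameters(a: AnovaResult, k: float | None = None) -> GeneticParameters:
    """Moment estimators of the genetic parameters from an ANOVA result.

    ``k`` defaults to the replication recorded in ``a``. Negative Vg is
    truncated to 0 before h2, CVg and the ratio are formed (the raw value is
    kept in ``Vg_raw``); h2 is a broad-sense repeatability of genotype means,
    bounded to [0, 100]%.
    """
    k = float(a.k if k is None else k)
    if k < 2:
        raise ValueError("k must be at least 2")
    vf = a.QMg / k
    ve = a.QMr / k
    vg_raw = (a.QMg - a.QMr) / k
    vg = max(0.0, vg_raw)
    h2 = 100.0 * vg / vf if vf > 0 else 0.0
    h2 = min(100.0, max(0.0, h2))
    if a.grand_mean == 0:
        warnings.warn("grand mean is zero; CV terms undefined", stacklevel=2)
        cvg = cve = math.nan
    else:
        cvg = 100.0 * math.sqrt(vg) / abs(a.grand_mean)
        cve = 100.0 * math.sqrt(a.QMr) / abs(a.grand_mean)
    if cve and not math.isnan(cve):
        ratio = cvg / cve
    else:
        ratio = 0.0 if vg == 0 else math.inf
    return GeneticParameters(
        trait=a.trait,
        Vf=vf,
        Ve=ve,
        Vg=vg,
        h2_pct=h2,
        CVg_pct=cvg,
        CVe_pct=cve,
        ratio=ratio,
        CV_pct=cve,
        Vg_raw=vg_raw,
    )


def genetic_parameters_from_mean_squares(
    trait: str, qmg: float, qmr: float, k: float, grand_mean: float = math.nan
) -> GeneticParameters:
    """Genetic parameters directly from published mean squares.

    Convenience path for re-analysing printed ANOVA tables where only QMg,
    QMr and k are available. The grand mean is optional; without it the CV
    terms are NaN but Vf, Ve, Vg, h2 and the CVg/CVe ratio (which does not
    depend on the mean) are still produced — the ratio is computed as
    sqrt(Vg)/sqrt(QMr) in that case.
    """
    k = float(k)
    vf = qmg / k
    ve = qmr / k
    vg_raw = (qmg - qmr) / k
    vg = max(0.0, vg_raw)
    h2 = min(100.0, max(0.0, 100.0 * vg / vf)) if vf > 0 else 0.0
    if math.isnan(grand_mean) or grand_mean == 0:
        cvg = cve = math.nan
    else:
        cvg = 100.0 * math.sqrt(vg) / abs(grand_mean)
        cve = 100.0 * math.sqrt(qmr) / abs(grand_mean)
    ratio = math.sqrt(vg) / math.sqrt(qmr) if qmr > 0 else (0.0 if vg == 0 else math.inf)
    return GeneticParameters(
        trait=trait,
        Vf=vf,
        Ve=ve,
        Vg=vg,
        h2_pct=h2,
        CVg_pct=cvg,
        CVe_pct=cve,
        ratio=ratio,
        CV_pct=cve,
        Vg_raw=vg_raw,
    )


def genetic_parameter_table(
    table: PhenotypeTable,
    traits: list[str] | None = None,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Per-trait ANOVA + genetic parameters, one row per trait.

    Mirrors the layout of a published genetic-parameter table: mean squares
    with significance stars, h2, variance components, CVg/CVe and CV%.
    """
    traits = traits if traits is not None else table.traits
    rows = []
    for trait in traits:
        a = anova_crd(table, trait, on_missing=on_missing)
        gp = genetic_parameters(a)
        rows.append(
            {
                "trait": trait,
                "QMg": a.QMg,
                "QMr": a.QMr,
                "F": a.F,
                "p": a.p,
                "sig": a.significance,
                "grand_mean": a.grand_mean,
                "df_g": a.df_g,
                "df_r": a.df_r,
                "k": a.k,
                **gp.as_dict(),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


__all__ += ["genetic_parameters_from_mean_squares", "genetic_parameter_table"]
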