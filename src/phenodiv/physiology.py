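"""Physical and physiological seed/seedling quality indices.

Implements the classical seed-analysis quantities used in germplasm
characterization trials: thousand-seed weight, final germination percentage,
Maguire's germination speed index (GSI), count-weighted mean germination time
(MGT), seedling biomass density (dry mass per unit length) and the seed vigor
index (germination % x seedling length).

Daily germination counts are *incremental* (seeds newly germinated on that
day), never cumulative; readers validate non-negativity and the bound
``sum(counts) <= seeds_sown``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "GerminationCourse",
    "SeedlingMeasure",
    "SeedLot",
    "thousand_seed_weight",
    "germination_percentage",
    "germination_speed_index",
    "mean_germination_time",
    "biomass_density",
    "seed_vigor_index",
    "germination_traits",
    "seedling_traits",
    "aggregate_replicates",
]

#: default length of the germination test window, in days after sowing
DEFAULT_N_DAYS = 21


@dataclass(frozen=True)
class GerminationCourse:
    """Daily germination counts for one genotype x replicate germination box.

    Parameters
    ----------
    genotype, replicate
        Labels identifying the experimental unit.
    seeds_sown
        Number of seeds placed to germinate (Nt).
    counts
        Mapping ``day -> newly germinated seeds`` with days counted from
        sowing (day 1 is the first possible count). Days with zero new
        germinations may be omitted.
    """

    genotype: str
    replicate: str
    seeds_sown: int
    counts: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seeds_sown <= 0:
            raise ValueError("seeds_sown must be positive")
        for day, count in self.counts.items():
            if int(day) < 1:
                raise ValueError(f"germination day must be >= 1, got {day}")
            if count < 0:
                raise ValueError(f"negative count on day {day}")
        if self.total_germinated > self.seeds_sown:
            raise ValueError(
                f"{self.genotype}/{self.replicate}: germinated "
                f"{self.total_germinated} > seeds sown {self.seeds_sown}"
            )

    @property
    def total_germinated(self) -> int:
        """Ng, the total number of seeds that germinated within the window."""
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class SeedlingMeasure:
    """Seedling length (cm) and dry mass (mg) for one genotype x replicate."""

    genotype: str
    replicate: str
    SL: float
    SDM: float

    def __post_init__(self) -> None:
        if self.SL <= 0:
            raise ValueError("seedling length must be positive")
        if self.SDM < 0:
            raise ValueError("seedling dry mass must be non-negative")


@dataclass(frozen=True)
class SeedLot:
    """A weighed seed sample used for thousand-seed weight determination."""

    genotype: str
    sample_weight_W: float
    sample_count_N: int

    def __post_init__(self) -> None:
        if self.sample_count_N <= 0:
            raise ValueError("sample count N must be positive")
        if self.sample_weight_W <= 0:
            raise ValueError("sample weight W must be positive")


def thousand_seed_weight(lot: SeedLot) -> float:
    """TSW = W * 1000 / N, in grams per thousand seeds."""
    return lot.sample_weight_W * 1000.0 / lot.sample_count_N


def germination_percentage(course: GerminationCourse) -> float:
    """Final germination percentage, G% = 100 * Ng / Nt, in [0, 100]."""
    return 100.0 * course.total_germinated / course.seeds_sown


def germination_speed_index(course: GerminationCourse) -> float:
    """Maguire's germination speed index, GSI = sum_i G_i / N_i.

    ``G_i`` is the number of seeds newly germinated at the count on day
    ``N_i``, days counted from sowing. Faster germination gives larger GSI;
    with no germination the index is 0.
    """
    return float(sum(g / day for day, g in course.counts.items()))


def mean_germination_time(course: GerminationCourse) -> float:
    """Count-weighted mean day of germination, MGT = sum(G_i N_i) / sum(G_i).

    Undefined when no seed germinated; returns NaN in that case (a zero or
    infinite placeholder would bias genotype means downstream) and the caller
    is expected to treat the cell as missing.
    """
    ng = course.total_germinated
    if ng == 0:
        return math.nan
    return float(sum(g * day for day, g in course.counts.items()) / ng)


def biomass_density(m: SeedlingMeasure) -> float:
    """DEN = SDM (mg) / SL (cm), seedling dry mass per unit length."""
    return m.SDM / m.SL


def seed_vigor_index(g_pct: float, sl: float) -> float:
    """SVI = G(%) x SL(cm), Abdul-Baki-style vigor product."""
    return g_pct * sl


def germination_traits(course: GerminationCourse) -> dict[str, float]:
    """All germination-derived traits for one replicate: G%, GSI, MGT."""
    return {
        "G": germination_percentage(course),
        "GSI": germination_speed_index(course),
        "MGT": mean_germination_time(course),
    }


def seedling_traits(m: SeedlingMeasure, g_pct: float) -> dict[str, float]:
    """Seedling-derived traits for one replicate: SL, SDM, DEN, SVI."""
    return {
        "SL": m.SL,
        "SDM": m.SDM,
        "DEN": biomass_density(m),
        "SVI": seed_vigor_index(g_pct, m.SL),
    }


def aggregate_replicates(
    germination: pd.DataFrame | None = None,
    seedlings: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble a tidy replicate-level trait table ready for ANOVA.

    The replicate (not the seed or the seedling) is the experimental unit, so
    no averaging across replicates happens here: the output keeps exactly one
    value per genotype x replicate per derived trait.

    Parameters
    ----------
    germination
        Long table with columns ``genotype, replicate, day, count,
        seeds_sown`` (incremental daily counts).
    seedlings
        Table with columns ``genotype, replicate, SL_cm, SDM_mg``.

    Returns
    -------
    Tidy frame with columns ``genotype, replicate, trait, value``. MGT cells
    with zero germinated seeds come out as NaN with a warning.
    """
    rows: list[dict] = []
    g_pct_lookup: dict[tuple, float] = {}
    n_undefined_mgt = 0
    if germination is not None:
        for (gen, rep), grp in germination.groupby(
            ["genotype", "replicate"], sort=True
        ):
            seeds = int(grp["seeds_sown"].iloc[0])
            counts = {
                int(d): int(c)
                for d, c in zip(grp["day"], grp["count"])
                if int(c) != 0
            }
            course = GerminationCourse(str(gen), str(rep), seeds, counts)
            traits = germination_traits(course)
            g_pct_lookup[(gen, rep)] = traits["G"]
            if math.isnan(traits["MGT"]):
                n_undefined_mgt += 1
            for trait, value in traits.items():
                rows.append(
                    {"genotype": gen, "replicate": rep, "trait": trait, "value": value}
                )
    if seedlings is not None:
        for rec in seedlings.itertuples(index=False):
            m = SeedlingMeasure(
                str(rec.genotype), str(rec.replicate), rec.SL_cm, rec.SDM_mg
            )
            g_pct = g_pct_lookup.get((rec.genotype, rec.replicate), math.nan)
            for trait, value in seedling_traits(m, g_pct).items():
                rows.append(
                    {
                        "genotype": rec.genotype,
                        "replicate": rec.replicate,
                        "trait": trait,
                        "value": value,
                    }
                )
    if n_undefined_mgt:
        warnings.warn(
            f"{n_undefined_mgt} replicate(s) had no germination; their MGT is "
            "recorded as missing and excluded from that trait's ANOVA",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["genotype", "replicate", "trait", "value"])
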