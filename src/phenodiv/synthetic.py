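"""Synthetic balanced-trial and germination-course generator.

Generates data with known ground truth so every downstream stage —
physiology indices, ANOVA and genetic parameters, mean grouping, divergence,
clustering, trait contributions and selection — can be validated without any
field data. The trait model is the additive two-component model underlying
the one-way CRD ANOVA,

    y_ij = mean + g_i + e_ij,   g_i ~ N(0, sigma2_g),  e_ij ~ N(0, sigma2_e)

with both effects normal (the generator's assumption; the estimators
themselves are moment-based and do not require normality). The implied
broad-sense repeatability of genotype means is
h2 = sigma2_g / (sigma2_g + sigma2_e / k).

The germination model draws, per genotype, a germination probability (on the
logit scale, to stay in (0,1)) and a mean germination time; each seed of a
replicate then germinates independently with that probability, on a day
drawn from a normal timing distribution truncated to the test window and
rounded to whole days (minimum day 1). Seeds that do not germinate within
the window are censored and appear in no daily count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import PhenotypeTable

__all__ = [
    "TraitSpec",
    "GerminationModel",
    "SimulationConfig",
    "simulate_trait_table",
    "simulate_germination",
    "ground_truth",
]


@dataclass(frozen=True)
class TraitSpec:
    """Ground-truth parameters for one simulated trait."""

    name: str
    mean: float
    sigma2_g: float  #: genotype variance (trait units squared)
    sigma2_e: float  #: residual variance of one replicate observation
    direction: str = "higher_is_better"

    def __post_init__(self) -> None:
        if self.sigma2_g < 0:
            raise ValueError("sigma2_g must be >= 0")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be > 0")
        if self.direction not in {"higher_is_better", "lower_is_better"}:
            raise ValueError(f"bad direction {self.direction!r}")

    def h2(self, k: int) -> float:
        """Implied broad-sense repeatability of genotype means, in [0, 1)."""
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e / k)


@dataclass(frozen=True)
class GerminationModel:
    """Genotype-level germination probability and timing distributions.

    Defaults mirror a standard 21-day laboratory germination test with 50
    seeds per replicate.
    """

    seeds_per_replicate: int = 50
    n_days: int = 21
    p_germ_mean: float = 0.95
    p_germ_genotype_sd: float = 0.5  #: on the logit scale
    time_mean: float = 6.0  #: days
    time_sd: float = 1.5  #: within-genotype seed-to-seed SD, days
    time_genotype_sd: float = 0.75  #: genotype-to-genotype SD of mean time

    def __post_init__(self) -> None:
        if not 0 < self.p_germ_mean < 1:
            raise ValueError("p_germ_mean must be in (0, 1)")
        if self.n_days < 1 or self.seeds_per_replicate < 1:
            raise ValueError("n_days and seeds_per_replicate must be >= 1")
        if min(self.p_germ_genotype_sd, self.time_sd, self.time_genotype_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Balanced-trial simulation settings (defaults: 20 genotypes x 4 reps)."""

    traits: tuple[TraitSpec, ...]
    n_genotypes: int = 20
    n_replicates: int = 4
    germination: GerminationModel = field(default_factory=GerminationModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        object.__setattr__(self, "traits", tuple(self.traits))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, rng_seed=int(seed))

    @property
    def genotype_labels(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genotypes + 1)]

    @property
    def replicate_labels(self) -> list[str]:
        return [f"R{i}" for i in range(1, self.n_replicates + 1)]


def simulate_trait_table(config: SimulationConfig) -> PhenotypeTable:
    """Draw a balanced genotype x replicate x trait table.

    A single RNG stream seeded from ``config.rng_seed`` drives all draws;
    the same config therefore yields bit-identical tables.
    """
    rng = np.random.default_rng(config.rng_seed)
    g, k = config.n_genotypes, config.n_replicates
    genotypes = config.genotype_labels
    replicates = config.replicate_labels
    frames = []
    for spec in config.traits:
        g_eff = rng.normal(0.0, math.sqrt(spec.sigma2_g), size=g)
        resid = rng.normal(0.0, math.sqrt(spec.sigma2_e), size=(g, k))
        values = spec.mean + g_eff[:, None] + resid
        frames.append(
            pd.DataFrame(
                {
                    "genotype": np.repeat(genotypes, k),
                    "replicate": np.tile(replicates, g),
                    "trait": spec.name,
                    "value": values.ravel(),
                }
            )
        )
    return PhenotypeTable(pd.concat(frames, ignore_index=True))


def _genotype_germination_params(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    m = config.germination
    logit = math.log(m.p_germ_mean / (1.0 - m.p_germ_mean))
    logits = rng.normal(logit, m.p_germ_genotype_sd, size=config.n_genotypes)
    p = 1.0 / (1.0 + np.exp(-logits))
    times = rng.normal(m.time_mean, m.time_genotype_sd, size=config.n_genotypes)
    return p, times


def simulate_germination(config: SimulationConfig) -> pd.DataFrame:
    """Daily germination counts per genotype x replicate.

    Returns a long frame with columns ``genotype, replicate, day, count,
    seeds_sown`` where ``count`` is the number of seeds newly germinated on
    that day (days 1..n_days; zero-count days included so the window is
    explicit). Each seed germinates with the genotype's probability; its day
    is a truncated-normal draw on [0.5, n_days + 0.5] rounded half-up to an
    integer day (so day 0 cannot occur).
    """
    m = config.germination
    rng = np.random.default_rng(config.rng_seed + 1)  # separate stream from traits
    p_g, t_g = _genotype_germination_params(config, rng)
    rows = []
    for gi, genotype in enumerate(config.genotype_labels):
        for replicate in config.replicate_labels:
            germinated = rng.random(m.seeds_per_replicate) < p_g[gi]
            n_germ = int(germinated.sum())
            counts = np.zeros(m.n_days, dtype=int)
            if n_germ:
                if m.time_sd > 0:
                    a = (0.5 - t_g[gi]) / m.time_sd
                    b = (m.n_days + 0.5 - t_g[gi]) / m.time_sd
                    raw = stats.truncnorm.rvs(
                        a, b, loc=t_g[gi], scale=m.time_sd,
                        size=n_germ, random_state=rng,
                    )
                else:
                    raw = np.full(n_germ, min(max(t_g[gi], 1.0), m.n_days))
                days = np.floor(raw + 0.5).astype(int)  # round half-up
                days = np.clip(days, 1, m.n_days)
                for day in days:
                    counts[day - 1] += 1
            for day in range(1, m.n_days + 1):
                rows.append(
                    {
                        "genotype": genotype,
                        "replicate": replicate,
                        "day": day,
                        "count": int(counts[day - 1]),
                        "seeds_sown": m.seeds_per_replicate,
                    }
                )
    return pd.DataFrame(rows)


def ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """Closed-form per-trait truths implied by the TraitSpecs.

    Columns: mean, sigma2_g, sigma2_e, h2_pct, CVg_pct, CVe_pct (CVe on the
    residual-SD convention, matching the estimators).
    """
    k = config.n_replicates
    rows = []
    for spec in config.traits:
        rows.append(
            {
                "trait": spec.name,
                "mean": spec.mean,
                "sigma2_g": spec.sigma2_g,
                "sigma2_e": spec.sigma2_e,
                "h2_pct": 100.0 * spec.h2(k),
                "CVg_pct": 100.0 * math.sqrt(spec.sigma2_g) / abs(spec.mean),
                "CVe_pct": 100.0 * math.sqrt(spec.sigma2_e) / abs(spec.mean),
            }
        )
    return pd.DataFrame(rows).set_index("trait")
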