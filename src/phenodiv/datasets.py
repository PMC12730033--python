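"""Reference values from a published beach-mandacaru diversity trial.

A 20-subpopulation *Cereus fernambucensis* (beach mandacaru) trial in a
completely randomized design with four replicates reported, per trait, the
genotype and residual mean squares (QMg, QMr) and the experiment coefficient
of variation. Those printed values serve two purposes here:

* re-deriving the genetic parameters directly from the published mean
  squares (a worked example of the estimator chain), and
* calibrating the synthetic generator's defaults so simulated trials live
  on the same scale as a real cactus germplasm trial: the residual variance
  is QMr, the genotype variance is (QMg - QMr)/k, and the trait mean is
  recovered from the experiment CV as mean = 100 * sqrt(QMr) / CV%.

Trait codes: PH plant height (cm); CD cladode diameter (cm); NR number of
ribs; FL fruit length (mm); FD fruit diameter (mm); FFM fresh fruit mass
(g); NS seeds per fruit; TSM thousand-seed mass (g); G germination %; GSI
germination speed index; MGT mean germination time (days); SL seedling
length (cm); SDM seedling dry mass (mg); DEN biomass density (mg/cm); SVI
seed vigor index.
"""

from __future__ import annotations

import math

import pandas as pd

from .synthetic import GerminationModel, SimulationConfig, TraitSpec

__all__ = [
    "reference_mean_squares",
    "reference_trait_specs",
    "reference_simulation_config",
]

_K = 4  # replicates in the reference trial

# trait: (QMg, QMr, CV%, direction)
_TABLE = {
    "PH": (856.78, 303.77, 25.12, "higher_is_better"),
    "CD": (0.78, 0.86, 18.87, "higher_is_better"),
    "NR": (0.30, 0.10, 8.54, "higher_is_better"),
    "FL": (136.38, 66.76, 18.58, "higher_is_better"),
    "FD": (30.45, 20.66, 16.27, "higher_is_better"),
    "FFM": (118.85, 116.73, 54.76, "higher_is_better"),
    "NS": (46075.81, 23251.43, 52.03, "higher_is_better"),
    "TSM": (0.07, 0.007, 6.02, "higher_is_better"),
    "G": (19.42, 8.59, 3.08, "higher_is_better"),
    "GSI": (2.70, 0.15, 4.81, "higher_is_better"),
    "MGT": (2.37, 0.09, 5.00, "lower_is_better"),
    "SL": (0.08, 0.01, 8.13, "higher_is_better"),
    "SDM": (0.08, 0.01, 11.74, "higher_is_better"),
    "DEN": (0.04, 0.01, 14.45, "higher_is_better"),
    "SVI": (544.28, 78.64, 7.32, "higher_is_better"),
}


def reference_mean_squares() -> pd.DataFrame:
    """Published per-trait mean squares: columns QMg, QMr, CV_pct, k."""
    frame = pd.DataFrame(
        [
            {"trait": t, "QMg": qmg, "QMr": qmr, "CV_pct": cv, "k": _K}
            for t, (qmg, qmr, cv, _) in _TABLE.items()
        ]
    ).set_index("trait")
    return frame


def reference_trait_specs() -> tuple[TraitSpec, ...]:
    """TraitSpecs calibrated to the reference trial's printed statistics."""
    specs = []
    for trait, (qmg, qmr, cv, direction) in _TABLE.items():
        mean = 100.0 * math.sqrt(qmr) / cv
        specs.append(
            TraitSpec(
                name=trait,
                mean=mean,
                sigma2_g=max(0.0, (qmg - qmr) / _K),
                sigma2_e=qmr,
                direction=direction,
            )
        )
    return tuple(specs)


def reference_simulation_config(rng_seed: int = 0) -> SimulationConfig:
    """The default simulated trial: 20 genotypes x 4 replicates, 15 traits,
    50-seed 21-day germination boxes — the reference trial's dimensions."""
    return SimulationConfig(
        traits=reference_trait_specs(),
        n_genotypes=20,
        n_replicates=4,
        germination=GerminationModel(),
        rng_seed=rng_seed,
    )
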