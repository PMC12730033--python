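import numpy as np
import pandas as pd
import pytest

from phenodiv import PhenotypeTable, SimulationConfig, TraitSpec, simulate_trait_table
from phenodiv.datasets import reference_simulation_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table(rng) -> PhenotypeTable:
    """A 6-genotype x 3-replicate x 3-trait balanced table with signal."""
    genotypes = [f"g{i}" for i in range(1, 7)]
    rows = []
    for trait, (mu, sg, se) in {
        "A": (10.0, 4.0, 1.0),
        "B": (50.0, 0.5, 2.0),
        "C": (5.0, 1.0, 0.5),
    }.items():
        effects = rng.normal(0, np.sqrt(sg), size=len(genotypes))
        for gi, gen in enumerate(genotypes):
            for rep in ("r1", "r2", "r3"):
                rows.append(
                    {
                        "genotype": gen,
                        "replicate": rep,
                        "trait": trait,
                        "value": mu + effects[gi] + rng.normal(0, np.sqrt(se)),
                    }
                )
    return PhenotypeTable(pd.DataFrame(rows))


@pytest.fixture
def trial_config() -> SimulationConfig:
    return reference_simulation_config(rng_seed=42)


@pytest.fixture
def trial_table(trial_config) -> PhenotypeTable:
    return simulate_trait_table(trial_config)


def random_means(rng, n_genotypes: int, n_traits: int) -> pd.DataFrame:
    return pd.DataFrame(
        rng.normal(size=(n_genotypes, n_traits)),
        index=[f"g{i}" for i in range(n_genotypes)],
        columns=[f"t{j}" for j in range(n_traits)],
    )
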