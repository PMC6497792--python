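import numpy as np
import pandas as pd
import pytest

import phenoscreen as ps


def long_frame(values: dict, trait: str = "t1") -> pd.DataFrame:
    """Build a long-format frame from {(genotype, environment): [reps]}."""
    rows = []
    for (genotype, environment), reps in values.items():
        for i, value in enumerate(reps, start=1):
            rows.append(
                {
                    "genotype": genotype,
                    "environment": environment,
                    "replicate": i,
                    "trait": trait,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_2x2x2():
    """The hand-computed 2-genotype x 2-environment x 2-replicate table.

    Known decomposition: SS_genotype=32, SS_environment=2,
    SS_interaction=0, SS_residual=8.
    """
    frame = long_frame(
        {
            ("G1", "non_stressed"): [1, 3],
            ("G1", "stressed"): [2, 4],
            ("G2", "non_stressed"): [5, 7],
            ("G2", "stressed"): [6, 8],
        }
    )
    return ps.phenotype_table_from_frame(frame)


@pytest.fixture(scope="session")
def study_population():
    """A full synthetic 16 x 2 x 3 population over the default 24 traits."""
    return ps.simulate_population(ps.default_catalogue(), g=16, s=2, r=3, seed=20260929)


def random_balanced_table(rng: np.random.Generator, g=None, s=2, r=None):
    """A random balanced table for oracle-equivalence checks."""
    g = g or int(rng.integers(2, 7))
    r = r or int(rng.integers(2, 5))
    envs = ["non_stressed", "stressed"][:s]
    values = {
        (f"G{i}", env): rng.normal(10, 3, size=r).tolist()
        for i in range(g)
        for env in envs
    }
    return ps.phenotype_table_from_frame(long_frame(values))
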