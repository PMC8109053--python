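import numpy as np
import pandas as pd
import pytest

from mqtlnet.containers import AbundanceMatrix
from mqtlnet.simulate import (CovariateEffect, PlantedModule, PlantedQTL,
                              SimulationConfig, generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with a planted QTL, module and outlier, reused
    across read-only tests."""
    cfg = SimulationConfig(
        n_subjects=400,
        n_metabolites=40,
        n_snps=120,
        n_rundays=6,
        missing_rate=0.03,
        n_outlier_subjects=1,
        planted_qtls=[PlantedQTL(0, 0, 0.3, 0.3)],
        planted_modules=[PlantedModule((10, 11, 12), 0.5, "fev1pp", 0.25)],
        covariate_effects={"age": CovariateEffect(0.25, 0.5)},
        seed=42,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def plain_matrix():
    """Tiny hand-checkable abundance matrix, single run day, no missing."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.lognormal(2.0, 0.5, (20, 5)),
        index=[f"S{i}" for i in range(20)],
        columns=[f"M{j}" for j in range(5)],
    )
    runday = pd.Series("D0", index=vals.index)
    return AbundanceMatrix(vals, runday, stage="raw")


def transformed_from(values: pd.DataFrame) -> AbundanceMatrix:
    """Wrap already-normal values as a transformed-stage matrix."""
    runday = pd.Series("D0", index=values.index)
    return AbundanceMatrix(values, runday, stage="transformed")
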