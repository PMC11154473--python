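import numpy as np
import pandas as pd
import pytest

from survbias import CohortTable, build_default_schema, generate_cohort
from survbias.cohort import CohortSchema, FeatureSpec


@pytest.fixture(scope="session")
def default_schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def small_cohort(default_schema):
    """Default-schema cohort, small enough for fast model fits."""
    return generate_cohort(default_schema, n=600, seed=11)


@pytest.fixture(scope="session")
def null_schema(default_schema):
    """Default schema with every outcome effect removed (labels independent of features)."""
    return default_schema.with_effects({})


@pytest.fixture(scope="session")
def signal_schema(default_schema):
    """All MDD signal concentrated in perturbable survey features, dominated by drinker_3."""
    return default_schema.with_effects({
        ("MDD", "drinker_3"): 1.2,
        ("MDD", "cigarette_smoker_5"): 0.6,
        ("MDD", "financial_difficulties"): 0.5,
        ("MDD", "binge_drinking"): 0.5,
        ("GAD", "binge_drinking"): 0.5,
    })


@pytest.fixture()
def separator_table():
    """Tiny hand-built cohort whose single continuous feature perfectly separates MDD."""
    rng = np.random.default_rng(0)
    y = (rng.random(200) < 0.3).astype(int)
    schema = CohortSchema(
        features=(FeatureSpec("marker", "continuous", mean=0.0, sd=1.0),),
        outcome_names=("MDD",),
        prevalence_targets={"MDD": 0.3},
    )
    df = pd.DataFrame({"marker": np.where(y == 1, 10.0, -10.0) + rng.normal(0, 0.1, 200),
                       "MDD": y})
    return CohortTable(df, schema)
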