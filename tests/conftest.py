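import numpy as np
import pandas as pd
import pytest

from kmosar.curation import curate
from kmosar.synthetic import PlantedSARSpec, generate_activity_table


@pytest.fixture(scope="session")
def planted_data():
    """Default 137-compound synthetic table with injected curation work."""
    return generate_activity_table(PlantedSARSpec(seed=11))


@pytest.fixture(scope="session")
def curated_records(planted_data):
    records, _ = curate(planted_data.table)
    return records


@pytest.fixture(scope="session")
def small_records():
    """A 60-compound curated set for the heavier model-fitting tests."""
    data = generate_activity_table(
        PlantedSARSpec(n_compounds=60, seed=5, duplicate_fraction=0, missing_fraction=0)
    )
    records, _ = curate(data.table)
    return records


@pytest.fixture(scope="session")
def rf_fixture():
    """A seeded random forest on 8 informative-ish features, for explainers."""
    from sklearn.ensemble import RandomForestClassifier

    rng = np.random.default_rng(7)
    X = rng.normal(size=(80, 8))
    y = (X[:, 0] + 0.7 * X[:, 1] - X[:, 2] + rng.normal(0, 0.6, 80) > 0).astype(int)
    model = RandomForestClassifier(n_estimators=25, random_state=0).fit(X, y)
    cols = [f"d{i}" for i in range(8)]
    return model, pd.DataFrame(X, columns=cols), y
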