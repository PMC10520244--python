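import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pcube
from pcube.cohort import CohortTable, FeatureSchema

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cohort(times, events, X=None, feature_names=None, cat=None):
    """Hand-rolled cohort: continuous matrix X plus optional categoricals."""
    n = len(times)
    df = pd.DataFrame(
        {"patient_id": [f"p{i}" for i in range(n)], "time": times, "event": events}
    )
    cont = []
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        feature_names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        for j, f in enumerate(feature_names):
            df[f] = X[:, j]
        cont = list(feature_names)
    cats = []
    if cat:
        for f, vals in cat.items():
            df[f] = vals
            cats.append(f)
    return CohortTable(df, FeatureSchema(tuple(cont), tuple(cats)))


@pytest.fixture(scope="session")
def preset_cohort():
    """Moderate synthetic registry draw shared across read-only tests."""
    return pcube.simulate_cohort(pcube.default_preset(n=800, seed=42))


@pytest.fixture(scope="session")
def preset_encoded(preset_cohort):
    spec = pcube.fit_encoding(preset_cohort)
    return spec, pcube.transform(preset_cohort, spec)
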