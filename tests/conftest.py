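import numpy as np
import pandas as pd
import pytest

from stepselect.preprocessing import FeatureTable
from stepselect.synthetic import (
    FeatureSpec,
    SyntheticSpec,
    generate_cohort,
    study_spec,
)


def small_spec(seed=0, n=120, n_features=4, signal=None, **kwargs):
    """A minimal cohort spec for fast model-fitting tests."""
    feats = tuple(FeatureSpec(f"x{i}") for i in range(n_features))
    coefs = {} if signal is None else dict(signal)
    kwargs = {"step_mean_base": 4300.0, "step_noise_sd": 1500.0, **kwargs}
    return SyntheticSpec(
        n_participants=n,
        feature_specs=feats,
        true_coefficients=coefs,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def small_cohort():
    return generate_cohort(small_spec(seed=7, signal={"x0": 1800.0}))


@pytest.fixture
def study_cohort():
    """Default study-condition cohort: n=268, 25 features, 2 planted signals."""
    return generate_cohort(study_spec(seed=42))


@pytest.fixture
def toy_table():
    data = pd.DataFrame(
        {"a": [2.0, 4.0, 6.0], "b": [3.0, 3.0, 3.0], "c": [1.0, 0.0, 2.0]},
        index=pd.Index(["p1", "p2", "p3"], name="id"),
    )
    return FeatureTable(data=data)


def scaled_design(cohort, threshold=2500.0):
    """Filter, min-max scale and label a cohort (global-scaler path)."""
    from stepselect import preprocessing as prep

    table, _ = prep.filter_missing(cohort.features)
    table = prep.apply_minmax(table, prep.fit_minmax(table))
    labels = np.asarray(prep.label_threshold(cohort.aspd_observed, threshold))
    return table, labels
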