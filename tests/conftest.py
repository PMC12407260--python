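import numpy as np
import pandas as pd
import pytest

import goldbioage as g


@pytest.fixture(scope="session")
def light_cohort():
    """The coefficient-recovery cohort: published clock ratios as truth."""
    config = g.make_light_truth(0.09, n=20_000, seed=0)
    return g.simulate_cohort(config), config


@pytest.fixture(scope="session")
def light_models(light_cohort):
    """Age-only model and constrained age+biomarker model on the same cohort."""
    cohort, _ = light_cohort
    model1 = g.fit(cohort, [])
    model2 = g.fit(cohort, cohort.biomarker_names, fixed_beta_age=model1.beta_age)
    return model1, model2


@pytest.fixture(scope="session")
def derived_clock(light_cohort, light_models):
    cohort, _ = light_cohort
    model1, model2 = light_models
    return g.derive_clock(model1, model2, cohort)


@pytest.fixture
def tiny_cohort():
    """Five hand-written subjects with one biomarker."""
    return g.Cohort(
        age=np.array([50.0, 60.0, 70.0, 55.0, 65.0]),
        biomarkers=pd.DataFrame({"bm": [1.0, -0.5, 0.3, 2.0, 0.0]}),
        time=np.array([5.0, 2.0, 8.0, 1.0, 10.0]),
        event=np.array([1, 0, 1, 1, 0]),
    )
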