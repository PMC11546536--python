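import numpy as np
import pytest
from hypothesis import settings

import hybridec as h

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture
def toy_csv(tmp_path):
    """Six-subject hybrid trial table: 4 trial subjects (2 treated), 2 external."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "y,a,d,x1\n"
        "2.0,1,1,0.5\n"
        "4.0,1,1,1.5\n"
        "1.0,0,1,0.0\n"
        "2.0,0,1,1.0\n"
        "0.5,0,0,0.2\n"
        "1.5,0,0,1.2\n"
    )
    return path


@pytest.fixture
def micro_data():
    """Hand-built 6-subject dataset: 2 treated, 2 internal controls, 2 external."""
    return h.HybridTrialData(
        y=[3.0, 5.0, 1.0, 2.0, 0.5, 1.5],
        a=[1, 1, 0, 0, 0, 0],
        d=[1, 1, 1, 1, 0, 0],
        x=np.array([[0.5], [1.5], [0.0], [1.0], [0.2], [1.2]]),
        covariate_names=["x1"],
        pi_a_design=2.0 / 3.0,
    )


@pytest.fixture
def micro_fits(micro_data):
    """Fixed nuisance values for the micro dataset (no fitting involved)."""
    n = micro_data.n
    return h.NuisanceFits(
        m1=np.array([3.2, 4.8, 2.1, 3.0, 2.2, 3.1]),
        m0=np.array([1.1, 2.2, 0.9, 1.8, 0.6, 1.6]),
        pi_d=np.array([0.7, 0.8, 0.6, 0.7, 0.4, 0.5]),
        pi_a=np.full(n, 2.0 / 3.0),
        r=np.full(n, 1.0),
        fold_id=np.zeros(n, dtype=int),
        learner_spec=h.LearnerSpec(),
    )


@pytest.fixture(scope="session")
def linear_data():
    """One realistic linear-truth hybrid trial draw (n = 200)."""
    return h.simulate_trial(h.setting_config(1, tau=1.0), seed=42)


@pytest.fixture(scope="session")
def linear_fits(linear_data):
    return h.fit_nuisances(linear_data, spec=h.setting_spec(1), k_folds=10, seed=42)
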