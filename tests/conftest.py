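import numpy as np
import pytest

from lipact import (
    ExchangeParams,
    FretParams,
    LogisticStageParams,
    NoiseSpec,
    TwoStageParams,
    paper_activity_design,
    paper_fret_design,
    simulate_activity,
    simulate_fret,
)

# published global-fit estimates used as generating truth throughout
TRUTH = TwoStageParams(
    stage2=LogisticStageParams(a0=1.1, a1=12.8, theta05=0.16, c_theta=15.0),
    stage1=ExchangeParams(k_ex=1.4, beta=2),
)
TRUTH_XI = 51.0


@pytest.fixture(scope="session")
def truth():
    return TRUTH


@pytest.fixture(scope="session")
def fret_truth():
    return FretParams(TRUTH_XI, TRUTH.stage1)


@pytest.fixture(scope="session")
def noise_free_data(truth, fret_truth):
    """Exact-model activity and FRET datasets on the published designs."""
    designs = paper_activity_design()
    act = simulate_activity(truth, designs, NoiseSpec(0.0, 0.0, seed=0))
    fret = simulate_fret(fret_truth, paper_fret_design(), NoiseSpec(0.0, 0.0, seed=0))
    return act, fret


@pytest.fixture()
def noisy_data(truth, fret_truth):
    """One seeded noisy realization of the published designs."""
    rng = np.random.default_rng(42)
    noise = NoiseSpec(0.5, 0.02, seed=42)
    act = simulate_activity(truth, paper_activity_design(), noise, rng=rng)
    fret = simulate_fret(fret_truth, paper_fret_design(), noise, rng=rng)
    return act, fret
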