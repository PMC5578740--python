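import numpy as np
import pytest

from statevar.deconvolution import FIRDeconvolver, build_fir_design
from statevar.synthetic import (
    GainGroundTruth,
    generate_session,
    generate_state_patterns,
    make_task_design,
)
from statevar.states import COMPONENTS


@pytest.fixture(scope="session")
def design():
    return make_task_design(seed=0)


@pytest.fixture(scope="session")
def patterns_and_mask():
    return generate_state_patterns(300, seed=1)


@pytest.fixture(scope="session")
def patterns(patterns_and_mask):
    return patterns_and_mask[0]


@pytest.fixture(scope="session")
def mask(patterns_and_mask):
    return patterns_and_mask[1]


@pytest.fixture(scope="session")
def noise_free_truth():
    return GainGroundTruth(
        gain_sd={c: 0.0 for c in COMPONENTS},
        noise_sd=1e-10,
        drift_sd=0.0,
        motion_coupling=0.0,
        p_incorrect=0.0,
    )


@pytest.fixture(scope="session")
def session_default(design, patterns):
    return generate_session(design, patterns, GainGroundTruth(), seed=7)


@pytest.fixture(scope="session")
def deconvolved_default(design, session_default):
    fir = build_fir_design(
        session_default.trials, design.n_tr_per_run, design.n_runs,
        motion=session_default.motion,
    )
    return FIRDeconvolver().fit(session_default.bold, fir), fir


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
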