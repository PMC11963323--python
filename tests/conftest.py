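import numpy as np
import pytest

from placebomatch.pipeline import RunConfig, run_fit
from placebomatch.synthetic import ForwardModel, generate_library

#: trimmed competition settings: full mechanics, small grids, one repeat —
#: keeps the non-acceptance suite fast without gating anything
FAST_GRIDS = {
    "linear": {},
    "ridge": {"alpha": [1.0]},
    "svr": {"C": [100.0], "epsilon": [0.1]},
    "random_forest": {"n_estimators": [100]},
    "gradient_boosting": {"n_estimators": [100], "max_depth": [2]},
}


@pytest.fixture(scope="session")
def default_library():
    """The canonical 323-sample simulated library at the default seed."""
    fwd = ForwardModel(noise_sd=2.0, seed=42)
    return generate_library(fwd, n=323, seed=42)


@pytest.fixture(scope="session")
def small_pipeline():
    """A quickly fitted pipeline (200 samples, trimmed grids) for
    persistence, attribution and CLI tests."""
    lib = generate_library(ForwardModel(noise_sd=2.0, seed=1), n=200, seed=1)
    cfg = RunConfig(
        seed=1,
        folds=5,
        repeats=1,
        grids=FAST_GRIDS,
        families=("linear", "ridge", "random_forest"),
    )
    return run_fit(lib, cfg), lib, cfg
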