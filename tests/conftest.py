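import numpy as np
import pytest

from ctgformer import (
    CohortSpec,
    SimulationParams,
    clean_channels,
    scale_unit,
    simulate_cohort,
    windows_to_arrays,
    windowize,
)


@pytest.fixture(scope="session")
def tiny_model_kwargs():
    """Small transformer configuration used across training tests."""
    return dict(
        n_layers=1, n_heads=2, d_model=32, d_ff=16,
        patch_len=16, stride=16, dropout=0.1, fc_dropout=0.1,
        attn_dropout=0.1,
    )


@pytest.fixture(scope="session")
def separable_windows():
    """A strongly separable synthetic cohort as model-ready arrays."""
    params = SimulationParams(adverse_effect=0.3, missing_rate=0.05)
    traces, _ = simulate_cohort(CohortSpec(60, 60, seed=11), params)
    windows = []
    for t in traces:
        windows.extend(windowize(scale_unit(clean_channels(t))))
    return windows_to_arrays(windows)


@pytest.fixture(scope="session")
def cohort_metadata():
    """Metadata table of a confounded cohort (no signal arrays needed)."""
    params = SimulationParams(missing_rate=0.0)
    _, meta = simulate_cohort(CohortSpec(80, 40, seed=5), params)
    return meta
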