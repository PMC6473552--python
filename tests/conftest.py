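import numpy as np
import pytest
from hypothesis import settings

import stratdesign as sd
from stratdesign import presets

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def full_spec():
    return sd.RegressionSpec.full(2, 2)


@pytest.fixture(scope="session")
def catalogue():
    return sd.contrast_catalogue(2, 2)


@pytest.fixture(scope="session")
def theta_confirmatory():
    return presets.theta_confirmatory()


@pytest.fixture(scope="session")
def first_illustration(full_spec):
    """Reduced model, contrasts, exclusions and weights of the worked example."""
    selected = presets.selected_contrasts()
    support = sd.support_for_selection(selected, 2, 2)
    reduced = sd.reduce_model(selected, support, full_spec)
    reduced_contrasts = [sd.express_in(c, reduced) for c in selected]
    support_idx = {pt.index for pt in support}
    exclusions = [pt.index for pt in sd.enumerate_support(2, 2)
                  if pt.index not in support_idx]
    problem = sd.DesignProblem(reduced, reduced_contrasts,
                               weights=presets.SELECTED_WEIGHTS,
                               exclusions=exclusions)
    return {"selected": selected, "support": support, "reduced": reduced,
            "reduced_contrasts": reduced_contrasts, "problem": problem}


@pytest.fixture(scope="session")
def solved_design(first_illustration):
    return first_illustration["problem"].solve(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
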