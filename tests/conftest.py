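import numpy as np
import pytest

import ivimfun as iv


@pytest.fixture(scope="session")
def scheme() -> iv.AcquisitionScheme:
    return iv.AcquisitionScheme.default()


@pytest.fixture(scope="session")
def gm_truth() -> iv.IVIMParameters:
    """Rounded gray-matter baseline truth used by the simulations."""
    return iv.IVIMParameters(f=0.04, D=0.7e-3, Dstar=17e-3)


@pytest.fixture(scope="session")
def tiny_spec() -> iv.PhantomSpec:
    """Small but fully populated phantom for fast end-to-end tests."""
    return iv.PhantomSpec(
        shape=(32, 32), brain_radius=14, gm_ribbon_width=4, visual_extent=7,
        n_subjects=4, blocks_per_condition=2, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_spec) -> iv.SyntheticStudy:
    return iv.simulate_study(tiny_spec)


def make_noisy_stack(params, scheme, shape, sigma, rng):
    """Image stack (rows, cols, n_b) of one tissue with i.i.d. Gaussian noise."""
    clean = iv.ivim_signal(params, scheme.b_values)
    stack = clean[None, None, :] + rng.normal(0.0, sigma, (*shape, scheme.n_b))
    return np.clip(stack, 1e-6, None)
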