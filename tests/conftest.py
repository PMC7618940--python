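import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_hsmm_truth():
    """A short HSMM dataset shared across tests (3 states, 8 channels)."""
    from modemix import simulate

    return simulate.simulate_hsmm_dataset(
        n_states=3, n_channels=8, n_samples=4000, seed=7
    )


def finite_difference(fn, tensor, n_probe=15, eps=1e-6, seed=0):
    """Central finite-difference gradient of scalar fn() w.r.t. a Tensor.

    Probes up to ``n_probe`` randomly chosen entries and returns pairs of
    (numeric, analytic) gradient values; fn must rebuild the graph on each
    call and the tensor must already hold its analytic gradient.
    """
    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(
        tensor.value.size, size=min(n_probe, tensor.value.size), replace=False
    )
    pairs = []
    for k in flat_idx:
        idx = np.unravel_index(k, tensor.value.shape)
        orig = tensor.value[idx]
        tensor.value[idx] = orig + eps
        f1 = float(fn().value)
        tensor.value[idx] = orig - eps
        f2 = float(fn().value)
        tensor.value[idx] = orig
        pairs.append(((f1 - f2) / (2 * eps), tensor.grad[idx]))
    return np.asarray(pairs)
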