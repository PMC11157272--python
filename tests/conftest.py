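import numpy as np
import pytest

from crafruk import simulate


@pytest.fixture
def titration_set():
    """Ten depleting-model curves at the default study conditions (2% noise)."""
    curves, truth = simulate.gen_titration(simulate.TitrationSimSpec(seed=11))
    return curves, truth


@pytest.fixture
def noiseless_curves():
    spec = simulate.TitrationSimSpec(seed=3, n_curves=3, noise_sd=0.0)
    curves, truth = simulate.gen_titration(spec)
    return curves, truth, spec


@pytest.fixture
def afm_sheet():
    """Noisy AFM measurement sheet with true-mass labels attached."""
    spec = simulate.AfmSimSpec(seed=7, noise_cv=0.05, n_peaks=80)
    return simulate.gen_afm_peaks(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
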