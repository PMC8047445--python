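import pytest

from slimbind.synth import gen_cpmg, gen_titration, wt_like_exchange_params


@pytest.fixture(scope="session")
def wt_titration():
    """Noisy titration planted with the wild-type-like Kd."""
    series, truth = gen_titration(kd=124.0, seed=11)
    return series, truth


@pytest.fixture(scope="session")
def wt_cpmg_dataset():
    """Two-field, 10-residue dispersion dataset, wild-type-like exchange."""
    params = wt_like_exchange_params(p_b=0.024, k_off=515.0)
    dataset, truth = gen_cpmg(params, seed=21)
    return dataset, truth


@pytest.fixture(scope="session")
def noiseless_cpmg_dataset():
    params = wt_like_exchange_params(p_b=0.03, k_off=700.0, n_residues=4)
    dataset, truth = gen_cpmg(params, intensity_noise_sd=0.0, seed=0)
    return dataset, truth
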