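import math

import pytest

import combonet as cn


@pytest.fixture(scope="session")
def default_design():
    return cn.make_study_design(seed=1)


@pytest.fixture(scope="session")
def truth(default_design):
    return cn.generate_ground_truth(default_design, n_edges=16, n_diffs=3, seed=2)


@pytest.fixture(scope="session")
def noiseless_data(truth, default_design):
    responses, viability = cn.simulate_dataset(
        truth, default_design, noise_sd=0.0, viability_noise_sd=0.0, replicates=2, seed=3
    )
    return responses, viability


@pytest.fixture(scope="session")
def noisy_data(truth, default_design):
    responses, viability = cn.simulate_dataset(
        truth, default_design, noise_sd=0.05, viability_noise_sd=0.03, replicates=3, seed=4
    )
    return responses, viability


@pytest.fixture(scope="session")
def fitted_model(noiseless_data, truth):
    responses, _ = noiseless_data
    return cn.final_model(responses, truth.edges(), theta=0.01, drug_target_map=truth.target_map)


@pytest.fixture(scope="session")
def shared_model(noiseless_data, truth):
    """Reference model with differences forbidden (theta = inf)."""
    responses, _ = noiseless_data
    return cn.final_model(
        responses, truth.edges(), theta=math.inf, drug_target_map=truth.target_map
    )


@pytest.fixture(scope="session")
def tiny_design():
    return cn.make_study_design(
        nodes=["MEK1", "ERK1", "AKT1"],
        drugs=["MEKi", "ERKi", "AKTi"],
        combo_count=3,
        single_dose_drug=None,
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_design):
    return cn.generate_ground_truth(
        tiny_design, n_edges=3, n_diffs=1, seed=6, expand_mek_children=False
    )


@pytest.fixture(scope="session")
def tiny_noisy(tiny_truth, tiny_design):
    responses, viability = cn.simulate_dataset(
        tiny_truth, tiny_design, noise_sd=0.05, viability_noise_sd=0.02, seed=7
    )
    return responses, viability
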