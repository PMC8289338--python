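import pytest
from hypothesis import settings

from isoselect import datasets, simulate_isolation_a, simulate_isolation_b
from isoselect.model_a import cake_void_volume

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

EXPERIMENTS = list(datasets.EXPERIMENT_NAMES)


@pytest.fixture(scope="session")
def experiments():
    return {name: datasets.experiment(name) for name in EXPERIMENTS}


@pytest.fixture(scope="session")
def model_a_results(experiments):
    out = {}
    for name, exp in experiments.items():
        out[name] = simulate_isolation_a(
            exp.feed, exp.porosity, exp.wash_spec(), exp.curves(), exp.cryst_solvent
        )
    return out


@pytest.fixture(scope="session")
def model_b_results(experiments):
    out = {}
    for name, exp in experiments.items():
        result, outcome = simulate_isolation_b(
            exp.feed,
            exp.filtration_setup(),
            exp.dispersion_setup(),
            exp.cryst_solvent,
            exp.curves(),
        )
        out[name] = (result, outcome)
    return out


@pytest.fixture(scope="session")
def void_volumes(experiments):
    return {
        name: cake_void_volume(exp.feed, exp.porosity)
        for name, exp in experiments.items()
    }
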