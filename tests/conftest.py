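import pytest

from anoxmet.stoichiometry import default_registry
from anoxmet.synthetic_data import (
    FermentationModel,
    nag_microcosm_model,
    simulate_nag_experiment,
)
from anoxmet.turnover import TimeFrame


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def frames():
    return [TimeFrame(0, 4), TimeFrame(4, 10), TimeFrame(0, 10)]


def all_pools_measured(model: FermentationModel) -> FermentationModel:
    """Make every pool observable (turns truth into the measured series)."""
    return FermentationModel(
        reactions=model.reactions,
        initial_concentrations=model.initial_concentrations,
        endogenous_co2_rate=model.endogenous_co2_rate,
        unmeasured_sink_fraction=model.unmeasured_sink_fraction,
        noise_sd=model.noise_sd,
        measured_analytes=frozenset(model.compounds()),
    )


@pytest.fixture(scope="session")
def noiseless_experiment():
    """All four arms, no noise, no sink, every pool measured."""
    model = all_pools_measured(nag_microcosm_model(sink_fraction=0.0, noise_sd=0.0))
    series, designs, outputs = simulate_nag_experiment(7, model=model)
    return model, series, designs, outputs
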