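"""The balanced kinetic simulator: conservation, succession, determinism."""

import io

import numpy as np
import pytest

from anoxmet.gasflux import chamber_flux
from anoxmet.stoichiometry import check_reaction_balance
from anoxmet.synthetic_data import (
    FermentationModel,
    SimulationError,
    default_reaction_library,
    nag_experiment_designs,
    nag_microcosm_model,
    nag_primary_only_model,
    simulate_chamber,
    simulate_microcosm,
    simulate_nag_experiment,
)
from anoxmet.turnover import TimeFrame, TreatmentDesign, net_turnover_table, recovery_ratio

from conftest import all_pools_measured


def test_library_reactions_are_balanced():
    library = default_reaction_library()
    assert len(library) >= 6
    for kr in library:
        assert check_reaction_balance(kr.reaction).balanced, kr.name


def test_methanogenic_reactions_are_bes_sensitive():
    for kr in default_reaction_library():
        produces_ch4 = any(c.name == "CH4" for c in kr.reaction.products)
        if produces_ch4:
            assert kr.bes_sensitive, kr.name


def test_primary_fermentation_routes_8_carbon_32_electrons():
    """One NAG carries 8 C and 32 e; its products carry exactly the same."""
    kr = next(r for r in default_reaction_library() if r.name == "nag_fermentation")
    consumed_c = sum(v * c.carbon_factor for c, v in kr.reaction.reactants.items())
    consumed_e = sum(v * c.reductant_factor for c, v in kr.reaction.reactants.items())
    produced_c = sum(v * c.carbon_factor for c, v in kr.reaction.products.items())
    produced_e = sum(v * c.reductant_factor for c, v in kr.reaction.products.items())
    assert (consumed_c, consumed_e) == (8, 32)
    assert (produced_c, produced_e) == (8, 32)


def test_bes_design_produces_no_methane(noiseless_experiment):
    _, _, _, outputs = noiseless_experiment
    assert (outputs["nag_bes"].truth["CH4"] == 0).all()
    assert (outputs["control_bes"].truth["CH4"] == 0).all()


def test_truth_conserves_carbon_and_electrons(noiseless_experiment):
    model, _, _, outputs = noiseless_experiment
    for tid, output in outputs.items():
        drift_c, drift_e = output.conservation_drift(model.compounds())
        assert drift_c < 1e-6, tid
        assert drift_e < 1e-6, tid


def test_conservation_with_sink_routed_to_unmeasured_pool():
    model = all_pools_measured(nag_microcosm_model(sink_fraction=0.3, noise_sd=0.0))
    design = nag_experiment_designs()["nag"]
    output = simulate_microcosm(model, design, seed=0)
    drift_c, drift_e = output.conservation_drift(model.compounds())
    assert drift_c < 1e-6 and drift_e < 1e-6
    assert output.truth["unmeasured_C"].iloc[-1] > 0


def test_qualitative_succession(noiseless_experiment):
    """NAG gone by day 4; transient formate/ethanol maxima; CH4 monotone."""
    _, _, _, outputs = noiseless_experiment
    truth = outputs["nag"].truth
    assert truth.loc[4.0, "NAG"] < 1.0
    for analyte in ("formate", "ethanol"):
        peak_day = truth[analyte].idxmax()
        assert peak_day < 4.0, analyte
        assert truth.loc[10.0, analyte] < truth[analyte].max()
    ch4 = truth["CH4"].to_numpy()
    assert np.all(np.diff(ch4) >= -1e-9)
    assert ch4[-1] > 0


def test_bes_enlarges_transient_formate_and_ethanol_pools(noiseless_experiment):
    _, _, _, outputs = noiseless_experiment
    for analyte in ("formate", "ethanol"):
        assert (
            outputs["nag_bes"].truth[analyte].max()
            > outputs["nag"].truth[analyte].max()
        ), analyte


@pytest.mark.parametrize("basis", ["carbon", "reductant"])
def test_recovery_decreases_strictly_with_sink_fraction(registry, basis):
    frame = TimeFrame(0, 10)
    recoveries = []
    for s in (0.0, 0.2, 0.4, 0.6):
        model = nag_primary_only_model(sink_fraction=s)
        series, designs, _ = simulate_nag_experiment(11, model=model)
        table = net_turnover_table(series, designs, "nag", [frame], registry)
        recoveries.append(recovery_ratio(table, frame, basis).percent)
    assert all(a > b for a, b in zip(recoveries, recoveries[1:]))
    assert recoveries[0] == pytest.approx(100.0, abs=1e-6)


def test_seeded_reproducibility_is_byte_identical():
    model = nag_microcosm_model(noise_sd=10.0)
    design = nag_experiment_designs()["nag"]

    def serialize(seed):
        out = simulate_microcosm(model, design, seed=seed)
        buf = io.StringIO()
        out.series.frame.to_csv(buf, index=False)
        return buf.getvalue()

    assert serialize(42) == serialize(42)
    assert serialize(42) != serialize(43)


def test_noise_is_truncated_at_zero():
    model = nag_microcosm_model(noise_sd=50.0)
    design = nag_experiment_designs()["control"]
    out = simulate_microcosm(model, design, seed=5)
    assert (out.series.frame["concentration_uM"] >= 0).all()


def test_negative_excursion_raises_not_clips(registry):
    """A reaction draining a co-substrate that runs out must fail loudly."""
    library = default_reaction_library()
    acetogenesis = next(r for r in library if r.name == "hydrogenotrophic_acetogenesis")
    fast = FermentationModel(
        reactions=(
            type(acetogenesis)(
                acetogenesis.reaction, 50.0, "H2", acetogenesis.bes_sensitive, 0.0
            ),
        ),
        initial_concentrations={"H2": 10000.0, "CO2": 10.0, "H2O": 1e6},
    )
    with pytest.raises(SimulationError, match="CO2"):
        simulate_microcosm(fast, TreatmentDesign("t"), duration=5.0, sampling_days=[0, 5], seed=0)


def test_supplement_must_be_a_model_pool():
    model = nag_primary_only_model()
    design = TreatmentDesign("t", supplement=("butyrate", 100.0))
    with pytest.raises(KeyError, match="butyrate"):
        simulate_microcosm(model, design, seed=0)


# --- chamber simulator ----------------------------------------------------


def test_chamber_simulator_is_inverse_of_estimator():
    series = simulate_chamber(123.4, volume_m3=0.05, area_m2=0.25, noise_sd=0.0)
    est = chamber_flux(series)
    assert est.flux_umol_m2_h == pytest.approx(123.4, rel=1e-12)


def test_chamber_simulator_zero_flux_is_flat():
    series = simulate_chamber(0.0, volume_m3=0.05, area_m2=0.25, noise_sd=0.0,
                              baseline_ppmv=411.0)
    assert series.ppmv == (411.0,) * 4


def test_chamber_simulator_seeded_determinism():
    a = simulate_chamber(50.0, volume_m3=0.05, area_m2=0.25, noise_sd=5.0, seed=9)
    b = simulate_chamber(50.0, volume_m3=0.05, area_m2=0.25, noise_sd=5.0, seed=9)
    assert a == b


def test_chamber_simulator_rejects_bad_geometry():
    with pytest.raises(ValueError):
        simulate_chamber(1.0, volume_m3=-0.05, area_m2=0.25)
    with pytest.raises(ValueError, match="timepoints"):
        simulate_chamber(1.0, volume_m3=0.05, area_m2=0.25, timepoints=[0.0])
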