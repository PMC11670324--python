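"""Frame differencing, control subtraction and recovery statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from anoxmet.turnover import (
    Delta,
    NetTurnoverTable,
    SlurryTimeSeries,
    TimeFrame,
    TreatmentDesign,
    control_subtract,
    frame_delta,
    net_turnover_table,
    product_fraction,
    recovery_ratio,
    to_carbon_reductant,
)


def series_from(rows):
    return SlurryTimeSeries.from_records(rows)


@pytest.fixture
def simple_series():
    rows = []
    for rep in ("r1", "r2"):
        for day in (0, 4, 10):
            rows.append(("t", rep, day, "flat", 100.0))
    rows += [
        ("t", "r1", 0, "acetate", 0.0),
        ("t", "r2", 0, "acetate", 0.0),
        ("t", "r1", 4, "acetate", 100.0),
        ("t", "r2", 4, "acetate", 120.0),
        ("t", "r1", 10, "acetate", 150.0),
        ("t", "r2", 10, "acetate", 170.0),
    ]
    return series_from(rows)


def test_series_rejects_duplicate_keys():
    with pytest.raises(ValueError, match="duplicate"):
        series_from([("t", "r1", 0, "a", 1.0), ("t", "r1", 0, "a", 2.0)])


def test_series_rejects_negative_concentration():
    with pytest.raises(ValueError, match="negative"):
        series_from([("t", "r1", 0, "a", -1.0)])


def test_timeframe_requires_order():
    with pytest.raises(ValueError):
        TimeFrame(4, 4)


def test_frame_delta_constant_series_is_zero(simple_series):
    d = frame_delta(simple_series, "t", TimeFrame(0, 10), "flat")
    assert d.value == 0.0
    assert d.se == 0.0


def test_frame_delta_mean_first(simple_series):
    d = frame_delta(simple_series, "t", TimeFrame(0, 4), "acetate")
    assert d.value == pytest.approx(110.0)
    # SE of the day-4 mean: sd([100,120])/sqrt(2) = 10; day-0 SE = 0.
    assert d.se == pytest.approx(10.0)


def test_frame_delta_policies_agree_on_mean(simple_series):
    a = frame_delta(simple_series, "t", TimeFrame(0, 10), "acetate")
    b = frame_delta(simple_series, "t", TimeFrame(0, 10), "acetate",
                    replicate_policy="per-replicate")
    assert a.value == pytest.approx(b.value)


def test_frame_delta_interpolates_missing_boundary(simple_series, caplog):
    with caplog.at_level("WARNING", logger="anoxmet.turnover"):
        d = frame_delta(simple_series, "t", TimeFrame(0, 7), "acetate")
    # midpoint of day 4 (110 mean) and day 10 (160 mean)
    assert d.value == pytest.approx(135.0)
    assert any("interpolated" in r.message for r in caplog.records)


def test_frame_delta_exact_mode_rejects_missing_day(simple_series):
    with pytest.raises(ValueError, match="day 7"):
        frame_delta(simple_series, "t", TimeFrame(0, 7), "acetate", interpolate=False)


def test_frame_delta_rejects_day_outside_range(simple_series):
    with pytest.raises(ValueError, match="outside"):
        frame_delta(simple_series, "t", TimeFrame(0, 12), "acetate")


def test_frame_delta_rejects_unknown_analyte(simple_series):
    with pytest.raises(ValueError, match="absent"):
        frame_delta(simple_series, "t", TimeFrame(0, 4), "butyrate")


def test_frame_additivity(simple_series):
    d1 = frame_delta(simple_series, "t", TimeFrame(0, 4), "acetate")
    d2 = frame_delta(simple_series, "t", TimeFrame(4, 10), "acetate")
    d3 = frame_delta(simple_series, "t", TimeFrame(0, 10), "acetate")
    assert d1.value + d2.value == pytest.approx(d3.value)


def test_control_subtract_identity_and_quadrature():
    x = Delta(37.5, 3.0)
    assert control_subtract(x, x).value == 0.0
    net = control_subtract(Delta(500.0, 3.0), Delta(100.0, 4.0))
    assert net.value == pytest.approx(400.0)
    assert net.se == pytest.approx(5.0)


def test_to_carbon_reductant(registry):
    assert to_carbon_reductant(-500.0, registry["NAG"]) == (-4000.0, -16000.0)
    assert to_carbon_reductant(100.0, registry["CO2"]) == (100.0, 0.0)
    assert to_carbon_reductant(0.0, registry["ethanol"]) == (0.0, 0.0)


# --- recovery / product fraction on a hand-built table --------------------


def table_from(rows):
    frame = pd.DataFrame(
        rows,
        columns=["frame_start", "frame_end", "analyte", "delta_uM", "se_uM"],
    )
    # factor arithmetic done by hand per analyte below
    factors = {"NAG": (8, 32), "acetate": (2, 8), "ethanol": (2, 12),
               "formate": (1, 2), "CO2": (1, 0)}
    frame["carbon_uM"] = [d * factors[a][0] for a, d in zip(frame["analyte"], frame["delta_uM"])]
    frame["reductant_uM"] = [d * factors[a][1] for a, d in zip(frame["analyte"], frame["delta_uM"])]
    return NetTurnoverTable(frame)


@pytest.fixture
def closed_carbon_table():
    # consumed 100 NAG = 800 uM-C; products carry 400+200+100+100 = 800 uM-C
    return table_from(
        [
            (0, 4, "NAG", -100.0, 0.0),
            (0, 4, "acetate", 200.0, 0.0),
            (0, 4, "ethanol", 100.0, 0.0),
            (0, 4, "formate", 100.0, 0.0),
            (0, 4, "CO2", 100.0, 0.0),
        ]
    )


def test_recovery_closed_budget_is_100(closed_carbon_table):
    result = recovery_ratio(closed_carbon_table, TimeFrame(0, 4), "carbon")
    assert result.defined
    assert result.percent == pytest.approx(100.0)
    assert not result.exceeds_100


def test_recovery_half_products_is_50():
    table = table_from(
        [
            (0, 4, "NAG", -100.0, 0.0),
            (0, 4, "acetate", 100.0, 0.0),
            (0, 4, "ethanol", 50.0, 0.0),
            (0, 4, "formate", 50.0, 0.0),
            (0, 4, "CO2", 50.0, 0.0),
        ]
    )
    assert recovery_ratio(table, TimeFrame(0, 4), "carbon").percent == pytest.approx(50.0)


def test_recovery_undefined_without_consumption():
    table = table_from([(0, 4, "acetate", 10.0, 0.0)])
    result = recovery_ratio(table, TimeFrame(0, 4), "carbon")
    assert not result.defined
    assert math.isnan(result.percent)


def test_recovery_over_100_is_reported_not_clipped():
    table = table_from([(0, 4, "NAG", -10.0, 0.0), (0, 4, "acetate", 100.0, 0.0)])
    result = recovery_ratio(table, TimeFrame(0, 4), "carbon")
    assert result.percent == pytest.approx(250.0)
    assert result.exceeds_100


def test_product_fraction(closed_carbon_table):
    frame = TimeFrame(0, 4)
    acetate = product_fraction(closed_carbon_table, frame, "acetate", "carbon")
    assert acetate.percent == pytest.approx(50.0)  # 400 of 800 uM-C
    assert product_fraction(closed_carbon_table, frame, "NAG", "carbon").percent == 0.0
    assert product_fraction(closed_carbon_table, frame, "butyrate", "carbon").percent == 0.0


def test_product_fraction_single_product():
    table = table_from([(0, 4, "NAG", -10.0, 0.0), (0, 4, "acetate", 10.0, 0.0)])
    assert product_fraction(table, TimeFrame(0, 4), "acetate", "carbon").percent == 100.0


def test_product_fraction_undefined_without_production():
    table = table_from([(0, 4, "NAG", -10.0, 0.0)])
    assert not product_fraction(table, TimeFrame(0, 4), "acetate", "carbon").defined


# --- design-level contracts ------------------------------------------------


def test_bes_mismatch_is_rejected(registry):
    series = series_from(
        [("t", "r1", d, "acetate", v) for d, v in ((0, 0.0), (10, 10.0))]
        + [("c", "r1", d, "acetate", 0.0) for d in (0, 10)]
    )
    designs = {
        "t": TreatmentDesign("t", supplement=("NAG", 500.0), bes=True, control_id="c"),
        "c": TreatmentDesign("c", bes=False),
    }
    with pytest.raises(ValueError, match="BES mismatch"):
        net_turnover_table(series, designs, "t", [TimeFrame(0, 10)], registry)


def test_missing_analyte_counts_as_zero_turnover(registry, caplog):
    series = series_from(
        [("t", "r1", d, "acetate", v) for d, v in ((0, 0.0), (10, 10.0))]
        + [("t", "r1", d, "CH4", v) for d, v in ((0, 0.0), (10, 5.0))]
        + [("c", "r1", d, "acetate", 0.0) for d in (0, 10)]
    )
    designs = {
        "t": TreatmentDesign("t", supplement=("NAG", 500.0), control_id="c"),
        "c": TreatmentDesign("c"),
    }
    with caplog.at_level("INFO", logger="anoxmet.turnover"):
        table = net_turnover_table(series, designs, "t", [TimeFrame(0, 10)], registry)
    ch4 = table.frame.loc[table.frame["analyte"] == "CH4", "delta_uM"].iloc[0]
    assert ch4 == pytest.approx(5.0)  # control lacks CH4 -> control delta 0
    assert any("missing" in r.message for r in caplog.records)


def test_sign_coherence_of_net_turnover_table(noiseless_experiment, registry, frames):
    """delta, carbon and reductant columns agree in sign compound-wise."""
    _, series, designs, _ = noiseless_experiment
    table = net_turnover_table(series, designs, "nag", frames, registry)
    for _, row in table.frame.iterrows():
        compound = registry[row["analyte"]]
        assert row["carbon_uM"] == pytest.approx(row["delta_uM"] * compound.carbon_factor)
        assert row["reductant_uM"] == pytest.approx(row["delta_uM"] * compound.reductant_factor)
        if compound.carbon_factor > 0:
            assert np.sign(row["carbon_uM"]) == np.sign(row["delta_uM"])
        if compound.reductant_factor == 0:
            assert row["reductant_uM"] == 0.0
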