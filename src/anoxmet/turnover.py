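"""Net carbon and reductant turnover accounting for microcosm time series.

Implements the budget-closure pipeline for replicated anoxic slurry
incubations: within a time frame, the change in each analyte's concentration
is computed (final minus initial, replicates averaged first), the matched
unsupplemented control is subtracted — controls with and without the
methanogenesis inhibitor BES are paired with treatments of the same BES
status — and the resulting net turnover (μM; positive = net production) is
converted to carbon (μM-C) and electron-equivalent (μM-e) units using each
compound's carbon and degree-of-reduction factors. Recovery (closure)
statistics then ask: what percentage of the carbon or electrons released by
net-consumed compounds reappears in net-produced ones?
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stoichiometry import Compound, carbon_reductant_factors

__all__ = [
    "TimeFrame",
    "TreatmentDesign",
    "SlurryTimeSeries",
    "Delta",
    "NetTurnoverTable",
    "RecoveryResult",
    "frame_delta",
    "control_subtract",
    "to_carbon_reductant",
    "net_turnover_table",
    "recovery_ratio",
    "product_fraction",
]

logger = logging.getLogger(__name__)

SERIES_COLUMNS = ["treatment", "replicate", "day", "analyte", "concentration_uM"]


@dataclass(frozen=True)
class TimeFrame:
    """A closed incubation interval [t_start, t_end] in days."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"t_start must be < t_end, got [{self.t_start}, {self.t_end}]")

    def __str__(self) -> str:
        def fmt(x: float) -> str:
            return f"{int(x)}" if float(x).is_integer() else f"{x:g}"

        return f"{fmt(self.t_start)}-{fmt(self.t_end)}"


@dataclass(frozen=True)
class TreatmentDesign:
    """One microcosm treatment and its matched control.

    ``supplement`` is the added substrate as ``(compound_name, amount_uM)``
    or None for unsupplemented controls. The control must share the
    treatment's BES status (BES-inhibited treatments are compared against
    BES-inhibited controls); a control maps to itself.
    """

    treatment_id: str
    supplement: tuple[str, float] | None = None
    bes: bool = False
    preincubation_days: int = 0
    control_id: str | None = None

    def __post_init__(self) -> None:
        if self.preincubation_days < 0:
            raise ValueError("preincubation_days must be >= 0")
        if self.control_id is None:
            object.__setattr__(self, "control_id", self.treatment_id)


class SlurryTimeSeries:
    """Replicated concentration measurements over incubation time.

    Wraps a long-format table with columns treatment, replicate, day,
    analyte, concentration_uM (all concentrations per litre of slurry).
    Validation rejects duplicate (treatment, replicate, day, analyte) keys
    and negative concentrations.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in SERIES_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"series is missing columns {missing}")
        df = frame.loc[:, SERIES_COLUMNS].copy()
        df["day"] = pd.to_numeric(df["day"])
        df["concentration_uM"] = pd.to_numeric(df["concentration_uM"])
        if (df["day"] < 0).any():
            bad = df.index[df["day"] < 0].tolist()
            raise ValueError(f"negative days at rows {bad}")
        if (df["concentration_uM"] < 0).any():
            bad = df.index[df["concentration_uM"] < 0].tolist()
            raise ValueError(f"negative concentrations at rows {bad}")
        keys = ["treatment", "replicate", "day", "analyte"]
        dup = df.duplicated(subset=keys)
        if dup.any():
            raise ValueError(
                f"duplicate (treatment, replicate, day, analyte) keys at rows {df.index[dup].tolist()}"
            )
        self.frame = df.sort_values(["treatment", "replicate", "analyte", "day"]).reset_index(
            drop=True
        )

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "SlurryTimeSeries":
        return cls(pd.DataFrame(list(records), columns=SERIES_COLUMNS))

    @property
    def treatments(self) -> list[str]:
        return sorted(self.frame["treatment"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self.frame["analyte"].unique())

    def analytes_of(self, treatment: str) -> list[str]:
        mask = self.frame["treatment"] == treatment
        return sorted(self.frame.loc[mask, "analyte"].unique())

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SlurryTimeSeries) and self.frame.equals(other.frame)


@dataclass(frozen=True)
class Delta:
    """A concentration change in μM with its standard error."""

    value: float
    se: float = 0.0


def _value_at_day(
    sub: pd.DataFrame, day: float, *, interpolate: bool, tol: float, context: str
) -> tuple[float, bool]:
    """Concentration of one replicate/analyte at a day, interpolating if allowed.

    Returns (value, was_interpolated).
    """
    days = sub["day"].to_numpy(dtype=float)
    conc = sub["concentration_uM"].to_numpy(dtype=float)
    exact = np.flatnonzero(np.abs(days - day) <= tol)
    if exact.size:
        return float(conc[exact[0]]), False
    if not interpolate:
        raise ValueError(f"day {day} not sampled for {context} (exact-match mode)")
    if day < days.min() or day > days.max():
        raise ValueError(
            f"day {day} outside sampled range [{days.min():g}, {days.max():g}] for {context}"
        )
    return float(np.interp(day, days, conc)), True


def frame_delta(
    series: SlurryTimeSeries,
    treatment: str,
    frame: TimeFrame,
    analyte: str,
    *,
    replicate_policy: str = "mean-first",
    interpolate: bool = True,
    day_tolerance: float = 1e-9,
) -> Delta:
    """Concentration change of an analyte over a time frame (final − initial).

    With the default ``"mean-first"`` policy, replicates are averaged at each
    frame endpoint and the means are differenced; standard errors of the two
    endpoint means are combined in quadrature. The ``"per-replicate"`` policy
    differences each replicate first and reports mean and SE of the
    replicate-level deltas (the two policies give identical means but
    different SEs when replicate identity carries shared structure).

    If a frame boundary was not a sampling day, the value is linearly
    interpolated between the bracketing samples per replicate and a warning
    is logged; pass ``interpolate=False`` to require exact sampling days.
    """
    if replicate_policy not in ("mean-first", "per-replicate"):
        raise ValueError(f"unknown replicate_policy {replicate_policy!r}")
    df = series.frame
    sub = df[(df["treatment"] == treatment) & (df["analyte"] == analyte)]
    if sub.empty:
        raise ValueError(f"analyte {analyte!r} absent for treatment {treatment!r}")

    endpoint_values: dict[float, list[float]] = {frame.t_start: [], frame.t_end: []}
    interpolated = False
    for replicate, rep_df in sub.groupby("replicate"):
        for day in (frame.t_start, frame.t_end):
            value, interp = _value_at_day(
                rep_df,
                day,
                interpolate=interpolate,
                tol=day_tolerance,
                context=f"{treatment}/{replicate}/{analyte}",
            )
            endpoint_values[day].append(value)
            interpolated |= interp
    if interpolated:
        logger.warning(
            "frame %s endpoint(s) interpolated for %s/%s", frame, treatment, analyte
        )

    start = np.asarray(endpoint_values[frame.t_start], dtype=float)
    end = np.asarray(endpoint_values[frame.t_end], dtype=float)
    if replicate_policy == "mean-first":
        delta = float(end.mean() - start.mean())
        se = math.hypot(_sem(start), _sem(end))
    else:
        deltas = end - start
        delta = float(deltas.mean())
        se = _sem(deltas)
    return Delta(delta, se)


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def control_subtract(treatment_delta: Delta, control_delta: Delta) -> Delta:
    """Net turnover: treatment change minus matched-control change.

    Removes the endogenous (background) turnover shared with the
    unsupplemented control; SEs combine in quadrature. BES matching between
    treatment and control is enforced upstream via :class:`TreatmentDesign`.
    """
    return Delta(
        treatment_delta.value - control_delta.value,
        math.hypot(treatment_delta.se, control_delta.se),
    )


def to_carbon_reductant(net_uM: float, compound: Compound) -> tuple[float, float]:
    """Convert a net turnover in μM to (μM carbon, μM electron equivalents)."""
    c, e = carbon_reductant_factors(compound)
    return net_uM * c, net_uM * e


class NetTurnoverTable:
    """Per-frame, per-compound net turnover in μM, μM-C and μM-e.

    Positive values are net production, negative net consumption. The three
    unit columns always agree in sign compound-wise (zero-factor columns are
    exactly zero). Carries provenance (treatment, control, replicate policy)
    for reporting.
    """

    COLUMNS = [
        "frame_start",
        "frame_end",
        "analyte",
        "delta_uM",
        "se_uM",
        "carbon_uM",
        "reductant_uM",
    ]

    def __init__(self, frame: pd.DataFrame, provenance: Mapping[str, object] | None = None):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"turnover table missing columns {missing}")
        self.frame = frame.loc[:, self.COLUMNS].reset_index(drop=True)
        self.provenance = dict(provenance or {})

    def frames(self) -> list[TimeFrame]:
        pairs = self.frame[["frame_start", "frame_end"]].drop_duplicates().to_numpy()
        return [TimeFrame(a, b) for a, b in pairs]

    def for_frame(self, frame: TimeFrame) -> pd.DataFrame:
        mask = (self.frame["frame_start"] == frame.t_start) & (
            self.frame["frame_end"] == frame.t_end
        )
        sub = self.frame[mask]
        if sub.empty:
            raise KeyError(f"frame {frame} not present in table")
        return sub


def net_turnover_table(
    series: SlurryTimeSeries,
    designs: Mapping[str, TreatmentDesign],
    treatment_id: str,
    frames: Sequence[TimeFrame],
    registry: Mapping[str, Compound],
    *,
    analytes: Sequence[str] | None = None,
    replicate_policy: str = "mean-first",
    interpolate: bool = True,
) -> NetTurnoverTable:
    """The full accounting pipeline for one treatment over several frames.

    For each frame and analyte: frame delta in treatment, frame delta in the
    matched control, control subtraction, conversion to carbon/reductant
    units. An analyte entirely absent from a treatment's records (e.g. a gas
    that could not be quantified) contributes zero turnover, with a logged
    notice. Raises if the design's control has a different BES status.
    """
    design = designs[treatment_id]
    if design.control_id not in designs:
        raise KeyError(f"control {design.control_id!r} of {treatment_id!r} is not in designs")
    control = designs[design.control_id]
    if control.bes != design.bes:
        raise ValueError(
            f"BES mismatch: treatment {treatment_id!r} (bes={design.bes}) paired with "
            f"control {control.treatment_id!r} (bes={control.bes})"
        )

    if analytes is None:
        analytes = sorted(
            set(series.analytes_of(treatment_id)) | set(series.analytes_of(control.treatment_id))
        )

    rows = []
    for frame in frames:
        for analyte in analytes:
            if analyte not in registry:
                raise KeyError(f"analyte {analyte!r} is not in the compound registry")
            deltas = {}
            for role, tid in (("treatment", treatment_id), ("control", control.treatment_id)):
                if analyte in series.analytes_of(tid):
                    deltas[role] = frame_delta(
                        series,
                        tid,
                        frame,
                        analyte,
                        replicate_policy=replicate_policy,
                        interpolate=interpolate,
                    )
                else:
                    logger.info(
                        "analyte %r missing for %s %r; treated as zero turnover",
                        analyte,
                        role,
                        tid,
                    )
                    deltas[role] = Delta(0.0, 0.0)
            net = control_subtract(deltas["treatment"], deltas["control"])
            carbon, reductant = to_carbon_reductant(net.value, registry[analyte])
            rows.append(
                (frame.t_start, frame.t_end, analyte, net.value, net.se, carbon, reductant)
            )
    table = pd.DataFrame(rows, columns=NetTurnoverTable.COLUMNS)
    return NetTurnoverTable(
        table,
        provenance={
            "treatment": treatment_id,
            "control": control.treatment_id,
            "bes": design.bes,
            "replicate_policy": replicate_policy,
        },
    )


@dataclass(frozen=True)
class RecoveryResult:
    """A closure percentage, or an explicit undefined flag.

    ``percent`` is 100 × (sum of net productions) / |sum of net
    consumptions| on the chosen basis. Values above 100 are reported as-is
    (production exceeding the measured substrate supply) and flagged via
    ``exceeds_100``; ``defined`` is False when the frame has no net-consumed
    compound, in which case ``percent`` is NaN.
    """

    percent: float
    defined: bool = True
    exceeds_100: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "exceeds_100", bool(self.defined and self.percent > 100.0)
        )


_BASIS_COLUMN = {"carbon": "carbon_uM", "reductant": "reductant_uM"}


def recovery_ratio(table: NetTurnoverTable, frame: TimeFrame, basis: str) -> RecoveryResult:
    """Budget closure for one frame: produced / consumed, as a percentage.

    On the ``"carbon"`` basis, this asks how much of the carbon released by
    net-consumed compounds is recovered in net-produced ones; the
    ``"reductant"`` basis does the same for electron equivalents. 100% means
    a closed measured budget; values below 100 indicate unmeasured sinks,
    above 100 unmeasured sources. If nothing was net-consumed in the frame
    the ratio is undefined and flagged, not a number.
    """
    if basis not in _BASIS_COLUMN:
        raise ValueError(f"basis must be 'carbon' or 'reductant', got {basis!r}")
    values = table.for_frame(frame)[_BASIS_COLUMN[basis]].to_numpy(dtype=float)
    produced = values[values > 0].sum()
    consumed = -values[values < 0].sum()
    if consumed == 0:
        logger.warning("no net consumption in frame %s on %s basis; recovery undefined", frame, basis)
        return RecoveryResult(float("nan"), defined=False)
    result = RecoveryResult(100.0 * produced / consumed)
    if result.exceeds_100:
        logger.warning(
            "recovery in frame %s on %s basis exceeds 100%% (%.1f%%): more %s recovered in "
            "products than available from consumed substrates",
            frame,
            basis,
            result.percent,
            basis,
        )
    return result


def product_fraction(
    table: NetTurnoverTable, frame: TimeFrame, compound: str, basis: str
) -> RecoveryResult:
    """Share of one compound in the total net production of a frame.

    100 × (positive turnover of the compound) / (sum of all positive
    turnovers) on the chosen basis; net-consumed compounds contribute zero
    to the numerator, and a compound absent from the table has share 0.
    Undefined (flagged) when the frame has no net production at all.
    """
    if basis not in _BASIS_COLUMN:
        raise ValueError(f"basis must be 'carbon' or 'reductant', got {basis!r}")
    sub = table.for_frame(frame)
    values = sub[_BASIS_COLUMN[basis]].to_numpy(dtype=float)
    total = values[values > 0].sum()
    if total == 0:
        return RecoveryResult(float("nan"), defined=False)
    own = sub.loc[sub["analyte"] == compound, _BASIS_COLUMN[basis]]
    contribution = float(own.iloc[0]) if len(own) else 0.0
    return RecoveryResult(100.0 * max(contribution, 0.0) / total)
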