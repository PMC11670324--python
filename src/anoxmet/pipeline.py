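"""Configuration and end-to-end orchestration of the accounting pipeline.

A :class:`RunConfig` (typically loaded from a YAML file) names the inputs —
a measured or simulated concentration series, the treatment design with its
control mapping, the time frames and bases — and :func:`run_pipeline` runs
simulation (optional), turnover accounting, recovery statistics and chamber
flux estimation, writing delimited-text outputs with a provenance header
(package version, seed, configuration hash) sufficient to reproduce the run.
Outputs are deterministic given the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .gasflux import FluxEstimate, chamber_flux, ratio_series
from .io import (
    read_chamber_series,
    read_slurry_series,
    write_flux_estimates,
    write_slurry_series,
    write_turnover_table,
)
from .stoichiometry import Compound, default_registry, load_registry
from .synthetic_data import (
    DEFAULT_SAMPLING_DAYS,
    nag_microcosm_model,
    simulate_nag_experiment,
)
from .turnover import (
    NetTurnoverTable,
    SlurryTimeSeries,
    TimeFrame,
    TreatmentDesign,
    net_turnover_table,
    recovery_ratio,
)

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline", "parse_frames"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def parse_frames(spec: Sequence) -> list[TimeFrame]:
    """Parse frames from ``[[0, 4], [4, 10]]`` or ``"0-4,4-10"`` notation."""
    if isinstance(spec, str):
        spec = [part.split("-") for part in spec.split(",")]
    return [TimeFrame(float(a), float(b)) for a, b in spec]


def _parse_designs(raw: Mapping[str, Mapping]) -> dict[str, TreatmentDesign]:
    designs = {}
    for tid, entry in raw.items():
        entry = entry or {}
        supplement = entry.get("supplement")
        if supplement is not None:
            supplement = (str(supplement["compound"]), float(supplement["amount_uM"]))
        designs[str(tid)] = TreatmentDesign(
            treatment_id=str(tid),
            supplement=supplement,
            bes=bool(entry.get("bes", False)),
            preincubation_days=int(entry.get("preincubation_days", 0)),
            control_id=entry.get("control"),
        )
    return designs


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    designs: Mapping[str, TreatmentDesign]
    treatments: tuple[str, ...]
    frames: tuple[TimeFrame, ...]
    output_dir: Path
    seed: int
    series_path: Path | None = None
    registry_path: Path | None = None
    bases: tuple[str, ...] = ("carbon", "reductant")
    scenario: Mapping[str, object] | None = None
    chamber: Mapping[str, object] | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if raw.get("seed") is None:
            raise ValueError("config must set an explicit seed")
        return cls(
            designs=_parse_designs(raw["designs"]),
            treatments=tuple(raw["treatments"]),
            frames=tuple(parse_frames(raw.get("frames", [[0, 4], [4, 10], [0, 10]]))),
            output_dir=Path(raw.get("output_dir", ".")),
            seed=int(raw["seed"]),
            series_path=Path(raw["series"]) if raw.get("series") else None,
            registry_path=Path(raw["registry"]) if raw.get("registry") else None,
            bases=tuple(raw.get("bases", ("carbon", "reductant"))),
            scenario=raw.get("scenario"),
            chamber=raw.get("chamber"),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def registry(self) -> dict[str, Compound]:
        if self.registry_path is None:
            return default_registry()
        return load_registry(self.registry_path)

    def canonical_hash(self) -> str:
        payload = {
            "designs": {
                t: {
                    "supplement": d.supplement,
                    "bes": d.bes,
                    "preincubation_days": d.preincubation_days,
                    "control": d.control_id,
                }
                for t, d in sorted(self.designs.items())
            },
            "treatments": list(self.treatments),
            "frames": [(f.t_start, f.t_end) for f in self.frames],
            "bases": list(self.bases),
            "seed": self.seed,
            "series": str(self.series_path),
            "registry": str(self.registry_path),
            "scenario": self.scenario,
            "chamber": self.chamber,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of everything a run produced."""

    series: SlurryTimeSeries
    tables: dict[str, NetTurnoverTable]
    recovery: pd.DataFrame
    fluxes: list[FluxEstimate] = field(default_factory=list)
    ratios: pd.DataFrame | None = None
    provenance: dict[str, object] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulation (optional), turnover, recovery and flux stages.

    Writes ``series.csv`` (when simulated), ``turnover_<treatment>.csv``,
    ``recovery.csv`` and, when a chamber block is configured, ``flux.csv``
    and ``ratio.csv`` into the output directory. Any stage failure aborts
    with the stage name and cause.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "anoxmet_version": __version__,
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
    }
    registry = _stage("registry")(config.registry)

    if config.scenario is not None:
        scenario = dict(config.scenario)
        model = nag_microcosm_model(
            sink_fraction=float(scenario.get("sink_fraction", 0.5)),
            noise_sd=float(scenario.get("noise_sd", 10.0)),
            endogenous_co2_rate=float(scenario.get("endogenous_co2_rate", 200.0)),
        )
        series, designs, _ = _stage("simulate")(
            simulate_nag_experiment,
            config.seed,
            model=model,
            nag_um=float(scenario.get("nag_um", 500.0)),
            duration=float(scenario.get("duration", 10.0)),
            sampling_days=scenario.get("sampling_days", DEFAULT_SAMPLING_DAYS),
        )
        if set(config.designs) - set(designs):
            raise PipelineError(
                "stage 'simulate' failed: configured designs do not match the scenario arms"
            )
        _stage("write-series")(write_slurry_series, series, out_dir / "series.csv", provenance)
    elif config.series_path is not None:
        series = _stage("read-series")(read_slurry_series, config.series_path)
    else:
        raise PipelineError("stage 'input' failed: need either a series path or a scenario")

    tables: dict[str, NetTurnoverTable] = {}
    recovery_rows = []
    for treatment in config.treatments:
        table = _stage("turnover")(
            net_turnover_table,
            series,
            config.designs,
            treatment,
            config.frames,
            registry,
        )
        tables[treatment] = table
        _stage("write-turnover")(
            write_turnover_table, table, out_dir / f"turnover_{treatment}.csv", provenance
        )
        for frame in config.frames:
            for basis in config.bases:
                result = _stage("recovery")(recovery_ratio, table, frame, basis)
                recovery_rows.append(
                    (
                        treatment,
                        str(frame),
                        basis,
                        result.percent,
                        result.defined,
                        result.exceeds_100,
                    )
                )
    recovery = pd.DataFrame(
        recovery_rows,
        columns=["treatment", "frame", "basis", "recovery_percent", "defined", "exceeds_100"],
    )
    with open(out_dir / "recovery.csv", "w", encoding="utf-8", newline="") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}={v}\n")
        recovery.to_csv(fh, index=False, lineterminator="\n")

    fluxes: list[FluxEstimate] = []
    ratios = None
    if config.chamber is not None:
        chamber = dict(config.chamber)
        series_list = _stage("read-chamber")(
            read_chamber_series,
            chamber["path"],
            volume_m3=float(chamber["volume_m3"]),
            area_m2=float(chamber["area_m2"]),
            temperature_k=float(chamber.get("temperature_k", 293.15)),
            pressure_pa=float(chamber.get("pressure_pa", 101325.0)),
        )
        fluxes = [_stage("flux")(chamber_flux, s) for s in series_list]
        _stage("write-flux")(write_flux_estimates, fluxes, out_dir / "flux.csv", provenance)
        flux_df = pd.DataFrame(
            [(f.plot_id, f.gas, f.flux_umol_m2_h) for f in fluxes],
            columns=["plot", "gas", "flux"],
        ).pivot(index="plot", columns="gas", values="flux")
        if {"CO2", "CH4"} <= set(flux_df.columns):
            rr = _stage("ratio")(ratio_series, flux_df["CO2"], flux_df["CH4"])
            ratios = pd.DataFrame(
                {"co2_ch4_ratio": rr.ratios, "undefined": rr.undefined}
            ).reset_index()
            with open(out_dir / "ratio.csv", "w", encoding="utf-8", newline="") as fh:
                for k, v in provenance.items():
                    fh.write(f"# {k}={v}\n")
                ratios.to_csv(fh, index=False, lineterminator="\n")

    return PipelineResult(
        series=series,
        tables=tables,
        recovery=recovery,
        fluxes=fluxes,
        ratios=ratios,
        provenance=provenance,
    )
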