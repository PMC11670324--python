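"""Reading and writing the delimited-text formats of the pipeline.

All files are comma-separated UTF-8 with "." decimal separator and fixed
documented headers; lines starting with ``#`` are provenance/comment lines.
Validation rejects malformed input listing the offending physical line
numbers — it never silently repairs.
"""

from __future__ import annotations

import csv
import io as _io
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gasflux import ChamberSeries, FluxEstimate
from .turnover import NetTurnoverTable, SlurryTimeSeries, SERIES_COLUMNS

__all__ = [
    "SeriesValidationError",
    "read_slurry_series",
    "write_slurry_series",
    "read_chamber_series",
    "write_turnover_table",
    "read_turnover_table",
    "write_flux_estimates",
]

CHAMBER_COLUMNS = ["plot", "treatment", "hour", "gas", "ppmv"]


class SeriesValidationError(ValueError):
    """Input rejected; ``errors`` lists (line_number, message) pairs."""

    def __init__(self, path, errors: list[tuple[int, str]]):
        self.errors = errors
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:20])
        more = "" if len(errors) <= 20 else f" (+{len(errors) - 20} more)"
        super().__init__(f"{path}: {detail}{more}")


def _read_rows(path, expected_header: Sequence[str]) -> tuple[list[dict], list[tuple[int, str]]]:
    rows: list[dict] = []
    errors: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header: list[str] | None = None
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in expected_header if c not in header]
                if missing:
                    raise SeriesValidationError(
                        path, [(line_no, f"missing columns {missing} in header {header}")]
                    )
                continue
            if len(fields) != len(header):
                errors.append((line_no, f"expected {len(header)} fields, got {len(fields)}"))
                continue
            rows.append({"_line": line_no, **dict(zip(header, (f.strip() for f in fields)))})
        if header is None:
            raise SeriesValidationError(path, [(0, "empty file, no header")])
    return rows, errors


def _as_float(row: dict, column: str, errors: list) -> float | None:
    try:
        return float(row[column])
    except (TypeError, ValueError):
        errors.append((row["_line"], f"non-numeric {column}: {row[column]!r}"))
        return None


def read_slurry_series(path) -> SlurryTimeSeries:
    """Read a long-format concentration series.

    Expected header: ``treatment,replicate,day,analyte,concentration_uM``.
    Rejects (listing line numbers): malformed numbers, negative days or
    concentrations, duplicate (treatment, replicate, day, analyte) keys.
    """
    rows, errors = _read_rows(path, SERIES_COLUMNS)
    records, seen = [], {}
    for row in rows:
        day = _as_float(row, "day", errors)
        conc = _as_float(row, "concentration_uM", errors)
        if day is None or conc is None:
            continue
        if day < 0:
            errors.append((row["_line"], f"negative day {day}"))
            continue
        if conc < 0:
            errors.append((row["_line"], f"negative concentration {conc}"))
            continue
        key = (row["treatment"], row["replicate"], day, row["analyte"])
        if key in seen:
            errors.append(
                (row["_line"], f"duplicate key {key} (first seen on line {seen[key]})")
            )
            continue
        seen[key] = row["_line"]
        records.append((row["treatment"], row["replicate"], day, row["analyte"], conc))
    if errors:
        raise SeriesValidationError(path, errors)
    return SlurryTimeSeries.from_records(records)


def _write_csv(path, header_lines: Iterable[str], frame: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def write_slurry_series(
    series: SlurryTimeSeries, path, provenance: Mapping[str, object] | None = None
) -> None:
    """Write a series in the same format :func:`read_slurry_series` reads."""
    meta = [f"{k}={v}" for k, v in (provenance or {}).items()]
    _write_csv(path, meta, series.frame)


def read_chamber_series(
    path,
    *,
    volume_m3: float,
    area_m2: float,
    temperature_k: float = 293.15,
    pressure_pa: float = 101325.0,
) -> list[ChamberSeries]:
    """Read closed-chamber gas series, one per (plot, gas).

    Expected header: ``plot,treatment,hour,gas,ppmv``; chamber geometry and
    conditions apply to every series in the file.
    """
    rows, errors = _read_rows(path, CHAMBER_COLUMNS)
    records = []
    for row in rows:
        hour = _as_float(row, "hour", errors)
        ppmv = _as_float(row, "ppmv", errors)
        if hour is None or ppmv is None:
            continue
        records.append((row["plot"], row["gas"], hour, ppmv, row["_line"]))
    if errors:
        raise SeriesValidationError(path, errors)
    df = pd.DataFrame(records, columns=["plot", "gas", "hour", "ppmv", "_line"])
    series = []
    for (plot, gas), sub in df.groupby(["plot", "gas"], sort=True):
        sub = sub.sort_values("hour")
        dup = sub["hour"].duplicated()
        if dup.any():
            raise SeriesValidationError(
                path,
                [(int(ln), f"duplicate timepoint for plot {plot!r} gas {gas!r}")
                 for ln in sub.loc[dup, "_line"]],
            )
        series.append(
            ChamberSeries(
                plot_id=str(plot),
                gas=str(gas),
                hours=tuple(sub["hour"]),
                ppmv=tuple(sub["ppmv"]),
                volume_m3=volume_m3,
                area_m2=area_m2,
                temperature_k=temperature_k,
                pressure_pa=pressure_pa,
            )
        )
    return series


def write_turnover_table(
    table: NetTurnoverTable, path, provenance: Mapping[str, object] | None = None
) -> None:
    """Write a net-turnover table with its provenance as ``#`` header lines."""
    meta = {**table.provenance, **(provenance or {})}
    _write_csv(path, (f"{k}={v}" for k, v in meta.items()), table.frame)


def read_turnover_table(path) -> NetTurnoverTable:
    """Read a table written by :func:`write_turnover_table`."""
    provenance = {}
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            entry = line.lstrip("#").strip()
            if "=" in entry:
                k, v = entry.split("=", 1)
                provenance[k.strip()] = v.strip()
        else:
            body.append(line)
    frame = pd.read_csv(_io.StringIO("\n".join(body)))
    return NetTurnoverTable(frame, provenance)


def write_flux_estimates(
    estimates: Sequence[FluxEstimate], path, provenance: Mapping[str, object] | None = None
) -> None:
    """Write flux estimates, one row per chamber deployment."""
    frame = pd.DataFrame(
        [
            (
                e.plot_id,
                e.gas,
                e.slope_ppmv_per_h,
                e.slope_se,
                e.flux_umol_m2_h,
                e.flux_se,
                e.r_squared,
                e.n_points,
            )
            for e in estimates
        ],
        columns=[
            "plot",
            "gas",
            "slope_ppmv_per_h",
            "slope_se",
            "flux_umol_m2_h",
            "flux_se",
            "r_squared",
            "n_points",
        ],
    )
    meta = [f"{k}={v}" for k, v in (provenance or {}).items()]
    _write_csv(path, meta, frame)
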