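"""Readers and writers for the pipeline's file formats.

Canonical dialects (all plain text):

- concentration series CSV: columns ``timestamp,concentration``; timestamps
  either elapsed seconds (numeric) or ISO-8601 datetimes (converted to
  elapsed seconds from the first stamp) — auto-detected.
- exclusion intervals CSV: columns ``start_s,end_s``.
- filter samples CSV: columns
  ``label,ti_mass_ng,censored,loq_ng,volume_m3,duration_h`` (``ti_mass_ng``
  empty when censored).
- scenario configuration: YAML with keys ``room``, ``purifiers``, ``oels``,
  ``duration_h``, ``initial_conc_ng_m3`` (validated by the pydantic
  scenario models).
- reports: JSON, always embedding the fully resolved configuration so the
  output is self-describing.

Malformed rows are reported with their 1-based file line numbers. No
reader or writer ever mutates its input file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from .inference import ConcentrationSeries, ExclusionIntervals
from .release import FilterSample
from .scenario import OELReference, Purifier, RoomScenario

__all__ = [
    "SeriesFormatError",
    "read_series_csv",
    "write_series_csv",
    "read_exclusions_csv",
    "write_exclusions_csv",
    "read_filter_samples_csv",
    "write_filter_samples_csv",
    "read_scenario_yaml",
    "write_json_report",
]


class SeriesFormatError(ValueError):
    """A structured parse/validation error naming the offending line."""


def _data_line(row_index: int) -> int:
    """1-based file line of a 0-based data row (line 1 is the header)."""
    return row_index + 2


def read_series_csv(
    path: str | Path, metric: str = "number", instrument_label: str | None = None
) -> ConcentrationSeries:
    """Read a timestamp,concentration CSV into a validated series."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SeriesFormatError(f"{path}: expected columns timestamp,concentration")
    cols = {c.strip().lower(): c for c in df.columns}
    tcol = cols.get("timestamp", df.columns[0])
    ccol = cols.get("concentration", df.columns[1])
    if len(df) < 2:
        raise SeriesFormatError(f"{path}: need at least 2 rows")

    raw_t = df[tcol]
    numeric_t = pd.to_numeric(raw_t, errors="coerce")
    if numeric_t.notna().all():
        t = numeric_t.to_numpy(dtype=float)
    else:
        stamps = pd.to_datetime(raw_t, errors="coerce", format="ISO8601")
        bad = np.nonzero(stamps.isna().to_numpy())[0]
        if bad.size:
            raise SeriesFormatError(
                f"{path}: line {_data_line(bad[0])}: timestamp {raw_t.iloc[bad[0]]!r} "
                "is neither elapsed seconds nor ISO-8601"
            )
        t = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy()

    values = pd.to_numeric(df[ccol], errors="coerce")
    bad = np.nonzero(values.isna().to_numpy())[0]
    if bad.size:
        raise SeriesFormatError(
            f"{path}: line {_data_line(bad[0])}: concentration "
            f"{df[ccol].iloc[bad[0]]!r} is not numeric"
        )
    v = values.to_numpy(dtype=float)
    neg = np.nonzero(v < 0)[0]
    if neg.size:
        raise SeriesFormatError(
            f"{path}: line {_data_line(neg[0])}: negative concentration {v[neg[0]]}"
        )
    non_mono = np.nonzero(np.diff(t) <= 0)[0]
    if non_mono.size:
        raise SeriesFormatError(
            f"{path}: line {_data_line(non_mono[0] + 1)}: timestamps not strictly increasing"
        )
    return ConcentrationSeries(
        timestamps_s=t,
        values=v,
        metric=metric,
        instrument_label=instrument_label if instrument_label is not None else path.stem,
    )


def write_series_csv(series: ConcentrationSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp": series.timestamps_s, "concentration": series.values}
    ).to_csv(path, index=False)


def read_exclusions_csv(path: str | Path) -> ExclusionIntervals:
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    scol = cols.get("start_s", df.columns[0])
    ecol = cols.get("end_s", df.columns[1])
    return ExclusionIntervals(
        tuple((float(s), float(e)) for s, e in zip(df[scol], df[ecol]))
    )


def write_exclusions_csv(excl: ExclusionIntervals, path: str | Path) -> None:
    pd.DataFrame(excl.intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)


def read_filter_samples_csv(path: str | Path) -> list[FilterSample]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"label", "ti_mass_ng", "censored", "loq_ng", "volume_m3", "duration_h"}
    missing = required - set(df.columns)
    if missing:
        raise SeriesFormatError(f"{path}: missing columns {sorted(missing)}")
    samples = []
    for i, row in df.iterrows():
        censored = bool(row["censored"]) if not isinstance(row["censored"], str) else (
            row["censored"].strip().lower() in ("true", "1", "yes")
        )
        try:
            samples.append(
                FilterSample(
                    label=str(row["label"]),
                    ti_mass_ng=None if censored else float(row["ti_mass_ng"]),
                    loq_ng=float(row["loq_ng"]),
                    sampled_volume_m3=float(row["volume_m3"]),
                    duration_h=float(row["duration_h"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SeriesFormatError(f"{path}: line {_data_line(i)}: {exc}") from exc
    return samples


def write_filter_samples_csv(samples: list[FilterSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "label": s.label,
                "ti_mass_ng": "" if s.censored else s.ti_mass_ng,
                "censored": s.censored,
                "loq_ng": s.loq_ng,
                "volume_m3": s.sampled_volume_m3,
                "duration_h": s.duration_h,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_scenario_yaml(path: str | Path) -> RoomScenario:
    """Parse and validate a scenario configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    room = raw.get("room", {})
    try:
        return RoomScenario(
            room_volume_m3=room.get("volume_m3"),
            ach_per_h=room.get("ach_per_h"),
            lambda_dep_per_h=room.get("lambda_dep_per_h", 0.0),
            outdoor_conc_ng_m3=room.get("outdoor_conc_ng_m3", 0.0),
            penetration=room.get("penetration", 1.0),
            purifiers=tuple(Purifier(**p) for p in raw.get("purifiers", [])),
            oels=tuple(OELReference(**o) for o in raw.get("oels", [])),
            duration_h=raw.get("duration_h", 10.0),
            initial_conc_ng_m3=raw.get("initial_conc_ng_m3", 0.0),
            n_output_points=raw.get("n_output_points", 241),
        )
    except ValidationError as exc:
        raise SeriesFormatError(f"{path}: invalid scenario configuration:\n{exc}") from exc


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json_report(payload: dict, path: str | Path, config: dict | None = None) -> None:
    """Write a JSON report embedding the fully resolved configuration."""
    doc = dict(payload)
    if config is not None:
        doc["config"] = config
    with open(path, "w") as fh:
        json.dump(_jsonable(doc), fh, indent=2, sort_keys=True)
        fh.write("\n")
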