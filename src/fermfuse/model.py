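"""Domain types and on-disk batch layout shared by the whole pipeline.

A fermentation *batch* is the unit of record: a set of time series from
three source classes —

* **online** — bioreactor sensors sampled at a high regular cadence
  (pH, DO, temperature, agitation, air flow, broth weight, pump rates);
* **at-line** — instrument readings with slow/irregular cadence that need
  processing before use (off-gas mass-spectrometry compositions);
* **offline** — manually sampled lab assays (biomass OD, titer).

All times are elapsed hours since inoculation, as decimal numbers.  Source
files may instead carry wall-clock timestamps; these are converted at load
time using the ``start_time`` entry of the batch metadata.

The on-disk layout is one directory per batch::

    <batch_dir>/
        meta.yaml      # batch_id, strain, medium, operation_conditions, ...
        online.csv     # first column time_h, one column per variable
        atline.csv
        offline.csv

Missing values in tables are explicit (empty cell or "NA"), never silently
dropped, so that downstream filling steps are auditable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SourceClass",
    "TimeSeries",
    "BatchMeta",
    "BatchDataset",
    "FusedFrame",
    "FermfuseError",
    "FormatError",
    "RangeError",
    "ConfigError",
    "validate_batch",
    "load_batch",
    "save_batch",
]

TIME_COLUMN = "time_h"
META_FILE = "meta.yaml"
SOURCE_FILES = {"online": "online.csv", "at_line": "atline.csv", "offline": "offline.csv"}


class FermfuseError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FermfuseError):
    """A source file or directory does not follow the batch layout."""


class RangeError(FermfuseError, ValueError):
    """A value lies outside its declared valid range."""


class ConfigError(FermfuseError):
    """A configuration document is malformed."""


class SourceClass(str, enum.Enum):
    """How a stream was collected; drives cadence assumptions downstream."""

    ONLINE = "online"
    AT_LINE = "at_line"
    OFFLINE = "offline"


@dataclass
class TimeSeries:
    """Timestamped values of one variable in one batch.

    Parameters
    ----------
    variable : str
        Variable name, unique within a batch.
    unit : str
        Engineering unit (free text, e.g. ``"%"`` or ``"rpm"``).
    source : SourceClass
        Collection class of the stream.
    times : ndarray
        Elapsed hours since inoculation, strictly increasing.
    values : ndarray
        Measurements; NaN marks a missing value (allowed only before the
        filling steps of the pipeline).
    """

    variable: str
    unit: str
    source: SourceClass
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.source = SourceClass(self.source)

    def __len__(self) -> int:
        return self.times.size

    def copy_with(self, **kwargs) -> "TimeSeries":
        """Return a copy with some fields replaced (arrays are copied)."""
        out = replace(self, **kwargs)
        out.times = np.array(out.times, dtype=float)
        out.values = np.array(out.values, dtype=float)
        return out

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class BatchMeta:
    """Experiment-design metadata of one batch; only ``batch_id`` is required."""

    batch_id: str
    strain: str = ""
    medium: str = ""
    operation_conditions: dict = field(default_factory=dict)
    control_strategy: str = ""
    start_time: str = ""  # ISO-8601 wall clock of inoculation, if known
    extra: dict = field(default_factory=dict)


@dataclass
class BatchDataset:
    """All streams plus metadata for one fermentation batch."""

    meta: BatchMeta
    series: dict[str, TimeSeries] = field(default_factory=dict)

    def add(self, ts: TimeSeries) -> None:
        if ts.variable in self.series:
            raise FormatError(f"duplicate variable {ts.variable!r} in batch {self.meta.batch_id!r}")
        self.series[ts.variable] = ts

    def by_source(self, source: SourceClass) -> dict[str, TimeSeries]:
        source = SourceClass(source)
        return {k: v for k, v in self.series.items() if v.source == source}

    @property
    def span(self) -> tuple[float, float]:
        starts = [ts.times[0] for ts in self.series.values() if len(ts)]
        ends = [ts.times[-1] for ts in self.series.values() if len(ts)]
        return (min(starts), max(ends))


@dataclass
class FusedFrame:
    """A rectangular view of one batch on the online time grid.

    ``data`` holds one row per grid point and one column per variable; no
    NaN remain after fusion.  ``provenance`` records, per column, the source
    class and the alignment/fill method that produced it.
    """

    times: np.ndarray
    data: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)
    meta: BatchMeta | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def as_batch(self) -> BatchDataset:
        """Re-wrap the fused columns as an all-online batch (for re-fusion)."""
        meta = self.meta or BatchMeta(batch_id="fused")
        b = BatchDataset(meta=meta)
        for name in self.data.columns:
            prov = self.provenance.get(name, {})
            b.add(
                TimeSeries(
                    variable=name,
                    unit=prov.get("unit", ""),
                    source=SourceClass.ONLINE,
                    times=self.times.copy(),
                    values=self.data[name].to_numpy().copy(),
                )
            )
        return b

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, TIME_COLUMN, self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: BatchMeta | None = None) -> "FusedFrame":
        df = pd.read_csv(path, float_precision="round_trip")
        if TIME_COLUMN not in df.columns:
            raise FormatError(f"{path}: missing {TIME_COLUMN!r} column")
        times = df[TIME_COLUMN].to_numpy(dtype=float)
        data = df.drop(columns=[TIME_COLUMN])
        return cls(times=times, data=data, meta=meta)


# ---------------------------------------------------------------------------
# Validation

def validate_batch(b: BatchDataset) -> list[str]:
    """Check every type invariant of a batch; return a report.

    Total: never raises, returns an empty list iff all invariants hold.
    Each violation names the offending series and the rule broken.
    """
    violations: list[str] = []
    if not b.meta.batch_id:
        violations.append("meta: empty batch_id")
    seen: set[str] = set()
    for key, ts in b.series.items():
        name = ts.variable
        if key != name:
            violations.append(f"{key}: key does not match variable name {name!r}")
        if name in seen:
            violations.append(f"{name}: duplicate variable")
        seen.add(name)
        if ts.times.size != ts.values.size:
            violations.append(f"{name}: times and values differ in length")
        if ts.times.size and not np.all(np.diff(ts.times) > 0):
            violations.append(f"{name}: non-increasing times")
        if np.isnan(ts.times).any():
            violations.append(f"{name}: NaN in time axis")
    if not b.by_source(SourceClass.ONLINE):
        violations.append("batch: no online series (required for fusion)")
    return violations


# ---------------------------------------------------------------------------
# On-disk layout

def _series_to_frame(series: dict[str, TimeSeries]) -> pd.DataFrame:
    """Merge same-source series into one table on the union of their times."""
    frames = []
    for name, ts in series.items():
        frames.append(pd.DataFrame({TIME_COLUMN: ts.times, name: ts.values}))
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on=TIME_COLUMN, how="outer")
    return out.sort_values(TIME_COLUMN).reset_index(drop=True)


def save_batch(b: BatchDataset, path) -> Path:
    """Write a batch directory (meta.yaml + one CSV per source class)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    units = {name: ts.unit for name, ts in b.series.items()}
    meta_doc = {
        "batch_id": b.meta.batch_id,
        "strain": b.meta.strain,
        "medium": b.meta.medium,
        "operation_conditions": b.meta.operation_conditions,
        "control_strategy": b.meta.control_strategy,
        "start_time": b.meta.start_time,
        "units": units,
    }
    meta_doc.update(b.meta.extra)
    with open(path / META_FILE, "w") as fh:
        yaml.safe_dump(meta_doc, fh, sort_keys=False)
    for source, fname in SOURCE_FILES.items():
        group = b.by_source(SourceClass(source))
        if not group:
            continue
        _series_to_frame(group).to_csv(path / fname, index=False)
    return path


def load_batch(path) -> BatchDataset:
    """Read a batch directory written by :func:`save_batch` (or by hand).

    Raises
    ------
    FormatError
        If the metadata file is missing, a table cannot be parsed, a cell
        is non-numeric, or two files define the same variable.
    """
    path = Path(path)
    meta_path = path / META_FILE
    if not meta_path.exists():
        raise FormatError(f"{path}: missing metadata file {META_FILE}")
    with open(meta_path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "batch_id" not in doc:
        raise FormatError(f"{meta_path}: missing batch_id")
    known = {"batch_id", "strain", "medium", "operation_conditions",
             "control_strategy", "start_time", "units"}
    meta = BatchMeta(
        batch_id=str(doc["batch_id"]),
        strain=str(doc.get("strain", "") or ""),
        medium=str(doc.get("medium", "") or ""),
        operation_conditions=doc.get("operation_conditions") or {},
        control_strategy=str(doc.get("control_strategy", "") or ""),
        start_time=str(doc.get("start_time", "") or ""),
        extra={k: v for k, v in doc.items() if k not in known},
    )
    units = doc.get("units") or {}
    b = BatchDataset(meta=meta)
    for source, fname in SOURCE_FILES.items():
        fpath = path / fname
        if not fpath.exists():
            continue
        df = pd.read_csv(fpath, na_values=["NA"], keep_default_na=True)
        if TIME_COLUMN not in df.columns:
            raise FormatError(f"{fpath}: first column must be {TIME_COLUMN!r}")
        times = _parse_times(df[TIME_COLUMN], meta, fpath)
        for col in df.columns:
            if col == TIME_COLUMN:
                continue
            raw = df[col]
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "NA")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"{fpath}: non-numeric value {raw.iloc[row]!r} at row {row + 2}, column {col!r}"
                )
            keep = ~np.isnan(times)
            b.add(
                TimeSeries(
                    variable=col,
                    unit=str(units.get(col, "")),
                    source=SourceClass(source),
                    times=times[keep],
                    values=vals.to_numpy(dtype=float)[keep],
                )
            )
    return b


def _parse_times(col: pd.Series, meta: BatchMeta, fpath) -> np.ndarray:
    """Accept decimal hours directly, or ISO timestamps anchored at start_time."""
    as_num = pd.to_numeric(col, errors="coerce")
    if not as_num.isna().any():
        return as_num.to_numpy(dtype=float)
    stamps = pd.to_datetime(col, errors="coerce", format="ISO8601")
    if stamps.isna().any():
        raise FormatError(f"{fpath}: time column is neither decimal hours nor ISO-8601")
    if not meta.start_time:
        raise FormatError(
            f"{fpath}: wall-clock times require 'start_time' in {META_FILE}"
        )
    t0 = pd.Timestamp(meta.start_time)
    return ((stamps - t0).dt.total_seconds() / 3600.0).to_numpy(dtype=float)
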