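"""Alignment of multi-rate streams onto the online time grid.

The online sensors define the master grid (~1 min cadence).  Fusion brings
every other stream onto that grid in three steps:

1. at-line series are section-averaged per instrument cycle (and any gaps
   mean-filled from adjacent points);
2. at-line series are aligned to the online time points by piecewise
   two-point Lagrange (i.e. linear) interpolation;
3. offline series are first anchored — each manual sample snapped to its
   nearest grid time — then linearly interpolated between anchors.

"Lagrange linear" is read as degree-1 Lagrange between the bracketing
observations; higher-degree Lagrange polynomials are rejected for their
oscillation on irregular grids.  Beyond the observed span of an at-line or
offline series the default policy holds the nearest value (flagged in the
column provenance); an ``error`` policy is available.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BatchDataset, FormatError, FusedFrame, RangeError, SourceClass, TimeSeries
from .preprocess import FillMethod, fill_gaps, section_average_atline

__all__ = [
    "Extrapolation",
    "TieBreak",
    "AlignmentSpec",
    "align_nearest",
    "interp_lagrange_linear",
    "fuse_batch",
]


class Extrapolation(str, enum.Enum):
    HOLD = "hold"
    ERROR = "error"


class TieBreak(str, enum.Enum):
    EARLIER = "earlier"
    LATER = "later"


@dataclass
class AlignmentSpec:
    """How each variable is brought onto the online grid.

    ``method`` maps variable name to ``"nearest"`` or ``"lagrange_linear"``;
    unlisted variables default to ``lagrange_linear``.  Equidistant
    nearest-time ties resolve to the earlier observation by default
    (causality: do not use future data).
    """

    method: dict[str, str] = field(default_factory=dict)
    default_method: str = "lagrange_linear"
    extrapolation: Extrapolation = Extrapolation.HOLD
    tie_break: TieBreak = TieBreak.EARLIER
    channel_cycle: float = 1.0 / 3.0  # at-line instrument cycle, hours
    section_average: bool = True

    def method_for(self, variable: str) -> str:
        return self.method.get(variable, self.default_method)


def align_nearest(ts: TimeSeries, grid, tie_break: TieBreak = TieBreak.EARLIER) -> TimeSeries:
    """Value of the temporally nearest observation at each grid point."""
    if len(ts) == 0:
        raise RangeError(f"{ts.variable}: cannot align an empty series")
    grid = np.asarray(grid, dtype=float)
    t = ts.times
    # index of first observation >= grid point
    right = np.searchsorted(t, grid, side="left")
    left = np.clip(right - 1, 0, len(t) - 1)
    right = np.clip(right, 0, len(t) - 1)
    dl = np.abs(grid - t[left])
    dr = np.abs(t[right] - grid)
    if TieBreak(tie_break) == TieBreak.EARLIER:
        pick_left = dl <= dr
    else:
        pick_left = dl < dr
    idx = np.where(pick_left, left, right)
    return ts.copy_with(times=grid.copy(), values=ts.values[idx])


def interp_lagrange_linear(
    ts: TimeSeries, grid, extrapolation: Extrapolation = Extrapolation.HOLD
) -> TimeSeries:
    """Piecewise two-point Lagrange (linear) interpolation onto ``grid``.

    Inside the observed span each grid value is the degree-1 Lagrange
    polynomial through the bracketing observations; a grid point on an
    observation time returns that observation exactly.  Outside the span,
    ``hold`` repeats the nearest end value; ``error`` raises.
    """
    if len(ts) < 2:
        raise RangeError(f"{ts.variable}: need >= 2 observations to interpolate")
    grid = np.asarray(grid, dtype=float)
    outside = (grid < ts.times[0]) | (grid > ts.times[-1])
    if outside.any() and Extrapolation(extrapolation) == Extrapolation.ERROR:
        raise RangeError(
            f"{ts.variable}: grid exceeds observed span "
            f"[{ts.times[0]}, {ts.times[-1]}] and extrapolation is 'error'"
        )
    vals = np.interp(grid, ts.times, ts.values)  # np.interp holds the ends
    return ts.copy_with(times=grid.copy(), values=vals)


def _online_grid(online: dict[str, TimeSeries]) -> np.ndarray:
    grids = [ts.times for ts in online.values()]
    grid = grids[0]
    for g in grids[1:]:
        if g.size != grid.size or not np.array_equal(g, grid):
            grid = np.union1d(grid, g)
    return np.asarray(grid, dtype=float)


def fuse_batch(b: BatchDataset, spec: AlignmentSpec | None = None) -> FusedFrame:
    """Fuse every stream of a batch onto the online time grid.

    The grid is the online series' time points (union, if several online
    series disagree).  At-line variables are section-averaged then
    interpolated; offline variables are anchored to their nearest grid
    times then interpolated between anchors.  Column provenance records
    the source class, the method applied, and whether extrapolation
    (hold) was used.  Fusing an already-fused frame is the identity.
    """
    spec = spec or AlignmentSpec()
    online = b.by_source(SourceClass.ONLINE)
    if not online:
        raise FormatError(f"batch {b.meta.batch_id!r}: no online series to define the grid")
    grid = _online_grid(online)
    columns: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}

    for name, ts in b.series.items():
        method = spec.method_for(name)
        steps: list[str] = []
        work = ts
        if ts.source == SourceClass.ONLINE:
            if np.array_equal(ts.times, grid):
                aligned = ts.copy_with()
            else:
                aligned = interp_lagrange_linear(work, grid, spec.extrapolation)
                steps.append("regridded")
        elif ts.source == SourceClass.AT_LINE:
            if spec.section_average:
                work = section_average_atline(work, spec.channel_cycle)
                steps.append("section_averaged")
            if work.has_missing:
                work = fill_gaps(work, FillMethod.MEAN)
                steps.append("mean_filled")
            aligned, steps = _align(work, grid, method, spec, steps)
        else:  # offline
            if work.has_missing:
                work = fill_gaps(work, FillMethod.INTERP)
                steps.append("interp_filled")
            # anchor: snap each offline timestamp to its nearest grid time
            snapped = _snap_to_grid(work, grid)
            steps.append("anchored")
            aligned, steps = _align(snapped, grid, method, spec, steps)
        held = bool((grid < work.times[0]).any() or (grid > work.times[-1]).any())
        columns[name] = aligned.values
        provenance[name] = {
            "source": ts.source.value,
            "unit": ts.unit,
            "method": method if ts.source != SourceClass.ONLINE else "identity",
            "steps": steps,
            "extrapolated": held and ts.source != SourceClass.ONLINE,
        }

    data = pd.DataFrame(columns)
    return FusedFrame(times=grid, data=data, provenance=provenance, meta=b.meta)


def _snap_to_grid(ts: TimeSeries, grid: np.ndarray) -> TimeSeries:
    pos = np.searchsorted(grid, ts.times)
    pos = np.clip(pos, 1, grid.size - 1)
    left, right = grid[pos - 1], grid[pos]
    snapped = np.where(ts.times - left <= right - ts.times, left, right)
    # keep strictly increasing times after snapping (collapse duplicates)
    keep = np.concatenate([[True], np.diff(snapped) > 0])
    return ts.copy_with(times=snapped[keep], values=ts.values[keep])


def _align(ts: TimeSeries, grid, method: str, spec: AlignmentSpec, steps: list[str]):
    if method == "nearest" or len(ts) == 1:
        out = align_nearest(ts, grid, spec.tie_break)
        steps = steps + ["nearest"]
    elif method == "lagrange_linear":
        out = interp_lagrange_linear(ts, grid, spec.extrapolation)
        steps = steps + ["lagrange_linear"]
    else:
        raise RangeError(f"unknown alignment method {method!r}")
    return out, steps
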