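"""Per-series cleaning: filtering, gap filling, normalization, section averaging.

These operations act on single :class:`~fermfuse.model.TimeSeries` objects
and always return new series; inputs are never mutated.  The cleaning
toolbox mirrors what a fermentation data platform applies before fusion:

* a moving-median filter for single-point sensor spikes (online streams);
* three gap-filling policies — neighbour-mean, linear interpolation in
  time, and zero fill;
* z-score / min-max normalization with recorded statistics so analytics
  can always report in original units;
* section averaging of at-line instrument cycles (an off-gas mass spec
  serves channels in ~20 min cycles; readings within one cycle are
  replaced by their mean).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .model import RangeError, SourceClass, TimeSeries

__all__ = [
    "FillMethod",
    "FillPolicy",
    "NormalizationSpec",
    "filter_series",
    "fill_gaps",
    "section_average_atline",
    "normalize",
    "denormalize",
]


class FillMethod(str, enum.Enum):
    MEAN = "mean_fill"
    INTERP = "interp_fill"
    ZERO = "zero_fill"
    NONE = "none"


@dataclass
class FillPolicy:
    """Gap-filling method per variable, with a fallback default.

    ``global_mean=True`` switches mean filling from the two adjacent
    neighbours of a gap to the series-wide mean.
    """

    default: FillMethod = FillMethod.INTERP
    per_variable: dict[str, FillMethod] = field(default_factory=dict)
    global_mean: bool = False

    def method_for(self, variable: str) -> FillMethod:
        return FillMethod(self.per_variable.get(variable, self.default))


@dataclass
class NormalizationSpec:
    """Normalization method plus the per-variable statistics for inversion."""

    method: str = "zscore"  # zscore | minmax | none
    location: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)


def filter_series(ts: TimeSeries, window: int = 5) -> TimeSeries:
    """Moving-median smoothing on the same time grid.

    ``window`` must be odd and no longer than the series; endpoints use
    shrunken (truncated) centred windows.  ``window=1`` is the identity.
    """
    n = len(ts)
    if window % 2 == 0 or window < 1:
        raise RangeError(f"window must be odd and positive, got {window}")
    if window > n:
        raise RangeError(f"window {window} exceeds series length {n}")
    half = window // 2
    vals = ts.values
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.nanmedian(vals[lo:hi]) if np.isnan(vals[lo:hi]).any() else np.median(vals[lo:hi])
    return ts.copy_with(values=out)


def fill_gaps(ts: TimeSeries, policy: FillPolicy | FillMethod = FillMethod.INTERP) -> TimeSeries:
    """Replace NaN markers according to the policy; non-missing values are untouched."""
    if isinstance(policy, FillPolicy):
        method = policy.method_for(ts.variable)
        global_mean = policy.global_mean
    else:
        method = FillMethod(policy)
        global_mean = False
    vals = ts.values.copy()
    missing = np.isnan(vals)
    if method == FillMethod.NONE or not missing.any():
        return ts.copy_with(values=vals)
    if method == FillMethod.ZERO:
        vals[missing] = 0.0
        return ts.copy_with(values=vals)
    if missing.all():
        raise RangeError(f"{ts.variable}: all values missing; cannot {method.value}")
    if method == FillMethod.MEAN:
        vals = _mean_fill(vals, global_mean)
    elif method == FillMethod.INTERP:
        good = ~missing
        vals[missing] = np.interp(ts.times[missing], ts.times[good], vals[good])
    return ts.copy_with(values=vals)


def _mean_fill(vals: np.ndarray, global_mean: bool) -> np.ndarray:
    """Fill each gap (run of NaN) with the mean of its flanking neighbours."""
    out = vals.copy()
    if global_mean:
        out[np.isnan(out)] = np.nanmean(vals)
        return out
    n = out.size
    i = 0
    while i < n:
        if np.isnan(out[i]):
            j = i
            while j < n and np.isnan(out[j]):
                j += 1
            left = out[i - 1] if i > 0 else np.nan
            right = out[j] if j < n else np.nan
            neighbours = [v for v in (left, right) if not np.isnan(v)]
            out[i:j] = float(np.mean(neighbours))
            i = j
        else:
            i += 1
    return out


def section_average_atline(ts: TimeSeries, channel_cycle: float = 1.0 / 3.0) -> TimeSeries:
    """Collapse each instrument measurement cycle to a single averaged point.

    Cycles partition the time axis into consecutive windows of
    ``channel_cycle`` hours starting at the first observation.  Readings
    within one cycle are replaced by their arithmetic mean, placed at the
    centroid (mean) of that cycle's reading times, so an affine signal is
    preserved exactly whatever the reading layout; a single reading keeps
    its own timestamp.  Empty cycles emit nothing.
    """
    if ts.source != SourceClass.AT_LINE:
        raise RangeError(f"{ts.variable}: section averaging applies to at-line series only")
    if channel_cycle <= 0:
        raise RangeError("channel_cycle must be positive")
    if len(ts) == 0:
        return ts.copy_with()
    # tolerance keeps readings that sit on a cycle boundary (within 1e-6 of a
    # cycle) in the later cycle instead of merging them into the earlier one
    idx = np.floor((ts.times - ts.times[0]) / channel_cycle + 1e-6).astype(int)
    out_t, out_v = [], []
    for k in np.unique(idx):
        sel = idx == k
        t = ts.times[sel]
        out_t.append(float(np.mean(t)))
        out_v.append(float(np.nanmean(ts.values[sel])))
    return ts.copy_with(times=np.array(out_t), values=np.array(out_v))


def normalize(ts: TimeSeries, spec: NormalizationSpec) -> TimeSeries:
    """Normalize a gap-free series, recording statistics in ``spec`` for inversion."""
    vals = ts.values
    if np.isnan(vals).any():
        raise RangeError(f"{ts.variable}: fill gaps before normalizing")
    if spec.method == "none":
        spec.location[ts.variable], spec.scale[ts.variable] = 0.0, 1.0
        return ts.copy_with()
    if spec.method == "zscore":
        loc, scale = float(np.mean(vals)), float(np.std(vals, ddof=1))
        if scale == 0:
            raise RangeError(f"{ts.variable}: zero variance, z-score undefined")
    elif spec.method == "minmax":
        loc, scale = float(np.min(vals)), float(np.max(vals) - np.min(vals))
        if scale == 0:
            raise RangeError(f"{ts.variable}: constant series, min-max undefined")
    else:
        raise RangeError(f"unknown normalization method {spec.method!r}")
    spec.location[ts.variable], spec.scale[ts.variable] = loc, scale
    return ts.copy_with(values=(vals - loc) / scale)


def denormalize(ts: TimeSeries, spec: NormalizationSpec) -> TimeSeries:
    """Invert :func:`normalize` using the statistics recorded in ``spec``."""
    if ts.variable not in spec.scale:
        raise RangeError(f"{ts.variable}: no recorded normalization statistics")
    loc, scale = spec.location[ts.variable], spec.scale[ts.variable]
    return ts.copy_with(values=ts.values * scale + loc)
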