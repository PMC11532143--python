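"""Rule-based device-fault identification for monitored signals.

An instrument channel is scanned with simple statistical rules over a
rolling time window; the canonical instantiation is the CO2-in-air
reference channel of an off-gas mass spectrometer, which in healthy
operation reads atmospheric CO2 (~0.04%):

* **mean band** — the rolling mean must stay inside [lower, upper]
  (defaults 0.02-0.05%); excursions indicate drift or miscalibration.
* **CV threshold** — the rolling coefficient of variation sd/mean must not
  exceed ``cv_max`` (default 0.1); bursts indicate unstable readings.

Windows are time-based (default 1 h, centred).  Flagged points are merged
into maximal anomalous intervals; intervals closer than one window are
joined, and intervals shorter than the window are tagged ``transient``.
The CV rule is invariant to positive rescaling of the signal; the mean
band is not.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .model import RangeError, TimeSeries

__all__ = [
    "FaultKind",
    "FaultRule",
    "FaultInterval",
    "FaultReport",
    "mean_band_check",
    "cv_check",
    "scan",
    "co2_in_air_rules",
]


class FaultKind(str, enum.Enum):
    MEAN_BAND = "mean_band"
    CV_THRESHOLD = "cv_threshold"


@dataclass(frozen=True)
class FaultRule:
    kind: FaultKind
    lower: float = 0.02
    upper: float = 0.05
    cv_max: float = 0.1
    window: float = 1.0  # hours
    episode_mode: bool = False  # statistic per whole series instead of rolling

    def __post_init__(self) -> None:
        if self.kind == FaultKind.MEAN_BAND and not self.lower < self.upper:
            raise RangeError("mean_band requires lower < upper")
        if self.kind == FaultKind.CV_THRESHOLD and self.cv_max <= 0:
            raise RangeError("cv_threshold requires cv_max > 0")
        if self.window <= 0:
            raise RangeError("window must be positive")


@dataclass
class FaultInterval:
    start: float
    end: float
    kind: FaultKind
    statistic: float  # worst offending value of the rule statistic
    tag: str = ""  # "", "transient" or "indeterminate"


@dataclass
class FaultReport:
    intervals: list[FaultInterval] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "anomalous" if any(iv.tag != "indeterminate" for iv in self.intervals) else "normal"

    def overlapping(self, start: float, end: float) -> list[FaultInterval]:
        return [iv for iv in self.intervals if iv.end >= start and iv.start <= end]


def co2_in_air_rules(window: float = 1.0) -> list[FaultRule]:
    """Default rule set for the CO2-in-air reference channel (percent units)."""
    return [
        FaultRule(kind=FaultKind.MEAN_BAND, lower=0.02, upper=0.05, window=window),
        FaultRule(kind=FaultKind.CV_THRESHOLD, cv_max=0.1, window=window),
    ]


def _rolling_windows(ts: TimeSeries, window: float):
    """Yield (index, slice of values) for a centred time window at each point."""
    t = ts.times
    if t[-1] - t[0] < window:
        raise RangeError(
            f"{ts.variable}: window {window} h longer than series span {t[-1] - t[0]:.3g} h"
        )
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    for i in range(t.size):
        yield i, ts.values[lo[i]:hi[i]]


def _merge(ts: TimeSeries, flags: np.ndarray, stats: np.ndarray, kind: FaultKind,
           window: float, tags: np.ndarray | None = None) -> list[FaultInterval]:
    """Merge flagged points into maximal intervals; join gaps < one window."""
    t = ts.times
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    # contiguous flagged runs -> raw intervals (index pairs)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    # join runs whose time gap is below one window
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if t[s] - t[merged[-1][1]] < window:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    worse = np.abs if kind == FaultKind.CV_THRESHOLD else (lambda x: x)
    intervals: list[FaultInterval] = []
    for s, e in merged:
        seg = slice(s, e + 1)
        seg_stats = stats[seg][flags[seg]]
        stat = float(seg_stats[np.argmax(worse(seg_stats))])
        if tags is not None and tags[seg][flags[seg]].any():
            tag = "indeterminate"
        elif t[e] - t[s] < window:
            tag = "transient"
        else:
            tag = ""
        intervals.append(FaultInterval(start=float(t[s]), end=float(t[e]), kind=kind,
                                       statistic=stat, tag=tag))
    return intervals


def mean_band_check(ts: TimeSeries, rule: FaultRule) -> FaultReport:
    """Flag intervals where the rolling mean leaves [lower, upper]."""
    if rule.kind != FaultKind.MEAN_BAND:
        raise RangeError("rule kind must be mean_band")
    if np.isnan(ts.values).any():
        raise RangeError(f"{ts.variable}: fill gaps before fault scanning")
    n = len(ts)
    means = np.empty(n)
    if rule.episode_mode:
        means[:] = float(np.mean(ts.values))
    else:
        for i, win in _rolling_windows(ts, rule.window):
            means[i] = float(np.mean(win))
    flags = (means < rule.lower) | (means > rule.upper)
    return FaultReport(intervals=_merge(ts, flags, means, FaultKind.MEAN_BAND, rule.window))


def cv_check(ts: TimeSeries, rule: FaultRule) -> FaultReport:
    """Flag intervals where the rolling CV (sample sd / mean) exceeds cv_max.

    Windows with zero mean have undefined CV and are reported as
    ``indeterminate`` rather than anomalous.
    """
    if rule.kind != FaultKind.CV_THRESHOLD:
        raise RangeError("rule kind must be cv_threshold")
    if np.isnan(ts.values).any():
        raise RangeError(f"{ts.variable}: fill gaps before fault scanning")
    n = len(ts)
    cvs = np.zeros(n)
    indet = np.zeros(n, dtype=bool)
    if rule.episode_mode:
        mean = float(np.mean(ts.values))
        if mean == 0:
            indet[:] = True
        else:
            cvs[:] = float(np.std(ts.values, ddof=1)) / mean
    else:
        for i, win in _rolling_windows(ts, rule.window):
            mean = float(np.mean(win))
            if mean == 0:
                indet[i] = True
            elif win.size >= 2:
                cvs[i] = float(np.std(win, ddof=1)) / mean
    flags = (np.abs(cvs) > rule.cv_max) | indet
    return FaultReport(
        intervals=_merge(ts, flags, cvs, FaultKind.CV_THRESHOLD, rule.window, tags=indet)
    )


def scan(ts: TimeSeries, rules: list[FaultRule]) -> FaultReport:
    """Apply every rule; verdict is normal iff no rule fires."""
    if not rules:
        raise RangeError("rule list must be non-empty")
    intervals: list[FaultInterval] = []
    for rule in rules:
        if rule.kind == FaultKind.MEAN_BAND:
            intervals.extend(mean_band_check(ts, rule).intervals)
        elif rule.kind == FaultKind.CV_THRESHOLD:
            intervals.extend(cv_check(ts, rule).intervals)
        else:
            raise RangeError(f"unknown rule kind {rule.kind!r}")
    intervals.sort(key=lambda iv: (iv.start, iv.kind.value))
    return FaultReport(intervals=intervals)
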