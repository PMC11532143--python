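"""Scaled-integer register codec for instrument transport payloads.

Off-gas mass spectrometers and similar instruments often transmit a
measurement over Modbus-style registers as an integer on a fixed transport
scale.  The engineering value is mapped linearly from its detection range
``[scale_lo, scale_hi]`` onto ``[0, full_scale]``:

    transmitted = (measured - scale_lo) / (scale_hi - scale_lo) * full_scale

and decoded by the inverse map.  Encoding rounds half-up to the nearest
integer on the transport scale, so a round trip is exact to within one
quantization step ``(scale_hi - scale_lo) / full_scale``.

Out-of-range inputs raise :class:`~fermfuse.model.RangeError` rather than
clamping, so sensor saturation surfaces to the fault checks instead of
being silently hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import RangeError

__all__ = ["ScaleSpec", "encode", "decode"]


@dataclass(frozen=True)
class ScaleSpec:
    """Register scaling of one transmitted variable.

    scale_lo / scale_hi: preset minimum / maximum detection values
    (engineering units); full_scale: maximum transmission value (counts).
    """

    scale_lo: float
    scale_hi: float
    full_scale: float = 65535.0

    def __post_init__(self) -> None:
        if not self.scale_hi > self.scale_lo:
            raise RangeError(f"scale_hi ({self.scale_hi}) must exceed scale_lo ({self.scale_lo})")
        if not self.full_scale > 0:
            raise RangeError(f"full_scale must be positive, got {self.full_scale}")

    @property
    def quantum(self) -> float:
        """Engineering-unit size of one transport count."""
        return (self.scale_hi - self.scale_lo) / self.full_scale


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def encode(measured, s: ScaleSpec):
    """Encode engineering value(s) to integer counts on the transport scale.

    Scalar in, scalar out; array in, array out.
    """
    arr = np.asarray(measured, dtype=float)
    if np.any(arr < s.scale_lo) or np.any(arr > s.scale_hi):
        raise RangeError(
            f"measured value outside detection range [{s.scale_lo}, {s.scale_hi}]"
        )
    raw = _round_half_up((arr - s.scale_lo) / (s.scale_hi - s.scale_lo) * s.full_scale)
    if np.isscalar(measured) or arr.ndim == 0:
        return float(raw)
    return raw


def decode(raw, s: ScaleSpec):
    """Decode transport counts back to engineering units (inverse of encode)."""
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < 0) or np.any(arr > s.full_scale):
        raise RangeError(f"raw value outside transport range [0, {s.full_scale}]")
    out = s.scale_lo + arr / s.full_scale * (s.scale_hi - s.scale_lo)
    if np.isscalar(raw) or arr.ndim == 0:
        return float(out)
    return out
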