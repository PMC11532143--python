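"""Fused physiological parameters: off-gas balances and rate/yield algebra.

CER/OUR from the inert-gas (N2) balance
---------------------------------------
With inlet air flow ``F_air_in`` (ml/min), broth mass ``m`` (kg) and gas
mole fractions in percent, nitrogen is treated as inert so the outlet flow
is corrected by the N2 ratio:

    CER = F_air_in / m * (y_N2_in * y_CO2_out / y_N2_out - y_CO2_in) / 100 * 60 / 22.4
    OUR = F_air_in / m * (y_O2_in - y_N2_in * y_O2_out / y_N2_out) / 100 * 60 / 22.4
    RQ  = CER / OUR

giving mmol * kg^-1 * h^-1 (22.4 L/mol molar volume at STP; 60 converts
per-minute flow to per-hour).  Compositions in percent require the /100
conversion to mole fraction for the units to close; a ``percent=False``
flag accepts fraction-of-one inputs instead.  RQ is NaN where OUR = 0.

Rates at three levels
---------------------
From a component balance  dM/dt = F_in*c_in - F_out*c_out + R + T  the
process-level reaction rate R (amount/time) is recovered, then scaled to
the reactor level  r = R / m_avg  and the cell-specific level
q = R / (OD*m)_avg.  Yields are rate ratios  Y_i/j = R_i/R_j, identical at
every level when the denominators are shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FusedFrame, RangeError, TimeSeries

__all__ = [
    "MOLAR_VOLUME_L_PER_MOL",
    "GasExchangeRecord",
    "PhysioRates",
    "BalanceInput",
    "RateTriple",
    "gas_rates",
    "estimate_dMdt",
    "process_rate",
    "specific_rates",
    "yield_coefficient",
    "add_gas_rates",
]

MOLAR_VOLUME_L_PER_MOL = 22.4  # STP molar volume as conventionally used; not T-corrected


@dataclass
class GasExchangeRecord:
    """Inlet/outlet gas compositions, air flow and broth mass at one instant.

    Fractions are percent (0-100) by default; set ``percent=False`` for
    mole fractions of one.  Arrays are accepted everywhere for vectorised
    evaluation along a fused grid.
    """

    f_air_in: float | np.ndarray  # ml/min
    m: float | np.ndarray  # kg broth
    y_co2_in: float | np.ndarray
    y_o2_in: float | np.ndarray
    y_n2_in: float | np.ndarray
    y_co2_out: float | np.ndarray
    y_o2_out: float | np.ndarray
    y_n2_out: float | np.ndarray
    percent: bool = True


@dataclass
class PhysioRates:
    """CER/OUR in mmol * kg^-1 * h^-1 and the dimensionless RQ (NaN if OUR=0)."""

    cer: float | np.ndarray
    our: float | np.ndarray
    rq: float | np.ndarray


@dataclass
class BalanceInput:
    """Terms of a component balance over one differencing interval."""

    inflow: float = 0.0  # F_in * c_in, amount/time
    outflow: float = 0.0  # F_out * c_out, amount/time
    transfer: float = 0.0  # T, amount/time transferred to other terms
    m_avg: float = 1.0  # mean broth mass, kg
    od_m_avg: float = 1.0  # mean OD*m over the interval


@dataclass
class RateTriple:
    """One substance's rate at process (R), reactor (r) and cell (q) level."""

    R: float
    r: float
    q: float


def gas_rates(g: GasExchangeRecord) -> PhysioRates:
    """Carbon-dioxide evolution and oxygen uptake rates from the N2 balance."""
    n2_out = np.asarray(g.y_n2_out, dtype=float)
    if np.any(n2_out <= 0):
        raise RangeError("y_n2_out must be positive (inert-gas divisor)")
    m = np.asarray(g.m, dtype=float)
    if np.any(m <= 0):
        raise RangeError("broth mass must be positive")
    conv = 0.01 if g.percent else 1.0
    factor = np.asarray(g.f_air_in, dtype=float) / m * conv * 60.0 / MOLAR_VOLUME_L_PER_MOL
    cer = factor * (np.asarray(g.y_n2_in, dtype=float) * np.asarray(g.y_co2_out, dtype=float) / n2_out
                    - np.asarray(g.y_co2_in, dtype=float))
    our = factor * (np.asarray(g.y_o2_in, dtype=float)
                    - np.asarray(g.y_n2_in, dtype=float) * np.asarray(g.y_o2_out, dtype=float) / n2_out)
    with np.errstate(divide="ignore", invalid="ignore"):
        rq = np.where(our != 0, cer / np.where(our != 0, our, 1.0), np.nan)
    if np.isscalar(g.f_air_in) and np.ndim(cer) == 0:
        return PhysioRates(cer=float(cer), our=float(our), rq=float(rq))
    return PhysioRates(cer=cer, our=our, rq=rq)


def estimate_dMdt(series: TimeSeries) -> TimeSeries:
    """Time derivative of a cumulative amount: central differences inside,
    one-sided at the ends.  Exact for affine signals."""
    n = len(series)
    if n < 3:
        raise RangeError(f"{series.variable}: need >= 3 points for differencing")
    if np.isnan(series.values).any():
        raise RangeError(f"{series.variable}: fill gaps before differencing")
    d = np.gradient(series.values, series.times)
    return series.copy_with(values=d)


def process_rate(bi: BalanceInput, dM_dt: float) -> float:
    """Reaction rate R from the component balance (R = dM/dt - in + out - T)."""
    return dM_dt - bi.inflow + bi.outflow - bi.transfer


def specific_rates(R: float, bi: BalanceInput) -> RateTriple:
    """Scale a process-level rate to reactor level (per kg broth) and cell level."""
    if bi.m_avg <= 0:
        raise RangeError(f"m_avg must be positive, got {bi.m_avg}")
    if bi.od_m_avg <= 0:
        raise RangeError(f"od_m_avg must be positive, got {bi.od_m_avg}")
    return RateTriple(R=R, r=R / bi.m_avg, q=R / bi.od_m_avg)


def yield_coefficient(i: RateTriple, j: RateTriple, rtol: float = 1e-9) -> float:
    """Yield Y_i/j = R_i/R_j; asserts the r- and q-level ratios agree.

    The three ratios coincide exactly when both substances share the same
    averaged denominators; a mismatch beyond ``rtol`` indicates the two
    rate triples were built from different intervals.
    """
    if j.R == 0 or j.r == 0 or j.q == 0:
        raise RangeError("denominator rate is zero; yield undefined")
    y = i.R / j.R
    for other in (i.r / j.r, i.q / j.q):
        if abs(other - y) > rtol * max(1.0, abs(y)):
            raise RangeError(
                f"yield level-invariance violated: R-ratio {y} vs {other}"
            )
    return y


def add_gas_rates(
    frame: FusedFrame,
    *,
    flow: str = "air_flow",
    mass: str = "weight",
    co2_out: str = "co2_out",
    o2_out: str = "o2_out",
    n2_out: str = "n2_out",
    inlet: tuple[float, float, float] = (0.04, 20.96, 79.00),
    percent: bool = True,
) -> FusedFrame:
    """Append CER/OUR/RQ columns to a fused frame.

    ``inlet`` is (y_co2_in, y_o2_in, y_n2_in); outlet compositions and the
    flow/mass channels are named fused columns.  Returns the same frame
    with three new columns and provenance entries.
    """
    for col in (flow, mass, co2_out, o2_out, n2_out):
        if col not in frame.data.columns:
            raise RangeError(f"fused frame lacks required column {col!r}")
    rec = GasExchangeRecord(
        f_air_in=frame.column(flow),
        m=frame.column(mass),
        y_co2_in=inlet[0],
        y_o2_in=inlet[1],
        y_n2_in=inlet[2],
        y_co2_out=frame.column(co2_out),
        y_o2_out=frame.column(o2_out),
        y_n2_out=frame.column(n2_out),
        percent=percent,
    )
    rates = gas_rates(rec)
    out = frame.data.copy()
    out["CER"] = rates.cer
    out["OUR"] = rates.our
    out["RQ"] = rates.rq
    prov = dict(frame.provenance)
    for name in ("CER", "OUR", "RQ"):
        prov[name] = {"source": "derived", "unit": "mmol/kg/h" if name != "RQ" else "-",
                      "method": "gas_balance", "steps": ["gas_rates"], "extrapolated": False}
    return FusedFrame(times=frame.times, data=out, provenance=prov, meta=frame.meta)
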