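"""Synthetic fed-batch fermentation generator with known ground truth.

The generator emulates the three stream classes the fusion pipeline
consumes, at their native cadences (online every minute, at-line every
~20 min per channel, offline every 2-4 h at irregular times), with
Gaussian sensor noise and optional injected device anomalies.

The biology is deliberately minimal — the pipeline, not the kinetics, is
under test:

* biomass follows a lagged logistic, X(t) = K / (1 + (K/X0 - 1) e^{-mu (t-lag)});
* oxygen uptake is growth-linked plus maintenance,
  OUR = a * dX/dt + m_O2 * X  (mmol O2 kg^-1 h^-1);
* CO2 evolution follows a target respiratory quotient, CER = RQ * OUR;
* outlet gas fractions are obtained by *inverting* the inert-gas balance
  (N2 closure to 100%), so that running the off-gas equations on a
  noiseless generated batch reproduces the ground-truth CER/OUR exactly;
* broth mass rises linearly once feeding starts; DO, agitation and base
  pump are coupled to OUR the way cascade control couples them in a real
  reactor; titer accumulates in proportion to integrated biomass.

Every batch is deterministic given its seed, and ships with a
:class:`GroundTruth` sidecar holding the noiseless trajectories and all
generator parameters, so tests never re-derive the truth they check
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .derived import MOLAR_VOLUME_L_PER_MOL
from .model import BatchDataset, BatchMeta, RangeError, SourceClass, TimeSeries

__all__ = [
    "INLET_AIR_PERCENT",
    "AnomalySpec",
    "SimConfig",
    "GroundTruth",
    "simulate_batch",
    "inject_anomaly",
    "simulate_study",
]

# dry air, percent: (CO2, O2, N2); sums to 100 exactly
INLET_AIR_PERCENT = (0.04, 20.96, 79.00)

DEFAULT_NOISE = {
    "ph": 0.01, "do": 0.5, "temperature": 0.05, "agitation": 2.0,
    "air_flow": 1.0, "weight": 0.0005, "feed_rate": 0.05, "acid_pump": 0.01,
    "base_pump": 0.01, "inspection_pump": 0.01,
    "co2_out": 0.01, "o2_out": 0.02, "n2_out": 0.02, "co2_air": 0.001,
    "biomass": 0.3, "titer": 0.05,
}


@dataclass
class AnomalySpec:
    """A device fault to inject: step, drift or variance burst."""

    variable: str
    kind: str  # step | drift | variance_burst
    start: float  # hours
    duration: float  # hours
    magnitude: float  # step/drift height in signal units; burst target CV


@dataclass
class SimConfig:
    """Generator parameters; defaults are a realistic 24 h fed-batch run."""

    duration_h: float = 24.0
    online_cadence_h: float = 1.0 / 60.0
    atline_cadence_h: float = 1.0 / 3.0
    offline_interval_h: tuple[float, float] = (2.0, 4.0)
    # growth
    lag_h: float = 2.0
    mu_max: float = 0.35  # 1/h
    x0: float = 0.2  # OD600 at inoculation
    capacity: float = 40.0  # OD600 carrying capacity
    # respiration
    o2_per_growth: float = 3.0  # mmol O2 per OD per kg, growth-linked
    o2_maintenance: float = 1.2  # mmol O2 per OD per kg per h
    rq: float = 1.05  # target respiratory quotient (constant profile)
    # reactor
    air_flow_ml_min: float = 1000.0
    m0_kg: float = 1.0
    feed_rate_kg_h: float = 0.008
    feed_start_h: float = 4.0
    titer_per_od_h: float = 0.01  # g/L product per (OD * h)
    inlet: tuple[float, float, float] = INLET_AIR_PERCENT
    # sampling
    noise_sigma: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    seed: int = 0
    anomalies: list[AnomalySpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.online_cadence_h <= 0 or self.atline_cadence_h <= 0:
            raise RangeError("cadences must be positive")
        if self.duration_h < 2 * self.offline_interval_h[0]:
            raise RangeError("duration must cover at least two offline samples")
        if any(s < 0 for s in self.noise_sigma.values()):
            raise RangeError("noise sigma must be non-negative")

    def sigma(self, variable: str) -> float:
        return float(self.noise_sigma.get(variable, 0.0))


@dataclass
class GroundTruth:
    """Noiseless trajectories on the online grid plus generator provenance."""

    times: np.ndarray
    biomass: np.ndarray
    cer: np.ndarray
    our: np.ndarray
    rq: np.ndarray
    anomalies: list[AnomalySpec] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _biomass(cfg: SimConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lagged logistic biomass and its analytic derivative."""
    k, x0 = cfg.capacity, cfg.x0
    z = np.exp(-cfg.mu_max * (t - cfg.lag_h))
    x = k / (1.0 + (k / x0 - 1.0) * z)
    dx = cfg.mu_max * x * (1.0 - x / k)
    return x, dx


def _respiration(cfg: SimConfig, t: np.ndarray):
    x, dx = _biomass(cfg, t)
    our = cfg.o2_per_growth * dx + cfg.o2_maintenance * x
    cer = cfg.rq * our
    return x, cer, our


def _broth_mass(cfg: SimConfig, t: np.ndarray) -> np.ndarray:
    return cfg.m0_kg + cfg.feed_rate_kg_h * np.clip(t - cfg.feed_start_h, 0.0, None)


def invert_gas_balance(cer, our, f_air_in, m, inlet=INLET_AIR_PERCENT):
    """Outlet gas fractions (percent) producing given CER/OUR under N2 closure.

    Solves the off-gas balance equations for (y_co2_out, y_o2_out,
    y_n2_out) given inlet composition, air flow (ml/min) and broth mass
    (kg), with the outlet fractions constrained to sum to 100%.
    """
    co2_in, o2_in, n2_in = inlet
    scale = np.asarray(m, dtype=float) / np.asarray(f_air_in, dtype=float) \
        * MOLAR_VOLUME_L_PER_MOL / 60.0 * 100.0
    a = np.asarray(cer, dtype=float) * scale  # n2_in*co2_out/n2_out - co2_in
    b = np.asarray(our, dtype=float) * scale  # o2_in - n2_in*o2_out/n2_out
    denom = n2_in + co2_in + o2_in + a - b
    n2_out = 100.0 * n2_in / denom
    co2_out = (a + co2_in) * n2_out / n2_in
    o2_out = (o2_in - b) * n2_out / n2_in
    if np.any(co2_out < 0) or np.any(o2_out < 0) or np.any(n2_out <= 0):
        raise RangeError("configuration yields negative outlet gas fractions")
    return co2_out, o2_out, n2_out


def simulate_batch(cfg: SimConfig | None = None, batch_id: str = "sim") -> tuple[BatchDataset, GroundTruth]:
    """Generate one batch (online + at-line + offline streams) and its truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    grid = np.round(np.arange(0.0, cfg.duration_h + 1e-9, cfg.online_cadence_h), 9)
    x, cer, our = _respiration(cfg, grid)
    m = _broth_mass(cfg, grid)
    rq = np.full_like(our, cfg.rq)

    meta = BatchMeta(
        batch_id=batch_id,
        strain="synthetic producer",
        medium="defined glucose",
        operation_conditions={
            "air_flow_ml_min": cfg.air_flow_ml_min,
            "inlet_co2_pct": cfg.inlet[0],
            "inlet_o2_pct": cfg.inlet[1],
            "inlet_n2_pct": cfg.inlet[2],
        },
        control_strategy="DO cascade (synthetic)",
    )
    b = BatchDataset(meta=meta)

    def noisy(name: str, values: np.ndarray) -> np.ndarray:
        s = cfg.sigma(name)
        return values + (rng.normal(0.0, s, values.shape) if s > 0 else 0.0)

    our_peak = float(our.max())
    online = {
        "ph": 7.0 - 0.25 * x / cfg.capacity,
        "do": np.clip(95.0 - 1.4 * our, 15.0, None),
        "temperature": np.full_like(grid, 37.0),
        "agitation": 300.0 + 6.0 * our,
        "air_flow": np.full_like(grid, cfg.air_flow_ml_min),
        "weight": m,
        "feed_rate": np.where(grid >= cfg.feed_start_h, cfg.feed_rate_kg_h * 1000.0, 0.0),
        "acid_pump": 0.5 + 0.3 * x / cfg.capacity,
        "base_pump": 0.2 + 0.8 * our / max(our_peak, 1e-12),
        "inspection_pump": np.full_like(grid, 1.0),
    }
    units = {"ph": "-", "do": "%", "temperature": "degC", "agitation": "rpm",
             "air_flow": "ml/min", "weight": "kg", "feed_rate": "g/h",
             "acid_pump": "ml/h", "base_pump": "ml/h", "inspection_pump": "ml/h"}
    for name, vals in online.items():
        b.add(TimeSeries(variable=name, unit=units[name], source=SourceClass.ONLINE,
                         times=grid, values=noisy(name, vals)))

    # at-line off-gas: one reading per instrument cycle
    at_t = np.round(np.arange(0.0, cfg.duration_h + 1e-9, cfg.atline_cadence_h), 9)
    x_a, cer_a, our_a = _respiration(cfg, at_t)
    m_a = _broth_mass(cfg, at_t)
    co2_out, o2_out, n2_out = invert_gas_balance(cer_a, our_a, cfg.air_flow_ml_min, m_a, cfg.inlet)
    atline = {
        "co2_out": co2_out,
        "o2_out": o2_out,
        "n2_out": n2_out,
        "co2_air": np.full_like(at_t, cfg.inlet[0]),
    }
    for name, vals in atline.items():
        b.add(TimeSeries(variable=name, unit="%", source=SourceClass.AT_LINE,
                         times=at_t, values=noisy(name, vals)))

    # offline assays at irregular 2-4 h intervals
    off_t = [0.0]
    lo, hi = cfg.offline_interval_h
    while off_t[-1] < cfg.duration_h:
        off_t.append(off_t[-1] + float(rng.uniform(lo, hi)))
    off_t = np.array([t for t in off_t if t <= cfg.duration_h])
    x_o, _, _ = _respiration(cfg, off_t)
    # product accumulates with integrated biomass (growth-independent term)
    x_fine = _biomass(cfg, grid)[0]
    titer_fine = cfg.titer_per_od_h * np.concatenate(
        [[0.0], np.cumsum(0.5 * (x_fine[1:] + x_fine[:-1]) * np.diff(grid))]
    )
    titer_o = np.interp(off_t, grid, titer_fine)
    b.add(TimeSeries(variable="biomass", unit="OD600", source=SourceClass.OFFLINE,
                     times=off_t, values=noisy("biomass", x_o)))
    b.add(TimeSeries(variable="titer", unit="g/L", source=SourceClass.OFFLINE,
                     times=off_t, values=noisy("titer", titer_o)))

    gt = GroundTruth(times=grid, biomass=x, cer=cer, our=our, rq=rq,
                     params={"config": replace(cfg)})
    for spec in cfg.anomalies:
        b, gt = inject_anomaly(b, spec, gt, seed=int(rng.integers(2**31 - 1)))
    return b, gt


def inject_anomaly(
    b: BatchDataset,
    spec: AnomalySpec,
    gt: GroundTruth | None = None,
    seed: int = 0,
) -> tuple[BatchDataset, GroundTruth | None]:
    """Apply a step, drift or variance burst to one variable over an interval."""
    if spec.variable not in b.series:
        raise RangeError(f"unknown variable {spec.variable!r}")
    ts = b.series[spec.variable]
    t0, t1 = spec.start, spec.start + spec.duration
    span = b.span
    if t0 < span[0] - 1e-9 or t1 > span[1] + 1e-9:
        raise RangeError(f"anomaly interval [{t0}, {t1}] outside batch span {span}")
    sel = (ts.times >= t0) & (ts.times <= t1)
    vals = ts.values.copy()
    if spec.kind == "step":
        vals[sel] += spec.magnitude
    elif spec.kind == "drift":
        tt = ts.times[sel]
        vals[sel] += spec.magnitude * (tt - t0) / max(t1 - t0, 1e-12)
    elif spec.kind == "variance_burst":
        # sustained reading-to-reading oscillation with relative amplitude
        # `magnitude`, so the realized CV over any sub-window of the interval
        # is ~magnitude (a Gaussian draw of few points can realize far less
        # variance than requested, making the injected label dishonest)
        rng = np.random.default_rng(seed)
        base = float(np.mean(np.abs(vals[sel]))) if sel.any() else 1.0
        k = int(sel.sum())
        signs = (-1.0) ** np.arange(k)
        vals[sel] += spec.magnitude * base * signs * (1.0 + 0.15 * rng.normal(size=k))
    else:
        raise RangeError(f"unknown anomaly kind {spec.kind!r}")
    b.series[spec.variable] = ts.copy_with(values=vals)
    if gt is not None:
        gt.anomalies = list(gt.anomalies) + [spec]
    return b, gt


def simulate_study(
    n_batches: int,
    cfg: SimConfig | None = None,
    outliers: dict[int, str] | None = None,
    jitter: float = 0.05,
    seed: int = 0,
) -> list[tuple[BatchDataset, GroundTruth]]:
    """Generate a multi-batch study with parameter jitter and designated outliers.

    ``outliers`` maps batch index to a failure mode: ``"stunted"`` (sharply
    limited growth, as under a nutrient deficiency) or ``"contaminated"``
    (early takeover: faster initial growth, collapsed RQ).  Remaining
    batches differ only by small relative jitter on growth parameters.
    """
    if n_batches < 2:
        raise RangeError("a study needs at least 2 batches")
    cfg = cfg or SimConfig()
    outliers = outliers or {}
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_batches):
        j = lambda: float(1.0 + rng.normal(0.0, jitter))  # noqa: E731
        bcfg = replace(
            cfg,
            mu_max=cfg.mu_max * j(),
            capacity=cfg.capacity * j(),
            lag_h=max(cfg.lag_h * j(), 0.1),
            seed=int(rng.integers(2**31 - 1)),
        )
        mode = outliers.get(i)
        if mode == "stunted":
            bcfg = replace(bcfg, capacity=cfg.capacity * 0.25, mu_max=cfg.mu_max * 0.5)
        elif mode == "contaminated":
            bcfg = replace(bcfg, mu_max=cfg.mu_max * 1.8, lag_h=0.2, rq=cfg.rq * 0.7)
        elif mode is not None:
            raise RangeError(f"unknown outlier mode {mode!r}")
        out.append(simulate_batch(bcfg, batch_id=f"batch{i + 1}"))
    return out
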