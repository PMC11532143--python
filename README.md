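# fermfuse

Multi-rate fermentation data fusion, monitoring and soft sensing.

A fermentation experiment produces three kinds of record that never share a
clock: *online* bioreactor sensors sampled every minute (pH, DO,
temperature, agitation, air flow, broth weight, pump rates), *at-line*
off-gas mass-spectrometry compositions read once per ~20-minute instrument
cycle, and *offline* lab assays (biomass OD600, titer) every 2–4 hours.
`fermfuse` is for bioprocess engineers and data scientists who need those
streams on one time grid before anything else can happen: physiological
parameters, device-fault screening, cross-batch comparison, or a biomass
soft sensor running on the live stream.

## What it computes

**Fusion.** At-line cycles are section-averaged, every stream is aligned to
the online grid by nearest-time or piecewise-linear (degree-1 Lagrange)
interpolation, and offline samples are anchored to their nearest grid time
and interpolated between anchors, with per-column provenance.

**Off-gas balances.** Treating N₂ as inert, with inlet flow F (ml/min),
broth mass m (kg) and percent mole fractions y:

    CER = F/m · (y_N2,in · y_CO2,out / y_N2,out − y_CO2,in)/100 · 60/22.4
    OUR = F/m · (y_O2,in − y_N2,in · y_O2,out / y_N2,out)/100 · 60/22.4
    RQ  = CER / OUR

in mmol·kg⁻¹·h⁻¹.  Component balances dM/dt = F_in·c_in − F_out·c_out + R + T
yield process rates R, reactor rates r = R/m_avg, cell-specific rates
q = R/(OD·m)_avg, and yields Y_i/j = R_i/R_j (identical at all three levels).

**Fault rules.** Rolling mean-band (CO₂-in-air within 0.02–0.05%) and
rolling coefficient-of-variation (CV ≤ 0.1) checks over a 1 h window, with
merged anomaly intervals and a normal/anomalous verdict.

**Analytics.** A Spearman screen of process factors against titer/rate/yield
targets, and two PCA views of a multi-batch study: batches as score-plane
points (outlier batches separate) and per-batch PC trajectories with
Savitzky–Golay smoothing and loadings (excursions attributable to
variables).

**Soft sensing.** Feature assembly from the fused grid, an exact 8:2
train/validation split, a pluggable regressor (reference: small MLP; linear
baseline), and streaming prediction in original units.

A synthetic fed-batch generator (lagged logistic growth, respiration-coupled
sensors, invertible off-gas balance, fault injection) provides fully
ground-truthed batches for every check; see `docs/methods.md`.

## Worked example

```python
import numpy as np
import fermfuse as ff

batch, truth = ff.simulate_batch(ff.SimConfig(duration_h=24.0, seed=7), batch_id="demo")
frame = ff.add_gas_rates(ff.fuse_batch(batch))   # fused 1-min grid + CER/OUR/RQ
for t in (4.0, 12.0, 20.0):
    i = int(np.argmin(np.abs(frame.times - t)))
    print(f"t={t:5.1f} h  CER={frame.column('CER')[i]:7.2f}  OUR={frame.column('OUR')[i]:7.2f}"
          f"  RQ={frame.column('RQ')[i]:5.3f}  biomass={frame.column('biomass')[i]:6.2f} OD")
```

prints

```
t=  4.0 h  CER=   0.71  OUR=   1.02  RQ=0.698  biomass=  0.61 OD
t= 12.0 h  CER=  12.58  OUR=  12.66  RQ=0.993  biomass=  5.95 OD
t= 20.0 h  CER=  45.74  OUR=  43.15  RQ=1.060  biomass= 29.00 OD
```

Respiration rates climb with biomass along the logistic growth curve, and
the estimated RQ converges on the generator's target (1.05) once gas
exchange rises above the spectrometer noise — at 4 h respiration is so low
that the composition differences are noise-dominated, which is exactly why
the fault module watches the spectrometer's reference channel.  Against the
generator's ground truth, the fused OUR is accurate to ~1% (median) once
the culture is respiring (t ≥ 8 h).

The same pipeline from the shell:

```
fermfuse --seed 7 simulate run1 --duration 24
fermfuse fuse run1                     # -> run1/fused.csv (+ provenance sidecar)
fermfuse derive run1/fused.csv         # appends CER, OUR, RQ
fermfuse fault-scan run1/atline.csv -v co2_air    # exit 1 if anomalous
```

Other subcommands: `preprocess`, `analyze spearman|pca-flat|pca-time`,
`soft-sensor train|predict`, `decode` (register counts → engineering
units), `export` (CSV / multi-sheet XLSX).

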