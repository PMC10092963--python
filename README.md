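# hepaflow

Signal processing for a combined non-invasive liver-function sensor:
**indocyanine green (ICG) clearance by optical densitometry** and
**microcirculatory blood-flow velocity by dynamic light scattering (DLS)**,
both measured at a finger.

ICG is removed from blood almost exclusively by the liver, so the
exponential rate at which its concentration decays — the *plasma
disappearance rate* (PDR, %/min) — is a standard liver-function index used
for diagnosis and surgical planning. Microcirculatory velocity (normally
0.5–3 mm/s in skin capillaries, falling as low as 0.05 mm/s in diffuse
liver disease) is the complementary hemodynamic signal the same sensor
head can record. This package implements the full estimation chain for
both channels, and a synthetic-signal generator with known ground truth so
every stage is validated by parameter recovery — no hardware or patient
data required. It is aimed at researchers building or evaluating such
optical sensors and at anyone needing a tested reference implementation of
the two estimators.

## The two estimators

**Densitometry → PDR.** Transmitted light obeys the Beer–Lambert law; with
intensity read as voltage u on the photodiode load,

    c = (1/(ε·z)) · log10(u0/u),        u = u0·10^(−ε·c·z),

and after the recirculation transient ends at t₁ the concentration decays
as c(t) = c₁·exp(−0.01·PDR·(t−t₁)). The double-log transform
f(t) = −ln[A(t)/A(t₁)]·100 % (A = absorbance) is linear with slope PDR,
estimated by ordinary least squares. The closed-form error model

    Δc = ln10·Δu/(ε·z·u0) · √(1 + exp(2·ln10·ε·c·z))

quantifies how the concentration error explodes at high dye load, bounding
the usable concentration range. Trace segmentation (baseline → injection
t₀ → recirculation peak → elimination start t₁) is automatic.

**DLS → velocity.** The normalized intensity autocorrelation of scattered
laser speckle decays as G(τ) = exp(−(τ/τc)²); the correlation time τc is
read at the 1/e level and converts to velocity through the optical-scheme
coefficient K:

    K = [ω² + σ²·Δx²]^(−1/2),  Δx = λ·l/(π·ω),  ϑ = 1/(τc·K).

G(τ) is computed by the Wiener–Khinchin theorem (FFT of the periodogram,
mean-subtracted, zero-padded). Ten replicate records are averaged per
measurement.

## Worked example

Simulate a clearance test with true PDR = 20 %/min and recover it:

```bash
hepaflow simulate clearance --seed 7 --out trace.csv --truth truth.json
hepaflow pdr trace.csv
```

```json
{
  "status": "ok",
  "pdr_pct_per_min": 20.01778335805507,
  "c1_mg_per_l": 3.09050723949473,
  "r_squared": 0.9999558593199701,
  "n_points": 754,
  "segmentation": {
    "t0_min": 1.0166666666666666,
    "peak_time_min": 1.6166666666666667,
    "t1_min": 2.45,
    "u0_v": 0.9997513498264635
  }
}
```

The injection was placed at 1.0 min and the recirculation end at 2.5 min;
segmentation finds them at 1.017 and 2.45 min, and the fitted slope
20.018 %/min recovers the true 20 %/min within 0.1 % despite the 10⁻³
relative voltage noise. `c1_mg_per_l` is the dye concentration at t₁
(truth: 3.0 mg/L).

The same round trip for the DLS channel, in Python:

```python
from hepaflow.synth import SpeckleScenario, simulate_speckle
from hepaflow.dls import aggregate_replicates

scen = SpeckleScenario(velocity_true=1.0, seed=7)   # 10 replicates, snr 10
traces, truth = simulate_speckle(scen)
est = aggregate_replicates(traces, scen.geometry)
print(est.mean_velocity, est.sd_velocity)           # 1.052 0.016 (mm/s)
```

A true velocity of 1 mm/s (correlation time 51.9 µs) is recovered as
1.052 ± 0.016 mm/s — the ≈5 % high readout is the expected noise-floor
bias of the lag-0-normalized 1/e estimator at snr = 10 (see
`docs/methods.md`).

Other CLI verbs: `hepaflow velocity` (replicate speckle CSVs → velocity
report), `hepaflow sweep` (in-silico flow-sweep calibration),
`hepaflow joint-report` (both channels in one JSON report; schema in
`docs/report_schema.json`), `hepaflow simulate speckle`.

## Layout

- `src/hepaflow/densitometry.py` — Beer–Lambert transduction, uncertainty
  model, trace segmentation, PDR fit
- `src/hepaflow/dls.py` — autocorrelation, correlation time, geometry
  coefficient, replicate aggregation
- `src/hepaflow/synth.py` — ground-truth signal generators and the flow
  sweep
- `src/hepaflow/io.py`, `src/hepaflow/cli.py` — CSV traces, validated
  YAML/JSON configuration, joint report, command line
- `docs/methods.md` — models, parameter defaults, numerical choices,
  known biases and limitations
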