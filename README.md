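# anshrv

Neurotransmitter-kinetics simulation of heart-rate variability (HRV),
built to study how progressive cholinergic depletion — the hallmark
neurochemistry of Alzheimer's disease (AD) — reshapes the cardiac
autonomic profile.

## The model

Heart rate is controlled by the two autonomic branches: the sympathetic
system via norepinephrine (NE) and the vagal/parasympathetic system via
acetylcholine (ACh). `anshrv` models each branch as a stochastically
stimulated release–clearance chain:

* a stimulus train (one vagal input per 2–4 s, respiratory band; one
  sympathetic input every tens of seconds) releases a quantum of
  transmitter into the **neuroeffector junction** (concentration `C_J`,
  fast first-order clearance), which feeds the **extra-junctional
  space** (`C_E`, slow clearance);
* a cooperative receptor transduction maps concentration to effect,
  `signal = g * f(wJ·C_J + wE·C_E)`, linear for NE and strongly
  supra-linear (Hill-type, two receptor populations) for ACh;
* the branch signals combine into the autonomic drive

      m(t) = m0 + S(t) + V(t),        m(t) > 0,

  with `S ≥ 0` sympathetic, `V ≤ 0` vagal and `m0 = 1` the intrinsic
  (denervated) drive;
* an integral pulse frequency modulation (IPFM) pacemaker fires a beat
  whenever `∫ m(t)/T0 dt` crosses an integer, yielding the RR-interval
  series, to which zero-mean Gaussian noise (SD 10 ms) is added.

Cholinergic depletion is a scale `α ∈ (0, 1]` applied to the ACh
concentration (several application levels are supported; the headline
protocol scales the junctional concentration).  Because the transduction
is cooperative, a modest transmitter loss produces a collapse of vagal
heart-rate modulation — the mechanism behind the sharp autonomic
deterioration the model reproduces.

On top of the simulator sit a standard short-term HRV feature battery
(SDNN, RMSSD; Welch and Burg-AR band powers with LF = 0.04–0.15 Hz,
HF = 0.15–0.40 Hz, normalized units, LF/HF; Poincaré SD1/SD2), the
10-state depletion protocol (`α` = 1.00 → 0.55 in steps of 0.05) with
calibration against the published simulated-feature table, a synthetic
control-vs-AD cohort generator, and an exact Mann–Whitney comparison
engine.

## Worked example

```python
import anshrv

# one 5-minute recording at 70% ACh availability
cfg = anshrv.default_config(alpha=0.70, seed=1)
rr = anshrv.simulate_rr(cfg)
f = anshrv.extract_features(rr.rr_ms, rr.beat_times_s)
print(f"{len(rr)} beats, mean RR {f.mean_rr_ms:.0f} ms, "
      f"SDNN {f.sdnn_ms:.1f} ms, LF/HF {f.lf_hf:.2f}")

# the full 10-state progression (seed-averaged)
table = anshrv.run_progression(n_seeds=10, base_seed=0)
print(table[["state", "ach_scale", "lf_nu", "hf_nu", "lf_hf"]].round(2))
print(anshrv.trend_check(table))
```

prints

```
531 beats, mean RR 564 ms, SDNN 24.4 ms, LF/HF 7.78
 state  ach_scale  lf_nu  hf_nu  lf_hf
     1       1.00  32.50  67.50   0.50
     2       0.95  43.72  56.28   0.79
     3       0.90  55.98  44.02   1.30
     4       0.85  71.81  28.19   2.59
     5       0.80  82.33  17.67   4.74
     6       0.75  86.45  13.55   6.44
     7       0.70  88.30  11.70   7.63
     8       0.65  89.21  10.79   8.38
     9       0.60  89.60  10.40   8.74
    10       0.55  89.76  10.24   8.90
{'lf_nu_increasing': True, 'lf_hf_increasing': True, 'sd2_sd1_increasing': True,
 'hf_nu_decreasing': True, 'sdnn_ms_decreasing': True, 'rmssd_ms_decreasing': True,
 'sd1_ms_decreasing': True, 'sd2_ms_decreasing': True}
```

At full ACh availability the model rests in slight parasympathetic
dominance (LF/HF ≈ 0.5); as ACh falls to 55% the normalized LF power
climbs from ~33 to ~90 and the sympathovagal ratio rises monotonically
to ~9 — the progressive sympathetic dominance and loss of short-term
variability that characterise cardiac autonomic dysfunction in AD.

The same pipeline is available from the shell:

```
anshrv simulate --alpha 0.7 --duration 300 --seed 1 --out rr.txt
anshrv features rr.txt --out features.csv
anshrv progression --seeds 10 --out table.csv
anshrv trend-check table.csv
anshrv cohort --n 20 --seed 42 --out-dir cohort/
anshrv compare --features cohort/features.csv --out comparison.csv
anshrv calibrate --budget 200 --seed 7 --out params.json
```

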