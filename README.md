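# scallop-pd

Substrate-vibration exposure metrics and valve-gape biologging analysis for
pile-driving impact studies on scallops.

Offshore wind-farm construction drives steel monopiles into the seabed with
impact hammers (discrete, impulsive strikes) and vibratory hammers
(quasi-continuous vibration at ~1150 blows/min). The substrate-borne
component of this disturbance reaches benthic invertebrates — scallops and
other bivalves — that cannot relocate, and induces valve closures with
potential energetic costs. This package implements, as a tested and
reusable pipeline, the analysis chain of a field exposure experiment on the
giant scallop (*Placopecten magellanicus*): seabed-vibration exposure
metrics from triaxial geophone records, valve-angle processing from
magnetometer biologging tags with strike-synchronized closure detection,
circadian periodicity testing, and behavioral event-rate comparison across
a before–during–after exposure design at two distances. Because the
original field recordings are not public, a first-class synthetic-data
module generates seeded geophone, tag, and annotation datasets with the
study's statistical structure and exact ground truth, so every estimator
can be validated closed-loop.

## Core quantities and models

All vibration levels are computed on the orientation-invariant vector
magnitude m(t) = √(x² + y² + z²) of the triaxial acceleration (µm s⁻²):

- **0-peak level** `20 log₁₀ max m(t)` (dB re 1 µm s⁻²);
- **pulse duration** (first-crossing time from 5% to 90% of max |a|) and
  **rise time** (5% cumulative energy to peak);
- **single-strike exposure** SEL_ss = `10 log₁₀ ∫ m²(t) dt` over the 90%
  energy window (the 5–95% cumulative-energy interval), dB re
  (1 µm s⁻²)²·s;
- **cumulative exposure** SEL_cum = `10 log₁₀ Σᵢ 10^(SEL_ss,i/10)` over all
  strikes of a pile-driving event;
- **vibratory/ambient levels**: RMS of m(t) within the 90% energy window
  (continuous signals) or over the record (ambient), plus Welch PSDs.

Valve angles are obtained from magnetometer voltage through a monotone
piecewise-linear calibration; partial/total closures are recovered by
sparse matched deconvolution (abrupt drop + exponential recovery kernel).
The circadian analysis computes the Fourier periodogram of 10-min binned
angles and tests its largest ordinate with **Fisher's exact g-test**,
g = max Iₖ / Σ Iₖ with null tail
`p = Σⱼ (−1)^(j−1) C(m,j)(1 − jg)^(m−1)`. Exposure effects are assessed by
a ladder of five nested linear mixed models on log-transformed angles
(random intercepts for individual and date; fixed effects added stepwise:
exposure phase, hammer type, repetition, day) compared by likelihood-ratio
tests, and behavioral event rates are compared with mixed models plus
Tukey-adjusted pairwise contrasts.

## Worked example

The bundled demo runs the whole before–during–after workflow on synthetic
data (4-day tag deployment, daily afternoon pile driving, geophone session,
two-site behavioral design):

```sh
scallop-pd run --seed 0 --out demo_out
```

The report (`demo_out/report.json`) contains, with the default seed:

```
"vibration": { "ambient_db": 53.897, "peak_level_db_mean": 109.877,
               "ipi_mean_s": 6.657, "sel_ss_db_mean": 96.56,
               "sel_cum_db": 113.16, "vh_rms_db": 86.009,
               "n_strikes_true": 44, "n_strikes_detected": 44 }
"tag":       { "pre15_mean_deg": 7.339, "exposure_mean_deg": 5.518,
               "post15_mean_deg": 7.329, "relative_reduction": 0.2481,
               "n_closures_true": 408, "n_closures_detected": 424 }
"circadian": { "dominant_period_h": 24.0, "fisher_g": 0.83294,
               "p_value": 1.58e-220 }
"behavior":  { "n_events": 3523, "n_fish_removed": 192,
               "near_juvenile_IH1_closures_per_min": 4.689 }
```

Reading the numbers: the geophone stage detects every simulated hammer
strike (44/44) and recovers the ambient floor (~54 dB re 1 µm s⁻²), the
per-strike peak level (~110 dB) and the 6.6-s inter-pulse interval the
generator was configured with; the tag stage shows the valve angle dropping
from ~7.3° before exposure to ~5.5° during it (a ~25% reduction) and
returning to baseline within 15 min; the circadian stage identifies the
24.0-h rhythm with an overwhelmingly significant Fisher g; and the
behavioral stage counts closure events per minute after removing
fish-related closures.

Each stage is equally usable from Python; for example:

```python
from scallop_pd import synthetic, vibration

cfg = synthetic.SimConfig(seed=1)
series, truth = synthetic.gen_ih_train(cfg, duration=900.0)
events = vibration.detect_strikes(series)
summary = vibration.event_summary(series, events)
print(summary.n_strikes, summary.ipi_mean_s, summary.sel_cum_db)
```

## Layout

- `scallop_pd.synthetic` — seeded generators with exact ground truth
- `scallop_pd.vibration` — strike detection and exposure metrics
- `scallop_pd.tag` — calibration, closures, exposure stats, model ladder
- `scallop_pd.circadian` — periodogram and Fisher's exact g-test
- `scallop_pd.behavior` — event rates and treatment comparisons
- `scallop_pd.io` / `scallop_pd.cli` — formats, config, pipeline, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
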