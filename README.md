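# sealdive

Bio-logging dive analysis for deep-diving marine predators: from raw
depth / tri-axial acceleration / tri-axial magnetometry streams to
prey-encounter events, dive-phase segmentation, per-dive foraging
covariates and the statistical models that relate them.

Female southern elephant seals (*Mirounga leonina*) spend months at sea
diving continuously to several hundred metres, foraging mostly at the
bottom of their dives. Archival tags record depth at 1 Hz and
acceleration/magnetism at 16 Hz; from these streams alone one can detect
individual prey-capture attempts (broadband head-jerk transients),
reconstruct body posture, and ask what diving behaviours predict
foraging success. `sealdive` implements that whole chain, plus a
synthetic daily-diary simulator with ground truth so every stage is
testable without animal data.

## The pipeline

1. **Band separation** (order-3 Butterworth, zero-phase by default):
   static (gravity) component below 0.20 Hz, prey-strike dynamics above
   2.64 Hz, lateral stroking in 0.44–1.02 Hz. *Swimming effort* is the
   rectified stroking band averaged to 1 Hz.
2. **Prey-encounter events (PEE)**: per axis, 1-s windowed SD of the
   dynamic acceleration → 5-s moving SD → exact 1-D two-means
   clustering into low/high states; an event is a maximal run of
   seconds with all three axes simultaneously high.
3. **Orientation**: unit-norm static acceleration gives
   `pitch = −arcsin(s_x)`, `roll = atan2(s_y, s_z)` (NED frame, X
   forward / Y right / Z down); heading comes from tilt-compensating the
   low-pass-filtered magnetic vector. Angular summaries use circular
   statistics (circular mean; circular variance `1 − R̄`).
4. **Dive segmentation**: zero-offset correction of pressure drift,
   dives = maximal runs deeper than 15 m (durations outside 500–1950 s
   flagged), *wiggles* (down-then-up depth excursions) and *steps*
   (glides with vertical speed strictly in (0, 0.35) m/s), bottom phase
   delimited by the first/last event deeper than 75 % of maximum depth,
   and drift (resting) dives excluded.
5. **Dive metrics**: PEE rate at the bottom (min⁻¹, via a
   log-exposure offset), bottom median depth, bottom vertical extent
   (Q90 − Q10), % bottom time in wiggles/steps, transit pitch and
   effort, pitch/heading circular variances, dive efficiency
   (bottom/dive duration), surface speed from bracketing GPS fixes, and
   a day/night label from solar altitude.
6. **Statistical models** (statsmodels-style `DiveModel` → `fit()` →
   `DiveModelResults`): negative-binomial GLMs of bottom PEE counts for
   day (1a) and night (1b), an LMM for surface speed (2), a
   variable-dispersion beta regression for dive efficiency (3), and an
   LMM with phase-type interactions for transit durations (4); backward
   AIC selection with polynomial escalation, ML→REML refit, one-in-ten
   thinning, VIF < 5 screening, and D² / Nakagawa R²m–R²c / squared
   Pearson pseudo-R².

## Worked example

```python
import sealdive as sd

cfg = sd.SimConfig(seed=42, n_dives=12)
dep, truth = sd.simulate_deployment(cfg)
ana = sd.analyze_deployment(dep, individual_id="seal1")

print(f"record: {dep.depth.n/3600:.1f} h, {len(ana.dives)} dives detected")
print(f"prey-encounter events: {len(ana.pee_events)} detected, "
      f"{len(truth.pee)} injected")
print(ana.pee_by_phase.phase.value_counts().to_dict())
```

prints

```
record: 4.8 h, 12 dives detected
prey-encounter events: 30 detected, 30 injected
{'bottom': 29, 'descent': 1}
```

— the detector recovered all 30 injected strike transients, and almost
all of them sit in delimited bottom phases, as expected for a
bottom-foraging diver. The per-dive covariate table then reads

```
 dive_id  bottom_pee_count  pee_rate_bottom  bottom_median_depth_m  dive_efficiency  var_heading_bottom daynight
       0                 1            1.714                  520.5            0.023               0.005      day
       1                 2            0.945                  371.5            0.082               0.295      day
       2                 4            1.048                  641.5            0.167               0.271      day
       3                 0            0.000                  419.5            0.078               0.107      day
```

where `pee_rate_bottom` (min⁻¹) is the foraging-success proxy and
`var_heading_bottom` the horizontal sinuosity of the bottom phase.
Fitting the five models on a multi-animal table:

```python
summary, results = sd.fit_five_models(dive_table, phase_table)
print(results["1a"].summary())
```

A thin CLI mirrors the stages:
`sealdive simulate | detect | segment | metrics | fit`.

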