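# thermoniche

Thermal-niche analysis of dung beetle communities: infrared-thermography
trace extraction, endothermy and thermoregulation-mechanism inference,
indicator-species (IndVal) habitat affinity, daily-activity classification,
diel microclimate summaries, and the comparative mixed-model statistics —
driven end to end by a seeded synthetic-data generator with known ground
truth.

## The scientific problem

When tropical forest is replaced by pastures or agroforestry, dung beetle
assemblages change drastically; the physiological hypothesis is that the
**thermal niche** — how far a species holds its thorax above ambient during
flight (endothermy, or excess temperature) and how it manages that heat
(thermoregulation) — determines which species can exploit hot, open,
human-created habitats. `thermoniche` implements the full analytical
pipeline behind that question for thermographic tethered-flight assays plus
community survey data:

* **Thermography** — per-frame maximum of fixed 3x3-pixel ROIs (thorax,
  abdomen, background) from multi-page TIFF frame stacks; greybody
  radiometric correction `W_obj = (W_meas - (1-ε)τ W_refl - (1-τ) W_atm)/(ετ)`
  with `W(T) ∝ T⁴`; cuticle-emissivity estimation against an ε = 0.95
  reference; the ≥ 40 s continuous-flight filter.
* **Thermal niche** — endothermy = mean(T_th − T_env) over the flight
  window; least-squares slopes sT_th, sT_abd, sT_env over
  [take-off, take-off + 40 s]; species-level mechanism calls by
  Kruskal–Wallis slope-pair tests: **APHT** (abdominal passive heat
  transfer: thorax and abdomen slopes differ, sT_th > 0, abdomen tracks the
  environment) vs **AAHT** (abdominal active heat transfer: thorax and
  abdomen slopes similar and positive, abdomen diverges from the
  environment), otherwise UNDEFINED.
* **Community** — IndVal_ij = A_ij × B_ij × 100 (Dufrêne–Legendre
  specificity × fidelity) with a seeded site-label permutation test;
  indicator (> 70%, P < 0.05) and detector (45–70%, P < 0.05) categories;
  diurnal vs evening/nocturnal/crepuscular (ENC) classification by the
  ≥ 60%-of-captures rule over the 7:00–18:00 / 18:00–7:00 periods.
* **Microclimate** — day/night mean/max/min of 5-min sensor logs and the
  thermal amplitude (day max − night min).
* **Comparative statistics** — `log(endothermy) ~ habitat*activity + mass +
  (1|species)` and analogues for the slope variables, REML, type-III Wald
  χ² ANOVA, Tukey-adjusted marginal-mean contrasts, Kruskal–Wallis +
  Conover–Iman post-hocs for body mass, Pearson correlations.

A bundled reference table of 17 Atlantic-forest species (7 diurnal, 10 ENC
across native forest, agroforestry parkland and open pasture) seeds the
synthetic generator, so every stage is testable without field data.

## Worked example

```python
from thermoniche.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(out_dir="demo_run", seed=1))
print(report["thermal_amplitude"])
# {'agroforestry': 13.05, 'native_forest': 11.01, 'open_pasture': 21.86}
print(report["endothermy_mean"]["Coprophanaeus cyanescens"])   # 9.293
print(report["endothermy_mean"]["Canthon curvodilatus"])       # 0.435
print(report["anova_interaction_P"]["endothermy"])             # 0.0135
```

The run simulates 128 flights across the 17-species pool, fits each
individual's endothermy and slopes, classifies mechanisms, scores habitat
affinity (all 17 planted species come back as significant indicators of
their home habitat at 999 permutations), classifies activity (7 diurnal,
10 ENC), summarizes per-habitat sensor logs, and fits the mixed models.
The numbers above read: open pasture spans a 21.9 °C day-max-to-night-min
amplitude versus 11–13 °C under canopy; the most endothermic species holds
its thorax ~9.3 °C above ambient and the least ~0.4 °C; and the
habitat × activity interaction for log-endothermy is significant
(P ≈ 0.014) — small, low-endothermy diurnal species are the ones exploiting
the open habitat. Outputs land in `demo_run/` as CSVs (each stamped with
the config hash and seed) plus `report.json`.

The same stages are available from the shell:

```bash
thermoniche simulate stack --seed 1 --out stack.tiff
thermoniche extract --stack stack.tiff --times stack.times.csv \
    --rois stack.rois.csv --emissivity 0.95 --out traces.csv
thermoniche indval --abundance abundance.csv --permutations 999 --seed 1
thermoniche run --seed 1 --out-dir demo_run
```

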