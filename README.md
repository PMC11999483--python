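# circavol

Circadian rest-activity metrics, Bayesian volatility/noise decomposition,
and mixed-model treatment contrasts for two-arm wrist-actigraphy trials.

Wrist actigraphy in mood-disorder trials produces daily series - daytime
activity amount and onset, nocturnal activity, self-reported affect - whose
*levels* and *variability* both carry clinical signal. `circavol` is for
researchers analysing such trials (or planning them via simulation). It
provides:

* **Non-parametric circadian metrics** from epoch-level acceleration:
  per-epoch signal magnitude vector SVM = Σ|√(x²+y²+z²) − g|, day
  exclusion beyond 3 h of non-wear, M10 (most active 10 h) and L5 (least
  active 5 h, searched noon-to-noon) amounts and onsets, relative
  amplitude RA = (M10−L5)/(M10+L5), interdaily stability IS and
  intradaily variability IV.
* **A hierarchical Bayesian filter** that inverts the generative model
  mu_t = mu_{t−1} + N(0, exp(log vmu_t)), y_t ~ N(mu_t, SD_t), with log
  vmu and log SD themselves drifting at rates kmu and vSD, on a dense
  (mu × log vmu × log SD) grid with model averaging over (kmu, vSD)
  candidates. It returns, for every day, the marginalized-posterior
  expectations of the mean, the volatility (persistent drift) and the
  noise (transient scatter), with uncertainty that grows through missing
  days.
* **REML linear mixed models** for group × phase contrasts (run-in
  baseline, weeks 1-4) of levels, onsets, volatilities/noises, and
  per-period RA/IS/IV, with participant-clustered sandwich inference,
  effect sizes d = 2t/√df, and within-subject / change-score correlation
  utilities.
* **A synthetic trial generator** producing every input above - latent
  volatility series, epoch-level days, and full two-arm trials with
  injected week-indexed effects and realistic missingness - so the whole
  chain is testable without data downloads.

See `docs/methods.md` for the models, conventions, and limitations.

## Worked example

Run a complete synthetic trial with the default injected effects (daytime
activity reduced 18.8-30.9%, onset advanced 1.55-1.69 h in weeks 3-4,
activity log-volatility raised 0.23-0.45):

```bash
circavol run-all --seed 1 --out runs/demo
```

This simulates 40 participants over days −14..28, computes daily and
per-period metrics, filters all six daily tracks per participant, fits the
mixed models, and writes `trial.csv`, `metrics.csv`, `rhythm.csv`,
`estimates.csv`, `results.csv`, `report.txt` and a manifest. The report's
activity-model section reads (seed 1):

```
[activity_level] lithium:week3: B=-21.371 t=-7.228 p=1.045e-08 d=-0.299
[activity_level] lithium:week4: B=-18.819 t=-5.707 p=1.323e-06 d=-0.236
[activity_onset] lithium:week3: B=-1.587 t=-6.762 p=4.558e-08 d=-0.280
[activity_onset] lithium:week4: B=-1.208 t=-3.496 p=0.001194 d=-0.145
```

Reading the week-4 rows: relative to the placebo arm and each arm's
pre-randomization baseline, the treated arm's M10 is lower by B ≈ 18.8
activity units - close to the injected 30.9% of the 57.3-unit baseline
(≈ 17.7) - and its daytime activity onset is B ≈ 1.2-1.6 h earlier,
recovering the injected 1.55-1.69 h phase advance. t and p use
participant-clustered standard errors; d is the declared 2t/√df
convention. Every generator knob (sample size, effect maps, missingness,
filter grids) is a YAML config away; `circavol simulate|metrics|filter|analyze`
rerun individual stages, and two runs with the same seed are byte-identical.

As a library:

```python
from circavol import (TrialDesign, simulate_trial, fit_series_bundle,
                      build_long_table, fit_activity_model)

design = TrialDesign(n_per_arm=20, seed=1)
trial = simulate_trial(design)
estimates = fit_series_bundle(trial)           # Bayesian filter, all tracks
table = build_long_table(trial, estimates)
fit = fit_activity_model(table)                # REML + clustered inference
print(fit.contrasts)                           # weekly group x phase rows
```

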