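# relapsekit

Computational markers of relapse risk in alcohol use disorder (AUD), as a
tested, reusable analysis pipeline.  The scientific question: can cognitive
and brain-activation measures collected during inpatient treatment —
prospect-theory risk preferences from a gamble task, frontotemporal oxy-Hb
responses (fNIRS) during an emotional go/no-go task and a verbal fluency task,
go/no-go / n-back behavior — predict who relapses within six months of
discharge?  The package is aimed at computational-psychiatry researchers who
want the full chain from raw-format data (or a calibrated synthetic cohort) to
group statistics and a logistic prognosis model, with every step unit- and
property-tested.

## The models at the core

**Risk preference.** Each gamble (win `x` JPY with probability `p`) is valued
as

    SV(p, x) = w(p; γ) · u(x; λ),   w(p) = exp(−(−ln p)^γ),   u(x) = (x / x_max)^λ

— the one-parameter Prelec probability weight (fixed point at 1/e) times a
power utility.  λ < 1 is risk-averse, λ = 1 risk-neutral, λ > 1 risk-seeking;
γ ≠ 1 distorts probabilities.  Choices follow a softmax with inverse
temperature τ, and (λ, γ, τ) are estimated per subject by bounded multi-start
maximum likelihood over the 120 non-catch trials.

**fNIRS integral mode.** Oxy-Hb series (channels 22–52, 0.1 s sampling) are
smoothed (5 s moving average), artifact channels rejected by deterministic
criteria, baseline-corrected by the line between the last-10 s means of the
pre- and post-task periods, and integrated over each task block; channel
integrals are averaged into frontopolar, left- and right-frontotemporal
regions and contrasted emotional − neutral.

**Prognosis.** Group comparisons (Mann-Whitney U / Student's t / chi-squared,
Spearman ρ) and a standardized binomial logistic regression of relapse on six
predictors with a Box-Tidwell linearity check, Wald CIs, and in-sample
sensitivity/specificity at a 0.5 cutoff.

Because no participant-level data are public, the package includes a
first-class synthetic-cohort generator (24 abstainers / 17 relapsers by
default) calibrated to the reported group statistics, with ground-truth
latents stored separately so recovery tests cannot leak.  See
`docs/methods.md` for every modeling decision and limitation.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic cohort (equivalently: `relapsekit demo --seed 7`):

```bash
python analysis/01_generate_cohort.py --seed 7   # cohort + raw streams
python analysis/02_process_fnirs.py              # integral-mode activations
python analysis/03_score_behavior.py             # go/no-go, n-back, VFT
python analysis/04_fit_risk_model.py             # per-subject MLE fits
python analysis/05_group_stats.py                # tables, model, figures
```

Output of the final step at seed 7:

```
lambda: medians 0.193 vs 0.428, p = 0.3206
right-FT contrast: medians 7.8 vs -63.7, p = 0.0659
logistic ORs: contrast 0.335, lambda 0.755; sens/spec 76.5/83.3%
report -> results/report
```

Reading: the relapser group shows the higher fitted utility-sensitivity λ
(more risk-seeking: 0.428 vs 0.193) and the lower right-frontotemporal
emotional contrast (−63.7 vs 7.8 concentration·s), the two injected effects.
At n = 41 a single realization is noisy — p-values and odds ratios swing
widely across seeds even though the generating effects are fixed; the
calibration experiments below quantify recovery at sizes where sampling noise
is small.  Full tables (demographics, behavior, region contrasts, risk
parameters, correlations, logistic model) land in `results/report/`, and
`summary.json` carries the seed and config hash for reproducibility.

Per-stage CLIs also exist: `relapsekit fit --choices choices.csv --out
fits.csv --starts 20 --seed 7`, `relapsekit process-fnirs`, `relapsekit
stats`, `relapsekit synth`, `relapsekit run --config pipeline.yaml`.

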