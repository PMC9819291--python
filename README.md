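# facit-mcid

Anchor-based estimation of the minimal clinically important difference
(MCID) for the FACIT Fatigue Scale (FACIT-FS) in systemic sclerosis,
with random-forest screening and logistic modelling of the predictors of
fatigue change — exercised end-to-end on a synthetic longitudinal cohort
generator, because patient-level data of this kind are generally not
shareable.

**Who it is for.** Biostatisticians and outcomes researchers who work
with patient-reported outcome measures (PROMs) and need a tested,
reproducible implementation of the anchor-based MCID workflow: scoring,
anchor classification, ROC cutoff selection, reconciliation across
anchors, responder classification, predictor screening and post hoc
power.

## The method

A patient's fatigue change is Δ = FACIT-FS(12 mo) − FACIT-FS(baseline),
oriented so Δ > 0 means improvement.  Two external anchors with
previously established MCIDs — VAS Fatigue (±10 mm, primary) and the
SF-36 Mental Component Summary (±5 points) — label each patient *truly
worsened*, *unchanged* or *improved*.  Per direction, every observed
integer Δ of the required sign is a candidate cutoff *c*; sensitivity
and specificity of the rule "Δ ≤ c" (worsening) or "Δ ≥ c" (improvement)
against the anchor labels trace a ROC curve whose AUC is the
tie-adjusted concordance probability

AUC = P(Δ_changed more extreme than Δ_unchanged) + ½·P(tie).

The operating cutoff maximizes the Youden index J = sensitivity +
specificity − 1 (ties toward the smaller |c|); disagreeing anchors are
reconciled by the primary anchor.  The final pair (MCID₋, MCID₊)
classifies the cohort, and the resulting groups feed two predictor
analyses: a conditional-inference random forest (association-test-based
splits, out-of-bag permutation importance aggregated over many forests,
selection above an all-noise-calibrated threshold) followed by binary
logistic regressions reporting odds ratios with Wald 95% intervals,
after dropping collinear predictors (|Spearman ρ| ≥ 0.7; CHFS is kept
over HAQ-DI).  Post hoc power of each group comparison is estimated by
Monte-Carlo resampling under the two-sided Wilcoxon–Mann–Whitney test.

The synthetic cohorts reproduce the structure this workflow assumes —
documented in detail in `docs/methods.md` — including a latent true
fatigue change with a known MCID pair of (−3, +4), anchors whose
observed changes rank-correlate 0.6 with the observed FACIT-FS change,
covariate marginals matching a published scleroderma cohort description
(e.g. 60.6% interstitial lung disease) and a tripled worsening odds
for ILD.

## Worked example

```bash
python analysis/01_simulate_cohort.py          # results/cohort.csv
python analysis/02_estimate_mcid.py            # MCID pair + ROC tables
python analysis/03_screen_predictors.py        # forest importances
python analysis/04_logistic_models.py          # odds-ratio tables
python analysis/05_power_checks.py             # post hoc power
```

The second step prints, for the default simulated cohort:

```
MCID pair: -4 (worsening), +4 (improvement)
  worsened  vas_fatigue  cutoff -4 sens 0.680 spec 0.915 AUC 0.844
  worsened  sf36_mcs     cutoff -4 sens 0.763 spec 0.877 AUC 0.836
  improved  vas_fatigue  cutoff +4 sens 0.818 spec 0.828 AUC 0.841
  improved  sf36_mcs     cutoff +4 sens 0.771 spec 0.890 AUC 0.851
group counts: {'worsened': 42, 'improved': 39, 'unchanged': 63, 'excluded': 0}
```

Reading: with this cohort's anchors, a 4-point FACIT-FS drop is the
change that best separates anchor-worsened patients from the rest
(sensitivity 0.68, specificity 0.92); the generator's true pair is
(−3, +4), so the worsening cutoff here landed one point outside —
single-cohort cutoff estimates at n = 144 carry roughly one point of
sampling uncertainty, which is why the recovery tests aggregate over
100 cohorts.  Classifying by the final pair splits the cohort into
42 worsened / 39 improved / 63 unchanged patients.  The screening step
then flags disease activity (rEUSTAR-AI), ILD, disease duration and
hand function (CHFS) as baseline predictors of the fatigue change, and
the logistic step estimates, e.g., OR ≈ 9.9 for ILD on worsening in
this particular draw.

The same stages are available as a console tool
(`facit-mcid simulate|score|mcid|screen|predict-change|power|compare|run-all`)
and as one orchestrated call (`facit_mcid.pipeline.run_pipeline`) that
writes every intermediate table plus a hashed run manifest.

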