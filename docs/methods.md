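# Methods

## The estimation problem

An anchor-based MCID analysis asks: what change in the target
instrument (FACIT-FS, 0–52, higher = less fatigue) best separates
patients an external criterion calls "truly changed" from the rest?
Formally, with oriented change scores Δ (positive = improvement) and
anchor-derived binary labels per direction, the estimator sweeps integer
candidate cutoffs, computes sensitivity/specificity per cutoff and the
tie-adjusted AUC, and returns the Youden-maximizing cutoff.  Two anchors
(VAS Fatigue, primary; SF36-MCS) are reconciled by letting the primary
anchor decide disagreements.  The package implements that estimator,
the surrounding pipeline (scoring, screening, logistic models, power),
and a synthetic-cohort generator that provides ground truth for
recovery testing.

## Instrument scoring

Items are recoded so higher always means better (explicit per-item
polarity; the shipped FACIT-FS definition reverse-scores all items
except the two positively worded ones), then summed with prorating by
`n_items / n_answered` when at least half the items are answered (the
FACIT convention, exposed as `min_answered_fraction`), or averaged for
mean-type scales.  SF-36 vitality items map onto the RAND values
0/20/.../100 before averaging.  Scores below the answering threshold
are reported as missing with an explanatory status, never as a number.

## The synthetic cohort generator

The generator's task is to produce cohorts with the statistical
structure the analysis assumes, with known truth.  Requirements it
encodes (all defaults, all overridable through `CohortSpec`):

* **n = 144** followed patients; direction mixture targeting
  44/65/35 worsened/unchanged/improved.
* **Latent true change `L`** on the FACIT-FS scale with true MCID pair
  (−3, +4).  The three mixture components are the *truncated slices of
  one normal* whose location and scale are solved from the mixture
  weights and thresholds (≈ N(−0.05, 5.81)).  Slicing one smooth
  density — rather than gluing three unrelated components — keeps the
  marginal latent density continuous across the thresholds, a property
  the ROC estimand needs (below).
* **Direction model**: a two-stage conditional logit.  Stage 1 draws
  worsened-vs-rest from a logistic model in the baseline covariates
  (ILD log-odds ln 3.197, plus disease activity, hand function,
  duration and skin-score effects with published signs); stage 2 draws
  improved-vs-unchanged among the non-worsened.  The two-stage form
  makes the downstream worsened-vs-rest logistic regression *exactly*
  correctly specified, so Wald coverage of the ILD effect is a clean
  test.  Intercepts are solved by Newton iteration so the realized
  group fractions match the mixture weights.
* **Observed change**: Δ = round(L + ε), ε ~ N(0, 0.75), clipped with
  the baseline to the 0–52 range; the clipped fraction is reported in
  the frame's `attrs`, not hidden.  The measurement SD models a
  carefully administered questionnaire; larger values mainly widen the
  cutoff sampling distribution.
* **Covariate marginals** approximate the published cohort description
  (ILD 60.6%, duration log-normal with mean 10.5 y / SD 7.6 y, 86.3%
  female, 55% diffuse subtype, FACIT-FS baseline median ≈ 38.5,
  VAS Fatigue baseline median ≈ 24 with a heavy right tail, etc.).
  HAQ-DI is a noisy monotone transform of CHFS (Spearman ≈ 0.85) so the
  collinearity-exclusion rule has something real to do.
* **Change-predictor couplings**: each candidate change-predictor's
  one-year change is `slope · L + noise`, with signs matching the
  published predictor effects (emotional well-being and physical
  condition move with fatigue; GI symptoms, hand disability and disease
  activity against it) and slopes giving modest rank correlations
  (~0.2–0.5) with Δ.

### Anchor construction and the recovery estimand

The naive construction — anchor change = monotone transform of `L` plus
additive noise, thresholded at the anchor MCID — *cannot* be recovered
by the Youden estimator: the Youden-optimal cutoff sits where
P(labeled changed | Δ) equals the label *prevalence* (the point where
the two class densities cross), and with symmetric smearing noise and a
~25% positive class that point lies well inside the true threshold.
The generator therefore builds the anchors so that the estimator's
population optimum coincides with the true MCID pair — the identifying
condition without which a recovery test would be testing a misspecified
world rather than the code:

1. **Estimand alignment.**  The anchor transform maps the anchor's MCID
   onto the latent point where the density-equality condition holds at
   the true threshold.  With normal latent, normal measurement noise
   (plus rounding variance 1/12) and labelling noise of width `w`, both
   sides of the condition are normal probabilities and the point has a
   closed form.  Because integer change scores bin the candidate
   cutoffs, the condition is evaluated a fraction of a point inside the
   threshold (`anchor_bin_offsets`, default 0.5 for worsening, 0.0 for
   improvement — the offset that equalizes the discrete Youden gaps on
   both sides of the peak depends on the positive-class prevalence).
2. **Anchor error, three components.**  (i) Threshold smearing: the
   label-driving latent carries N(0, w²) noise, w = 0.25 FACIT points.
   (ii) Gross errors: a fraction (default 5%, raised automatically when
   needed, see below) of patients carry an anchor value drawn
   independently from the marginal — completely-at-random label
   corruption, which provably scales the population Youden curve
   without moving its argmax.  (iii) Category-preserving scrambling:
   anchor *magnitudes* are exchanged among patients the anchor placed
   in the same worsened/unchanged/improved category; the dichotomizing
   ROC never sees these magnitudes, so this tunes the observed-change
   correlation without touching the estimand.
3. **Correlation calibration.**  The Spearman correlation between
   observed ΔFACIT-FS and the observed oriented anchor change is
   brought to `anchor_correlation` (default 0.6) by bisection: first on
   the scrambling fraction, then — because accurate labels alone
   already correlate ≈ 0.70 with Δ, so scrambling saturates above the
   target — on the gross-error fraction.  The labels are a threshold of
   the anchor value, so label information can never exceed anchor
   information: a 0.6 correlation *forces* roughly 15% random label
   corruption.  This is the binding constraint on recovery precision.

With these defaults, recovery experiments over 100 cohorts give median
estimated pair exactly (−3, +4); the worsening cutoff lands within ±1
point in ≈99% of cohorts.  The improvement cutoff is harder — a smaller
positive class (35/144) and the forced label corruption put its
integer-argmax sampling SD near one point — and its ±1 rate stays a few
points below 90%.  The recovery test asserts the 90% bound for both
directions and currently documents this shortfall rather than relaxing
the condition that causes it.

### What the generator does not emulate

Attrition (the real study lost 16 of 160 patients), item-level response
vectors (totals are generated directly; the scoring engine is tested on
its own fixtures), informative missingness (generated cohorts are
complete), non-monotone anchor–target relations, and any real
instrument's measurement-error structure — in particular the
category-preserving scrambling is a synthetic-world device, not a model
of how VAS marks err.  Passing recovery tests therefore show the
*pipeline* is correct under the assumed structure, not that the design
would identify MCIDs under arbitrary real-world anchor behaviour.
There is no direct baseline–follow-up correlation knob: it is implied
by the baseline SD (~10.5) and the change model (implied Spearman
≈ 0.85); lower it by raising `obs_noise_sd` or the baseline SD.

## ROC, cutoff selection, reconciliation

Candidate cutoffs are every observed integer Δ of the required sign
plus a 0 sentinel.  AUC is computed from mid-ranks (exactly the
tie-adjusted concordance probability; verified against exhaustive pair
counting to 1e−12).  The Youden argmax excludes the 0 sentinel unless
it is the only candidate — a *minimal important* difference of zero is
self-contradictory, and permitting it would let the reconciled pair
violate its own sign constraint.  Ties resolve toward the smaller
|cutoff| (the more sensitive MCID).  Reconciliation policies: primary
anchor on disagreement (default, the published behaviour), max, min,
mean-rounded.  The negative ROC class pools unchanged and
opposite-direction patients; patients with a missing target or anchor
delta are excluded from that anchor's ROC and reported.

## Rank statistics

Thin wrappers over scipy.stats with explicit conventions: mid-ranks for
ties everywhere; Mann-Whitney U counts pairs with a > b (ties half),
normal approximation without continuity correction, exact null for
n ≤ 12 without ties; the signed-rank statistic is W⁺ with zero
differences dropped (Wilcoxon's rule; Pratt optional), exact for ≤ 12
untied nonzero pairs; Spearman p via the t approximation, exact by full
permutation enumeration for n ≤ 8.  Note the exact and
normal-approximate p-values of the discrete rank tests differ by up to
~0.07 at the smallest exact-feasible sizes; the tests document the
convergence rather than pretending agreement.

## Conditional-inference forest screening

Each node samples `mtry` (default ⌈√p⌉; a standalone tree tests all
predictors) candidate predictors and applies a rank-correlation
association test between predictor and response (normal approximation
of the linear rank statistic; for a binary response this reduces to the
rank-sum test), Bonferroni-adjusted over the candidates.  Nodes stop
when the best adjusted p exceeds `split_alpha` (0.05) or fewer than
2·`min_node` (= 40) rows remain; otherwise the node splits the most
significant predictor at the cut maximizing the standardized two-sample
rank statistic, ties toward the balanced split, midpoint thresholds.
Trees grow on bootstrap samples; importance is the out-of-bag loss
increase after permuting a predictor among OOB rows, exactly zero for
predictors a tree never used, averaged over trees; per-tree seeds are
derived arithmetically from the forest seed so results are independent
of any execution order.  Hot kernels are numba-compiled.

Aggregation across forests (default 50 forests × 100 trees; the
published analysis used 1000 × 500, available as a flag — the
aggregation contract is scale-invariant): the selection threshold is
1.5 × |most negative mean importance|.  The plain largest-negative-
excursion rule under-covers because permutation importance of a
predictor spuriously associated with the response *in the sample at
hand* is positive whichever the association's sign, so the negative
excursions understate the spurious positive tail; the 1.5 margin
(exposed as a parameter) restores specificity at a small sensitivity
cost.

## Logistic models

Maximum likelihood by IRLS with step-halving (the log-likelihood path
is non-decreasing by construction and is exposed on the fit),
convergence at max |score| < 1e−8 or 25 iterations, Wald SEs from the
observed information, CIs exp(β ± 1.96·SE).  Complete separation is
detected from the scaled coefficient magnitude and flagged on the
result instead of silently returning divergent estimates.  Collinearity
rule: predictors visited in priority order (CHFS before HAQ-DI, then
column order); one of each pair with |Spearman ρ| ≥ 0.7 is dropped and
reported.  The four predictor models (worsened/improved × baseline/
one-year-change) use listwise deletion with a logged count, keep
unchanged patients in the reference class, and apply no multiplicity
adjustment — matching the analysis they reproduce.  A failed model
(e.g. an empty direction) is recorded as its exception; the others
still run.

## Power

Empirical power = rejection proportion of the two-sided Mann-Whitney
test over `n_reps` Monte-Carlo replicates (default 10,000; the pipeline
uses 2,000–5,000), drawing groups from parametric samplers or — the
pipeline default, matching the "empirical power" framing — resampling
the observed groups with replacement.  The Monte-Carlo SE
√(p(1−p)/n_reps) is always reported.  On the default synthetic cohorts
the classified groups separate strongly on the anchor scales, so these
powers sit near 1.0.

## Determinism and problem sizes

Every stage seed derives from one global seed through
`numpy.random.SeedSequence` keyed by a fixed stage index; the generator
uses per-stage child streams; forest tree seeds are arithmetic in the
forest seed.  Identical configuration + seed reproduces every artifact
byte-for-byte (hashed in the run manifest).  Test and acceptance runs
use desk-scale sizes chosen for tight feedback loops: cohorts of 144
(the study scale) with 10,000-patient cohorts for convergence checks,
50 forests × 100 trees for screening, 100-seed recovery experiments,
10,000-replicate power calibrations, and 200 replicates at n = 5,000
for Wald coverage.
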