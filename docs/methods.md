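# Methods

## The task and the two hypotheses

A memory display of 64 randomly positioned bars is shown for half a
second.  The bars carry exactly two feature values ("old" values) drawn
from a 7-step ordinal series — orientations from 0° to 90° in 15° steps,
or one of two 7-level luminance ladders (a green and a blue hue family
whose xyY/L\*a\*b\*/sRGB coordinates ship with the package).  The two old
values are always two series steps apart, so the intervening step is their
never-shown mean.  A single probe follows and the observer answers Yes
("that value was present") or No.  The probe is the mean value (M), one of
the old values (O), or a novel value outside the old range (N, one to four
steps from the nearest old item).

Two accounts predict how p(No) should vary over probes:

* **Perceptual averaging** — the display is summarized by its mean feature
  value, so p(No) grows with the probe's ordinal distance from the mean.
* **Similarity** — responses reflect confusability with the two actually
  presented values, with confusions at the two old items independent.
  The N probes one step from the nearest old item (N1A below the old
  range, N1B above it) are exactly as far from an old item as the M probe,
  which yields a point prediction with no free parameters:

      p(No|M) = p(No|N1A) · p(No|N1B)

  equivalently p(Yes|M) = p(Yes|N1A) + p(Yes|N1B) −
  p(Yes|N1A)·p(Yes|N1B).  The two forms are exact complements; the
  package exposes both.

The analysis tests the point prediction with a paired t-test (Cohen's d
and a JZS Bayes factor alongside), and separately fits each participant's
p(No)-by-distance curve under the two classificatory schemes — distance
from the mean (categories x = 0 M, 1 O, 2–5 N) versus distance from the
nearest old item (x = 0 O, 1 M and N1, 2–4 N2–N4) — with the
three-parameter log-logistic

    p(No; x) = a + (1 − a) / (1 + exp(b − c·x)),

comparing the two fits by BIC.  `a` ∈ [0,1] is the floor rejection rate
(the asymptote as x → −∞), `b` a unitless location, `c` ≥ 0 the slope per
ordinal step.  The printed p(Yes) variant of this function is not the
algebraic complement of the p(No) variant; the package treats the p(No)
form as authoritative and defines p(Yes) = 1 − p(No).

## Synthetic observers

The simulator reproduces the four designs (480 experimental trials:
240/120/120 O/M/N for the single-dimension experiments; a 3×3
relevant × irrelevant probe factorial with 80 per cell at relevant-O and
40 otherwise for the two-dimension experiments; 20 flagged practice
trials; families balanced half/half; five blocks of 96) and answers them
with one of two observer rules:

* an **averaging observer**, p(No) = log-logistic of distance-from-mean
  (default preset `a=0.2, b=3.6, c=1.7`, chosen so the M/O/N1 category
  probabilities are ≈ 0.22/0.30/0.56, the orientation experiment's
  marginal means);
* a **similarity observer**, p(No) = ∏ᵢ (1 − g(dᵢ)) over the two old
  items, with a non-increasing confusion kernel g (default preset
  `g = (0.72, 0.35, 0.10, 0)`, giving an O-probe rejection rate ≈ 0.25
  as in the color experiment).  Because the preset kernel vanishes at
  distance ≥ 3, the similarity product prediction holds exactly for the
  generating process, which anchors the consistency tests.

For the two-dimension designs there is no established generative model of
how the irrelevant dimension intrudes; the simulator mixes the
relevant-dimension p(No) with an irrelevant-dimension p(No) with weight
λ (default 0.15, small relative to the relevant effect), both the weight
and the irrelevant rule being configurable.  One root seed per session is
split into design, layout and response sub-streams, so the trial sequence
is bit-identical whichever observer answers it.

What the simulator does *not* emulate: sequential effects, lapses,
response bias drift, perceptual noise on the feature continuum (all
responses are conditionally independent Bernoulli draws), and any
rendering/timing properties of the display.  Passing tests therefore
validate the analysis machinery and the statistical logic of the designs,
not claims about human vision.

## Estimation and numerical choices

* **Condition tables** are exact No-response ratios per category; empty
  categories are reported missing, never imputed.
* **Exclusion rule**: a participant is dropped when p(No) on the N probes
  at their own maximal observed distance-from-mean is ≤ 0.5 (at or worse
  than chance).  Threshold and strictness are configurable; every
  decision is logged with the offending value.
* **N1 side policy**: the product prediction uses side-specific N1A/N1B
  estimates when both sides have ≥ 5 trials (boundary old pairs starve
  one side), otherwise the pooled N1 rate enters both factors; the policy
  is configurable and recorded per participant.
* **Fitting** minimizes trial-count-weighted squared error over
  (a, b, c) within bounds a ∈ [0,1], b ∈ [−20,20], c ∈ [0,20],
  multi-started from a fixed 4×4×4 grid (a ∈ [0,0.6], b ∈ [−2,6],
  c ∈ [0.1,4]); the best `n_local_starts` grid points (8 by default, 4 in
  the power simulation's inner loop) seed bounded L-BFGS-B refinements.
  Fits are deterministic given the data.  Constant-response data drive c
  to its boundary and are flagged degenerate rather than dropped.  Under
  the from-old scheme the M and N1 rows share x = 1 and are pooled by
  trial counts ("N1 & mean" category); a no-pooling variant is available.
* **BIC** has two variants.  The Gaussian least-squares form
  `n·ln(RSS/n) + k·ln(n)` (k = 3, n = number of category points, RSS on
  the category proportions) matches the scale on which per-participant
  BICs are conventionally reported for these fits and is the analysis
  default.  It is, however, unsuitable for *selecting between the two
  schemes* at low trial counts: the schemes bin the same trials into
  different numbers of points (6 vs 5) with different per-point noise
  variances, and the n-dependent penalty then favors the coarser scheme
  regardless of the generating process (measured on synthetic data, the
  averaging observer's mean BIC difference points the wrong way).  Model
  selection — the scheme-recovery validation and the power simulation —
  therefore defaults to the trial-level binomial-likelihood form
  `−2·logL + k·ln(N_trials)`, which puts both schemes on one likelihood
  scale; under it both generating rules are recovered in well over 90% of
  synthetic participants at full session trial counts.
* **Inference**: paired t with d = mean(Δ)/sd(Δ); JZS Bayes factor by
  adaptive quadrature of the noncentral-t likelihood over a Cauchy(0, r)
  effect-size prior (r = √2/2 by default, configurable).  Balanced
  repeated-measures ANOVAs are computed from the closed-form
  sums-of-squares decomposition with each effect tested against its own
  participant-by-effect interaction (uncorrected df, matching the
  conventional reporting); Tukey HSD uses the studentized-range
  distribution with the factor's own error mean square and df.
* **Power simulation**: per bootstrap replicate, binomial No-counts are
  drawn per participant per probe-type condition (12 trials per condition
  by default) from a generating preset; both schemes are fitted, BICs
  averaged over the group, and the replicate is won by the scheme with
  the lower mean BIC (ties count against the generating model).
  Replicates are nested across group sizes (2–10 by default, 500
  replicates), so the power curve is evaluated under paired draws.
  The generating presets are the two observer presets above; the original
  pilot probabilities behind the registered analysis are not public, so
  these runs are reference conditions rather than reproductions — under
  the Table-anchored averaging preset power at n = 10 is ≈ 0.87–0.94
  rather than > .95.

## Problem sizes used in the shipped validation

The test suite and the acceptance script run entirely on synthetic data:
24 simulated participants per single-dimension experiment (the studies'
own scale), ~10,000 trials for the estimator-consistency check, 100
sessions for noisy parameter recovery, 200–500 synthetic participants for
scheme recovery, and 500 bootstrap replicates for the power and
type-I-error checks.

## Known limitations

* The location (b) and slope (c) of the log-logistic are weakly
  identified from 5–6 category proportions even at 480 trials per
  session: their per-session sampling IQRs are ≈ 1.4 and ≈ 0.5, and
  nonlinear least squares leaves a small median bias (≈ 0.1 on b) that no
  amount of per-session data at this design can remove.  The floor
  parameter a is well identified.  Conclusions in this pipeline rest on
  fit comparison and the point prediction, not on the absolute values of
  b and c.
* The Gaussian-BIC scheme comparison is reported for continuity with
  conventional practice but is close to uninformative for
  averaging-generated data (see above); the binomial variant is the
  recommended model-selection statistic.
* Reading deposited raw data requires a user-supplied column mapping;
  no foreign layout is hard-coded.
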