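# ensembleyn

Analysis toolkit for Yes/No ensemble-perception experiments: does
recognition of a briefly seen set of features reflect a stored *average*
of the set, or the probe's *similarity* to the values actually shown?

The package targets the four-experiment probe-recognition design in which
a 500-ms memory display of 64 bars carries two "old" feature values from a
7-step series (orientations 0°–90° in 15° steps, or 7-level green/blue
luminance ladders), and a single probe — the never-shown mean (M), an old
value (O), or a novel value outside the old range (N) — is judged
present/absent.  It provides, for researchers in visual psychophysics and
for anyone who needs the statistical machinery:

* a **synthetic-observer simulator** generating full trial sequences for
  all four designs (including the 3×3 relevant × irrelevant probe
  factorials) and binomial Yes/No responses from parameterized *averaging*
  or *similarity* observers;
* the **similarity point prediction** p(No|M) = p(No|N1A)·p(No|N1B) and
  its paired test (t, Cohen's d, JZS Bayes factor);
* **log-logistic psychometric fits** p(No; x) = a + (1−a)/(1+e^{b−cx}) of
  each participant's data under the distance-from-mean and
  distance-from-old classificatory schemes, compared by BIC;
* **repeated-measures ANOVAs** (one-way and 3×3, each effect against its
  own participant interaction) with Tukey HSD post hocs;
* the **registered bootstrap power simulation** for BIC scheme recovery;
* canonical **CSV trial-table I/O** with a column-mapping adapter for
  foreign data layouts.

See `docs/methods.md` for the model, estimators and numerical choices.

## Worked example

Simulate 24 averaging observers on the orientation design and run the
full analysis:

```sh
ensembleyn run-all --experiment 1 --observer exp1 --participants 24 \
    --seed 7 --out-dir results/exp1
```

```
retained 24 participants; similarity test t(23) = -4.881, p = 6.265e-05
outputs in results/exp1
```

The paired test compares each participant's observed p(No|M) with the
similarity product prediction built from their N1 probes.  A *negative* t
means the mean probe was accepted more often than similarity alone
predicts — the averaging-observer signature.  The bundle contains the
trial table, exclusion log, per-category condition tables, per-participant
fits under both schemes, the BIC comparison, and the ANOVA with its Tukey
chain (here `N1 > Old > M`: the never-shown mean is rejected *less* often
than values that were actually displayed).

The power simulation behind the design's sample size:

```sh
ensembleyn power --preset exp1 --group-sizes 2:10 --trials 12 \
    --reps 500 --seed 1 --out results/power.csv
```

which reports, per group size, the fraction of 500 bootstrap replicates
in which the generating model's classificatory scheme wins the
group-average BIC comparison, with Clopper–Pearson intervals.

Everything is importable as a library (`ensembleyn.synthetic_data`,
`.descriptives`, `.psychometric_fit`, `.inference`, `.power_sim`,
`.pipeline`) and fully deterministic under a seed.

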