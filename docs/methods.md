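# Methods

This note documents the models implemented in `rulegen`, the parameter
choices that matter, and what the synthetic data can and cannot show.

## Canonical distributions

All analyses are built on three training distributions of 24 tokens per
block: `Skew4 = [14, 6, 3, 1]`, `Unif4 = [6, 6, 6, 6]`, and `Unif8 = [3] × 8`.
The skewed vector is not arbitrary: among all descending 4-part compositions
of 24 it is the only one with a rank-1 frequency of 14, a rarest type of
frequency 1, and a Shannon entropy that rounds to 1.52 bits — the three
published properties of the distribution. The test suite re-verifies this
uniqueness by enumeration. Scaling by the number of blocks (24 → 72 tokens
over three blocks) leaves entropy and all rank-based comparisons unchanged.

## Productivity measures

* **Entropy** is computed in bits (base-2 log) with the convention
  `0·log 0 = 0`. It is maximal for uniform distributions and decreases with
  skew; it is scale-invariant, so per-block and post-training values agree.
* **Tolerance Principle**: `θ_N = N / ln N` is kept at full floating-point
  precision internally; rounding to one decimal (θ₈ ≈ 3.8, θ₁₂ ≈ 4.8) happens
  only in presentation. `N < 2` is rejected: the threshold is degenerate
  there.
* **Potential productivity** `P` divides the hapax count by the token count.
  It is comparable across samples only at equal token counts, which holds by
  construction here (24 or 72 tokens per suffix).
* **Low-frequency-tail comparison** walks the two frequency spectra over all
  integer frequencies 1, 2, 3, … up to the larger maximum, including
  frequencies absent from both (count 0 on both sides decides nothing), and
  prefers the distribution with more types at the first frequency where the
  counts differ. Identical spectra are a tie. This makes the comparison a
  strict weak order that is antisymmetric by construction.
* **Vocabulary growth curves** average the distinct-type count after each
  prefix of a shuffled 24-token block over 100 randomisations (the default
  replicate count). The ribbon is a normal-approximation 95% confidence
  interval for the mean; a percentile band is not used because, with
  integer-valued curves, its bounds need not bracket the mean.

## Synthetic experiment

The generator reproduces the experiment's structure exactly: per-participant
random assignment of the two suffixes to distributions, stems drawn from the
20 printed nonce stems and mapped bijectively to frequency ranks (8 stems in
group 1, 12 in group 2), three training blocks of 48 trials shuffled within
block (24 tokens per suffix per block, 144 trials in total), and a 16-trial
test phase with 8 familiar stems (4 per distribution; for Unif8, 4 of its 8
stems sampled without replacement) and 8 distinct novel stems. Novel stems
reuse the untrained printed stems first and fall back to generated CVC/CCVC
fillers disjoint from the printed list; the number of *distinct* novel stems
is not fixed by the design description, so eight distinct stems is an
assumption of this implementation. The practice phase (16 trials for group 1,
24 for group 2) is exposed as a design constant but not behaviourally
modelled: only test-phase responses feed any analysis.

Simulated participants respond by independent Bernoulli draws: correct on
familiar trials with probability `p_correct_familiar` (default 1.0, the
perfect learners analysed throughout), and non-baseline on novel trials with
probability `p_nonbaseline_novel`. The default bias is `logistic(0.26) ≈
0.565`, the grand-mean preference estimated for perfect learners in the
original data; it is a generating parameter here, not a fitted quantity.

The analysis summary is a participant-level percentile bootstrap (default
2,000 resamples) of per-participant non-baseline proportions, in place of a
hierarchical Bernoulli regression: the regression's target data (real
participants) are out of scope, and the bootstrap supports the same recovery
checks — point estimates within 0.03 of the generating bias at 1,000
participants, and ≥ 90% interval coverage at 50.

What the synthetic data do **not** emulate: learning dynamics within
training, item-level or participant-level heterogeneity beyond the single
bias parameter, reaction times, and any semantics. Passing recovery tests
therefore shows the pipeline is consistent and unbiased under its own
generative assumptions, not that real participants satisfy them.

## Urn model

Each learner holds one urn per suffix; training fills the urns with the full
72-token canonical input. In the test phase familiar stems are answered with
the correct urn (and their token added to it); for novel stems the learner's
strategy nominates a preferred urn, ties are resolved by a fair coin, the
preferred urn's token count is augmented by the learner's preference strength
`k`, and the urn is sampled from the normalised counts. `k` is drawn once per
learner from Poisson(λ); λ ranges over {1, 5, 10, 20, 50, 100} in the default
grid, putting the largest values on the scale of the 72 observed tokens. For
probability matching `k` is forced to 0, which realises "not swayed by any
property" exactly and coincides in distribution with augmenting a
coin-chosen urn while the urns are symmetric.

The strategy's preference is recomputed before every novel trial on the
urns' *current* contents, so chosen urns accumulate frequency-1 types and
reinforce themselves (the rich-get-richer dynamic of a two-table Chinese
restaurant process). A static variant that freezes the preference at its
post-training value is available behind a flag for sensitivity analysis. The
Tolerance-Principle strategy takes `N` to be all distinct types currently in
either urn and treats the other urn's types as the exceptions, which
reproduces the N = 8 / N = 12 arithmetic at the start of test and extends it
as types are added.

Reproducibility: every learner gets an RNG substream derived from the master
seed by `SeedSequence` spawn keys `(strategy, λ, group, learner)`, so cells
are independent and identical regardless of execution order. Languages are
regenerated per learner; since all quantities are rank-based this choice does
not affect the results. Per-learner outcomes are proportions of 8 novel
trials, hence multiples of 1/8; cell means at 1,000 learners carry a
Monte-Carlo standard error below ~1.6 percentage points even in the worst
(bimodal) case.

## Bayesian model

The latent population behind each observed distribution is modelled as a
categorical distribution over the observed types plus `n ∈ {1, 2, 5}` unseen
types, with a symmetric Dirichlet(α) prior; α defaults to 1 (uniform on the
simplex). The posterior is conjugate — Dirichlet(counts + α), posterior mean
`(c_i + α)/(tokens + αK)` — which keeps every downstream quantity exact or
cheaply simulable and testable against closed forms. The original analysis
fitted the categorical model with a regression package's default
softmax-scale priors; the conjugate prior is a deliberate divergence chosen
for exactness, so the model's outputs are compared at the level of
qualitative patterns, not decimal places.

The missing-type likelihood draws 8,000 probability vectors from the
posterior (the published dataset count), generates one multinomial dataset
per vector with as many tokens as the observed sample — the natural reading
of "samples just like the training data" — and reports the fraction of
datasets in which at least one population type has zero tokens ("fails to
contain every type" is read as *missing at least one*). Monte-Carlo standard
errors accompany every proportion. A cell whose raw proportion is exactly
zero (possible at 72 tokens for Unif4) reports the MC upper bound
`3/n_datasets` instead, flagged, so that the posterior normalisation stays
defined. With a uniform prior over a group's two candidate distributions the
posterior is the normalised likelihood pair.

The conjugate closed form is cross-checked in the tests against two
independent oracles: Monte-Carlo Dirichlet sampling (posterior means within
3 MC standard errors) and the inclusion–exclusion formula
`P(miss ≥ 1) = Σ_{∅≠S} (−1)^{|S|+1} (1 − Σ_{i∈S} p_i)^n` for point-mass
populations.

## Problem sizes and numerical choices

Defaults mirror the study conditions: 1,000 learners per grid cell, 8,000
posterior-predictive datasets per likelihood, 100 vocabulary-growth
randomisations, 2,000 bootstrap resamples. Unit tests exercise smaller
configurations of their own choosing where a property does not require the
full size (e.g. 150–400 learners for equivalence and monotonicity checks,
with tolerances set from the binomial standard error at that size); the
acceptance-level checks run the full 1,000-learner cells and 8,000-dataset
sweeps. Ties in floating-point entropy comparisons are exact-equality ties;
with the canonical integer counts no near-tie ambiguity arises.

## Known limitations

* The urn simulator is restricted to exactly two urns; no new-category
  creation, and no iterated transmission between learners.
* The Bayesian module's priors are conjugate Dirichlet, not the original
  softmax-Gaussian defaults; absolute likelihood values will differ from the
  original figures even where the patterns agree.
* The bootstrap summary estimates a group mean; it does not model
  participant-level variance components and cannot recover anything beyond
  the mean bias it is tested on.
* Real-data regression estimates of learning accuracy are not reproducible
  here and are not attempted.
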