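# Methods

## Data model

The unit of analysis is an individual observed at two time points on k
ordinal domains (default k=7: functioning, distress, nutrition, activity,
sleep, social, substance — this registry order is fixed and doubles as the
deterministic tie-break order everywhere). Levels are poor < fair <
healthy, coded 0/1/2. The CSV dialect is one row per individual with
`<domain>_t0` / `<domain>_t1` columns; labels are case-insensitive on read
and lower-case on write. When raw visit sequences are supplied, baseline is
the first visit and follow-up the earliest visit between `min_days=7` and
`max_days=183` after it (one week to six months, with a month taken as
30.5 days; the exact six-month bound is configurable since conventions
differ). Individuals with no visit in the window are dropped and counted.
Panels are assumed complete per record; missing-data handling is out of
scope.

## Structure posterior

The causal model is a DAG over the 2k temporal variables with the hard
constraint that follow-up nodes cannot point at baseline nodes; edges
within either slice and from baseline to follow-up are allowed. The prior
over admissible DAGs is uniform.

**Score.** Ordinal codes are scored as Gaussian via the BGe marginal
likelihood after per-column standardization (a constant column is rejected
with an explicit error — its direction information is void). This keeps
the category ordering in the likelihood while staying decomposable and
identical across Markov-equivalence classes. Hyperparameters follow the
literature defaults: `alpha_mu = 1`, `alpha_w = d + 2` (d = 2k), prior
mean zero, prior scale `t·I` with `t = alpha_mu (alpha_w − d − 1) /
(alpha_mu + 1)`. The per-family score is a difference of two subset
marginal likelihoods whose degrees of freedom carry the `−d + |W|`
determinant correction; without it, subset marginals would be inconsistent
and score equivalence would fail (the test suite checks equivalence to
1e-8 and the empty-parent family against an independently coded scalar
formula).

**Sampler.** States are ordered node partitions; a partition stands for
all DAGs whose parents lie in strictly earlier blocks with at least one
parent in the immediately preceding block, which assigns every DAG to
exactly one partition. Because the score is decomposable, a partition's
score is a per-node log-sum-exp over admissible parent sets, bounded by
`max_parents = 4` (with 14 nodes and that bound, all per-node sums are
exact and the score table — about 8,000 families — is precomputed once).
Moves: split a block (uniform over ordered splits), merge adjacent blocks,
relocate a single node into any block or gap, swap adjacent blocks. A move
is drawn uniformly from the concrete neighbour set and accepted by
Metropolis–Hastings with the exact neighbourhood-size correction; each
concrete move has a unique concrete inverse, so the kernel is reversible.
Chains start from the single-block partition (the empty graph, always
finite). One DAG is drawn per retained partition draw by sampling each
node's parent set proportionally to its family score — an exact draw from
the posterior restricted to that partition; weighting partitions
analytically instead would estimate the same expectations, and per-draw
DAGs keep every downstream quantity a plain Monte-Carlo average.

**Defaults and diagnostics.** 8 chains, 60,000 iterations, 20,000 burn-in,
thinning 40; chain c is seeded from
`SeedSequence(master_seed, spawn_key=(c,))`, so runs are bit-reproducible.
The convergence report is the maximum over directed pairs of the
cross-chain spread (max − min) of edge probabilities, with a 0.05
tolerance; failure downgrades a pipeline run with a prominent warning
rather than aborting. On small problems the sampler is validated against
exhaustive enumeration (≤5 nodes, uniform prior), and the partition score
against an explicit sum over the compatible-DAG set.

## Networks and interventions

Each sampled DAG is fitted as a categorical Bayesian network. CPT cells are
`(count + c) / (row_total + 3c)` with pseudocount `c = 1` — the mode of a
symmetric Dirichlet(2) posterior. The smoothing matters: with up to 3^4
parent configurations per node and cohort-scale n, many rows are sparse or
empty (empty rows become uniform). The pseudocount is configurable because
reasonable fits differ; sensitivity to it is not resolved here.

Follow-up inference clamps baseline nodes to the observed profile and
evaluates follow-up CPTs exactly; baseline CPTs are fitted but unused in
inference. The reference path enumerates the full 3^k joint; the
production path computes each domain's marginal by summing only over its
within-follow-up ancestor set, vectorized across baseline states, and is
tested for exact equality against the enumeration. The do-operation on a
domain removes all edges into its *follow-up* node and replaces its CPT by
a point mass on healthy — the intervention acts at follow-up; the original
network is never modified. A hand-computed confounded example pins down
the difference between conditioning on a healthy outcome and intervening
to produce one.

## Decision layer

Utilities are additive: `U(x) = Σ_d w_d u(x_d)` with named subutility
presets default `(0, 0.75, 1)` (moderately risk-averse), risk_neutral
`(0, 0.5, 1)`, risk_averse `(0, 1, 1)`, and nonnegative per-domain weights
(default 1, so U ranges 0–7 over seven domains). Additivity means the
exact EU needs only per-domain follow-up marginals. Preference order is
invariant under positive affine maps of the subutility, which the suite
checks numerically.

Posterior EU is the mean of per-network exact EUs. The headline SE is a
Monte-Carlo standard error using an effective sample size from the Geyer
initial-positive-sequence autocorrelation estimate of the per-draw EU
series (draws inherit the chain's autocorrelation); the posterior SD is
reported alongside, since either convention is defensible. The ATE of a
target is the *paired* per-draw difference against doing nothing — by
linearity identical to the difference of means, asserted to 1e-12.

`p_opt` and `p_rec(N)` resolve optimality per posterior draw — giving
genuine probabilities rather than a point ranking — and weight baseline
states by their empirical frequency (unobserved states get weight zero; no
smoothing model is imposed). `nothing` is excluded from these tabulations
but always reported in per-state rankings. Ties are broken by registry
order and recorded. The shipped up-weighting example for the sensitivity
analysis (weight 2 on distress and functioning) is illustrative, not an
elicited preference.

## Synthetic generator

The generator emulates the statistical shape the analysis assumes: seven
3-level domains; baseline levels drawn independently per domain from
cohort-like marginals (e.g. activity ≈ 75% healthy, social ≈ 43% poor);
strong same-domain persistence (`autoregressive_strength = 0.6` is the
probability mass placed on repeating the baseline level, the remainder
spread as the domain's marginal); and sparse cross-domain structure —
2 lagged plus 4 within-follow-up edges by default, mirroring the edge
classes a two-slice analysis distinguishes. Cross effects are log-linear
likelihood-ratio tilts `exp(effect_size · (p−1) · (l−1))` with
`effect_size = 1` (a healthy-vs-poor parent shifts the child's
healthy-to-poor odds ratio by e²) — monotone by construction, which the
suite asserts over every table. Total in-degree is capped at
`max_in_degree = 4` so the generating model stays inside the learner's
default parent-set bound. Within-baseline dependence is available but off
by default; its strength in real cohorts is unknown.

What the generator does *not* emulate: baseline cross-domain dependence
(real cohorts show a dense baseline network, so real panels concentrate
more mass on profiles like all-healthy than independent marginals do),
enrolment/retention selection, item-level measurement, and time-varying
effects. Passing recovery tests therefore demonstrates correctness of the
machinery under the stated generative assumptions, not validity of causal
conclusions on any particular real cohort.

Ground truths expose the exact-EU optimal target per baseline state
(enumeration on the true network), enabling end-to-end checks: at n=5000
with defaults, all autoregressive edges are recovered above 0.8 posterior
probability and the modal recommended target matches the exact optimum on
the most frequent baseline states.

## Problem sizes used in the checked runs

The automated checks run the sampler at reduced but sufficient sizes
chosen once: 3-node oracle comparisons use 4 chains × 8,000 iterations;
the mixing check 4 × 80,000; the 14-node end-to-end recovery 4 × 12,000
iterations on an n=5000 panel with 100 fitted networks. The scoring table
is precomputed, so panel size barely affects sampling cost.

## Known limitations

- Within-slice cycles are excluded by the acyclicity assumption; feedback
  at a single time point is not representable.
- Orientation of within-slice edges can be weakly identified; chains may
  dwell in different orientation modes, which the convergence spread
  surfaces. Longer runs help; borderline edges (posterior near the prior)
  mix slowest.
- The BGe-on-codes treatment of ordinal data is a pragmatic compromise; a
  probit/rank likelihood would be more faithful but lacks this closed
  form.
- One decision epoch only: no sequential policies, no intervention costs,
  no utility elicitation machinery.
- The empirical baseline weighting assigns zero mass to unobserved
  profiles, which is exactly right for cohort summaries and wrong for
  extrapolation.
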