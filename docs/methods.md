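# Methods

## The observer model

A disk of radius `s` (mm) held edge-on between thumb and index finger
produces three conditionally independent Gaussian size measurements per
presentation: `Thumb ~ N(s, σ_T)`, `Index ~ N(s, σ_I)` (cutaneous,
curvature-driven) and `Config ~ N(s, σ_C)` (proprioceptive, width-driven).
An observer is characterised by the sigma triplet and by one of three
combination rules applied identically on every presentation:

| rule | percept `ŝ` | percept SD `σ_ŝ` | PSE-vs-conflict slope |
|---|---|---|---|
| WTA | sample of the min-σ cue | `min σ` | +1 if config is best, else −1 |
| AVG | arithmetic mean | `√(σ_T²+σ_I²+σ_C²)/3` | −1/3 |
| OPT | inverse-variance weighted mean | `1/√(Σ 1/σ²)` | `(1/σ_C² − 1/σ_I² − 1/σ_T²)/Σ(1/σ²)` |

Useful limits: OPT → WTA as one σ → 0, OPT → AVG as the σs equalise, and
`σ_ŝ(OPT) ≤ min σ` always. All rules are unbiased, so single-interval
percepts carry no systematic error; only a cue-conflict stimulus, which
moves the config-cue mean to `s + c` and the cutaneous means to `s − c`,
separates the rules' *mean* percepts. Because every percept is linear in
the cue samples, the conflict-induced PSE shift is exactly linear in `c`
with the slopes above.

Degenerate inputs are handled deterministically: exact ties for the most
reliable cue resolve with the fixed priority config > index > thumb, and a
WTA observer whose best cue is cutaneous has slope −1 (its cue mean moves
opposite to the conflict). Both conventions only matter on
measure-zero inputs but keep tests and seeds reproducible.

## 2IFC task and psychometric function

A trial presents a reference and a comparison (radius `reference + Δ`) in
random order; the response is "comparison larger" iff the comparison
interval's percept exceeds the reference interval's (exact ties, possible
only in degenerate noiseless tests, are broken by a fair coin). The
difference of two independent percepts has SD `√2 σ_ŝ`, so the response
probability is

    Ψ(Δ) = Φ((Δ − μ) / (√2 σ)),

with `μ = 0` for circular references and `μ` = the PSE shift for conflict
references. The `√2` conversion from the single-interval scale is applied
exactly once, at likelihood evaluation; all model predictions stay on the
single-interval scale. Counts `k_Δ` are of comparison-judged-larger
responses (consistent with Ψ above); the correct-response bookkeeping is
the mirror image `k ↔ n − k` at negative Δ.

There is no lapse parameter: Ψ genuinely asymptotes at 0 and 1. A single
"impossible" response therefore annihilates the likelihood at the offending
parameter values — accepted as part of the model, with `log_ndtr` keeping
every value finite and an underflow floor applied only to max-centred
log-likelihoods during normalisation (−745, below which `exp` underflows;
centring first guarantees the floor can never reorder parameters).

## Bayesian estimation

Single-cue σ posteriors use a uniform prior on a fixed grid, 0.01–40.01 mm
in 0.05 mm steps (801 points); conflict conditions get a joint (μ, σ)
posterior with μ uniform on −5…+5 mm in 0.1 mm steps. Likelihoods omit
binomial coefficients (constant in the parameters). The PSE estimate is the
mode of the μ marginal, ties broken toward the smallest |μ| so that
symmetric evidence yields 0. Posterior draws use inverse-CDF sampling with
linear interpolation restricted to mass-bearing grid points, so a
point-mass posterior yields constant draws.

Grid bounds matter at small trial counts: at 8 levels × 20 trials, levels
spanning ±5 mm barely constrain σ above ~10 mm, so posteriors for noisy
cues are strongly right-skewed (mode near truth, mean far above). This is
faithful to the data, not a defect, and it is exactly the uncertainty the
triplet-sampling stage propagates into model comparison.

## Model comparison

For one observer, three single-cue posteriors are sampled independently
(one draw per cue) to form σ triplets; the default 1,000 triplets are
shared by all three candidate rules. Each rule maps a triplet to predicted
psychometric parameters — `σ_ŝ` alone for non-conflict Combined data, a
(`μ_c = slope × c`, `σ_ŝ`) pair per conflict level for conflict data, with
the WTA best cue re-evaluated per triplet. The rule's marginal likelihood
is the plain arithmetic mean of the per-triplet data likelihoods
(log-sum-exp internally; conflict conditions enter jointly). With a uniform
model prior the normalised marginals are posterior model probabilities;
the classification is the argmax, exact ties resolving OPT > WTA > AVG and
flagged in the output. Posterior-probability ratios equal Bayes factors by
construction.

## Synthetic populations and the validation experiments

Observers are drawn with each σ_cue sampled from `N(M_cue, S_cue)`
truncated below at 0.1 mm (a floor far below any plausible threshold; the
truncation bias is negligible except for the widest populations). Three
stock populations cover the qualitatively distinct regimes:

1. exceptional config cue — M = (8, 8, 2), S = (2, 2, 1) mm;
2. similar sigmas — M = (4, 4, 4), S = (0.1, 0.1, 0.1) mm;
3. varied sigmas — M = (7, 6, 3), S = (2, 3, 1) mm.

The stock experiment designs use a 10 mm reference with comparison radii
{5, 8, 9, 9.5, 10.5, 11, 12, 15} (Δ = ±0.5, ±1, ±2, ±5 mm), 20 trials per
level per condition, four conditions (Thumb, Index, Config, Combined) or —
for the conflict experiment — three single-cue blocks plus one block per
conflict level in {−3, −2, +2, +3} mm, conflict references paired against
circular comparisons only. A 15 mm-reference variant and an adaptive-
schedule variant mirror the other tested designs.

The validation tables (`run_table1`, `run_table2`, `scripts/acceptance.py`)
classify 1,000 simulants per generating rule from population 1. That
population is the default because it reproduces the empirically typical
regime — finger configuration far more reliable than the cutaneous cues —
and because it is the regime in which the classification problem shows its
characteristic structure: heavy OPT↔WTA confusion with circular disks
(their predictions nearly coincide when one cue dominates), a cleanly
separable AVG, and a large accuracy gain for every generating rule when
conflict stimuli are added. Under the varied-sigma population the AVG rule
is instead systematically under-recovered at these trial budgets: the
right tail of the cutaneous σ posteriors inflates `√(Σσ²)/3` predictions
and AVG-generated observers leak to WTA, so that population exercises the
pipeline but does not exhibit the reference classification rates.

What the generator deliberately does not emulate: lapses and attentional
drift, learning across blocks, heteroskedastic (Weber-like) cue noise,
inter-cue correlations, and any contact-mechanics detail of real stimuli.
Passing tests therefore demonstrate internal consistency of the inference
chain and recoverability under the stated noise model — not that human
data obey it.

## Adaptive stimulus selection

The adaptive schedule greedily presents the candidate Δ (from the design's
disk set) maximising the expected reduction in posterior entropy, computed
exactly on the grid by marginalising over the two possible responses; no
lookahead. The running posterior is over σ (circular references) or (μ, σ)
(conflict references) and is updated trial by trial with the same Ψ as the
offline fits. This is a standard entropy-greedy member of the
adaptive-testing family rather than a bit-exact reconstruction of any
particular published procedure. With matched budgets it yields lower
posterior entropy than constant stimuli on average (asserted in the test
suite over 200 replicates).

## Problem sizes and determinism

Default sizes throughout are the study-scale ones: 8 levels × 20 trials
per condition, 1,000 triplets, 1,000 simulants per cohort in the
validation tables (about 40 s total on one CPU; the test suite samples the
same pipelines at full scale for the table checks and smaller scales
elsewhere). Every stochastic entry point takes a `numpy` `Generator`; cohort
runs spawn one child stream per observer from the master seed, so results
are reproducible end to end and independent of observer order. Reports
serialise numbers at full precision and round only for display.

## Known limitations

- Grid posteriors are exact only up to discretisation; σ below 0.01 mm or
  above 40.01 mm and |μ| > 5 mm are unrepresentable by construction.
- The marginal likelihood is a finite-sample average; its Monte Carlo SE
  (≈0.02–0.05 log units at 1,000 triplets for typical data) can flip
  classifications when two rules' predictions nearly coincide, which is
  precisely the OPT/WTA regime of population 1 and 2 — an inherent
  property of the design, not of the estimator.
- `analyze_dataset` fixes its own trial-log schema; external data would
  need a thin column-mapping layer.
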