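# Methods

## The model

`ddonmix` estimates abundance of several species simultaneously from
*dependent double-observer* (DDO) point-count surveys. In a DDO survey a
primary observer calls out every individual they detect; a secondary
observer records those and additionally any individuals the primary
missed. Because the secondary observer verifies the primary's records,
the protocol suppresses false positives (misidentifications and double
counts), and the removal structure identifies detection probability.

The model has two hierarchical layers.

**Biological process.** Latent abundance of species *i* at plot *j*
(and, in the covariate variant, year *y*) is Poisson,

    N_ij ~ Poisson(lambda_i)                       (basic)
    N_ijy ~ Poisson(lambda_ijy)                    (covariate)
    log lambda_ijy = beta0_i + beta1_i * ownership_j
                     + beta2_i * year_y + alpha_j

with `ownership` and `year` binary codes and `alpha_j ~ Normal(0,
sigma_plot^2)` a plot random effect. The population is closed within a
season: the same `N` underlies all `K` replicate visits. In the basic
variant the log mean is a species-level effect, constant across plots;
no information is shared between species in the abundance layer.

**Observation process.** On each visit every one of the `N` individuals
falls into one of three outcomes with probabilities

    pi1 = p1                 primary detects
    pi2 = (1 - p1) * p2      secondary detects a primary miss
    pi3 = (1 - p1) * (1 - p2)  both miss

so the observed pair of counts `(y1, y2)` is trinomial in `N`:
`(y1, y2, N - y1 - y2) ~ Multinomial(N, (pi1, pi2, pi3))`. In the basic
detection structure there is one probability per observer *role*; the
`by_observer` structure gives each observer identity its own
probability, and `by_observer_and_species` adds sum-to-zero species
offsets on the logit scale (additive rather than fully crossed, to stay
identifiable at realistic survey sparsity).

**Priors.** Log mean abundance and regression coefficients get vague
Normal(0, 1000-variance) priors. Detection probabilities are
Uniform(0, 1) by default — equivalently, standard-logistic on
logit(p). A vague logit-Normal(0, 10000) alternative is available
(`Priors.detection_prior="logit_normal"`); note that on the probability
scale that density concentrates almost all mass near 0 and 1, which is
why it is not the default. The plot-effect standard deviation has a
Uniform(0, 100) prior. In practice the two detection priors give
indistinguishable results on the designs shipped here, because the
likelihood dominates.

## Inference

Fitting is by Metropolis-within-Gibbs MCMC (`ddonmix.mcmc.fit`), with a
fixed sweep order chosen once for reproducibility:

1. **Latent abundance, exactly.** The full conditional
   `p(N | y, lambda, pi) ∝ Poisson(N; lambda) * prod_k Trinomial(y_k; N, pi_k)`
   is discrete with a hard floor at `max_k (y1_k + y2_k)`. It is sampled
   by direct enumeration on a window above the floor. The window starts
   at a Poisson tail bound at rate `lambda * pi3` and doubles until the
   largest normalised weight in the final column is below 1e-10, so the
   truncation error is negligible by construction. All sites are updated
   in one vectorised pass.
2. **Detection.** The trinomial factorises into a primary-observer
   binomial (`y1` of `N`) and a secondary-observer binomial (`y2` of
   `N - y1`), so each observer slot has two scalar sufficient statistics
   (successes, failures) and is updated by a random-walk Metropolis step
   on the logit scale.
3. **Abundance parameters.** Random-walk Metropolis on `log lambda_i`
   (basic), or per-species blocks of `(beta0, beta1, beta2)`, individual
   `alpha_j` updates, and a scalar `sigma_plot` move that respects the
   uniform support (covariate variant).
4. **Ridge move.** The posterior of N-mixture models is strongly
   correlated along "more individuals, everyone detects less": the data
   pin the products `lambda * pi1` and `lambda * pi2` far more tightly
   than the factors. Componentwise walks cross this ridge slowly, so an
   extra symmetric Metropolis move (applied three times per sweep)
   translates every log mean by `delta` while lowering all logit
   detections by `(5/3) * delta` — the coefficient `1/(1 - p)` that
   would hold `lambda * p` exactly constant, evaluated at p = 0.4. The
   move is plain Metropolis on the same posterior; it changes mixing
   speed, not the stationary distribution. With it, the desk-scale
   protocol below reaches split R-hat ≈ 1.02 instead of ≈ 1.08.

Step sizes adapt multiplicatively during burn-in only (target acceptance
0.2–0.5, checked every 50 iterations) and are frozen afterwards, so the
kept draws come from a fixed kernel. Chains start from over-dispersed
values: logit detections at Normal(0, 1.5^2), log means at a crude
moment estimate (the mean detected floor) plus Normal(0, 1.5^2) jitter,
and `N` at its floor plus Poisson(2) jitter. Centering the abundance
starts on the crude estimate keeps the starts over-dispersed relative to
the posterior while letting short burn-ins reach stationarity. If the
initial state has non-finite posterior density it is redrawn at halved
dispersion (up to six times).

A dataset with zero plots short-circuits every likelihood term, so the
same machinery samples the priors; the prior-recovery tests use exactly
this path.

## Chain protocol and diagnostics

The reference protocol is 3 chains of 50,000 iterations with the first
5,000 discarded as burn-in and no thinning. Convergence is assessed by
the potential scale reduction factor computed on *split* chains (each
chain halved before the classic among/within variance ratio), which also
detects within-chain drift; values below 1.01 at full length and below
1.05 at the reduced desk-scale protocol are treated as converged.
Posterior summaries report the pooled mean, SD and equal-tailed 95%
credible interval, with percentiles by linear interpolation between
order statistics (the numpy default) — fixed and documented because the
interval endpoints feed the coverage metric. Monitored parameters are
the abundance and detection parameters; per-site latent `N` draws are
stored but excluded from the convergence gate.

## Synthetic data

`simulate_basic` generates the canonical evaluation design: 4 species,
20 plots, 3 replicate visits, one season, primary detection 0.3 and
secondary 0.5, shared across species. Species mean abundances default to
`log lambda_i ~ Uniform(log 2, log 30)`, drawn afresh per dataset, so
repetitions span rare (~2 per plot) through common (~30 per plot)
species; fixed vectors can be supplied. Counts are generated by the
two-stage mechanism itself (primary binomial, then secondary binomial on
the misses), which is exactly the trinomial.

`simulate_covariate` emulates the two-year field layout: 80 plots split
evenly public/private, ownership/year/plot effects on the log mean, and
an observer pool (default 2 with fixed roles; the `casestudy` preset
uses 14 observers with logit-normal heterogeneous detection spanning
roughly 0.1–0.8, and random pair assignment per visit).

What the generator does *not* emulate: availability (every individual is
assumed present and available at each visit), false positives (the DDO
premise is that they are negligible), unbalanced designs, missing
visits, and any temporal movement within a season. Passing tests
therefore demonstrate correct recovery under the model's own
assumptions, not robustness to their violation.

## Evaluation harness

`run_study` repeats simulate → fit → summarize with per-repetition seeds
spawned deterministically from a root seed (results are independent of
parallelism and repetition order). Two metrics follow:

* **Coverage** — the fraction of (parameter, repetition) pairs whose
  equal-tailed 95% CRI contains the generating value, with endpoint hits
  counted as covered. The primary abundance unit is the species mean
  `lambda_i` (4 per repetition); coverage of the plot-level latent `N`
  is reported secondarily. Detection coverage pools the two observer
  probabilities.
* **MAPE** — `100 * |posterior mean - truth| / truth` per parameter and
  repetition, summarised as the grand mean and binned (abundance: 0–20,
  21–40, …, >100 percent; detection: integer percent bins). Zero truths
  would make the metric undefined and are excluded with a logged count
  (they cannot occur with the shipped generators).

Repetitions with any monitored R-hat ≥ 1.1 are flagged and counted, but
kept in the summaries.

### Problem sizes

The shipped study configurations use 25 repetitions (test suite) or 50
repetitions (`scripts/acceptance.py`) at 3 chains × 6,000 iterations
with 1,000 burn-in, plus one full-length 3 × 50,000 fit for the
convergence bound. These sizes give binomial Monte-Carlo standard errors
of about 2% on coverage estimates while keeping a complete run in the
minutes range on a single core; the full 100-repetition, full-length
protocol is a straightforward configuration change
(`StudyConfig(n_reps=100, mcmc=MCMCConfig())`).

## Known limitations

* Detection accuracy at this design is limited by the abundance–detection
  ridge. The exact posterior (validated against brute-force quadrature)
  has sd(p_hat) ≈ 0.02–0.045 at the default design, so per-repetition
  detection MAPE averages around 5% with occasional values above 10%,
  even though coverage is nominal. More plots or replicates — not more
  individuals — tighten it.
* The basic variant shares detection across species; strong real-world
  species effects require the `by_observer_and_species` structure.
* Equal-tailed intervals are reported; for strongly skewed marginal
  posteriors (rare species) HPD intervals would be shorter.
* The sampler is exact but single-threaded per chain; very large designs
  (hundreds of plots, many species) will be slow compared to
  gradient-based approximations.
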