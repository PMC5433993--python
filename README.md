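# ddonmix

Multispecies abundance estimation from **dependent double-observer (DDO)**
surveys, via a hierarchical Bayesian N-mixture model.

In a DDO survey, a primary observer dictates every individual they detect
to a secondary observer, who records those plus anything the primary
missed. The protocol suppresses false positives (misidentification,
double counts) because two observers confirm each record, and its removal
structure identifies detection probability. `ddonmix` combines that
observation process with a multispecies N-mixture abundance layer:

```
N_ij  ~ Poisson(lambda_i)                     latent abundance, species i, plot j
y_ijk ~ Multinomial(N_ij, (pi1, pi2, pi3))    replicate visit k, with
pi1 = p1,  pi2 = (1-p1) p2,  pi3 = (1-p1)(1-p2)
```

where `p1`, `p2` are the primary and secondary observers' detection
probabilities and the third (unobserved) cell counts the individuals both
missed. A covariate variant models `log lambda` with land-ownership and
year effects plus a plot random effect, and per-observer (optionally
per-species) detection. The posterior is sampled by Metropolis-within-Gibbs
MCMC with an exact enumeration update for the latent `N` (see
`docs/methods.md` for the full model, priors and sampler details).

The package is aimed at quantitative ecologists running multispecies
point-count programs: it simulates DDO data with known truth, fits the
model, checks convergence (split-chain R-hat, trace plots), and measures
operating characteristics (credible-interval coverage, mean absolute
percent error) over repeated simulations.

## Worked example

```python
import ddonmix as dx

# 4 species on 20 plots, 3 visits; p1 = 0.3, p2 = 0.5; known truth
data, truth = dx.simulate_basic(dx.SimConfig(seed=42))

samples = dx.fit(
    data,
    dx.ModelSpec(variant="basic"),
    dx.Priors(),
    dx.MCMCConfig(n_chains=3, n_iter=6000, n_burn=1000, seed=7),
)
print(dx.summarize(samples, params=samples.param_names(monitored_only=True)).round(3))
print("truth:", truth.lambda_species.round(2), (truth.p_primary, truth.p_secondary))
```

```
                mean     sd    q2.5   q97.5   rhat
parameter
lambda[sp1]   17.162  1.646  14.438  20.847  1.006
lambda[sp2]    6.727  0.800   5.339   8.489  1.007
lambda[sp3]   21.316  1.911  18.078  25.663  1.010
lambda[sp4]   14.228  1.380  11.814  17.294  1.008
p[primary]     0.282  0.021   0.238   0.321  1.009
p[secondary]   0.451  0.045   0.358   0.532  1.010
truth: [16.27  6.56 20.46 13.22] (0.3, 0.5)
```

Each `lambda[sp*]` row is the posterior for that species' mean abundance
per plot with its equal-tailed 95% credible interval — all four contain
the generating values, as do the two detection probabilities — and
`rhat` is the split-chain potential scale reduction factor (values near
1 indicate the three chains agree).

The same pipeline is available from a shell:

```
ddonmix simulate --preset basic --seed 1 --out sim/
ddonmix fit --data sim/counts.csv --iters 6000 --burn 1000 --out fit/
ddonmix diagnose --draws fit/draws.csv --out diag/
ddonmix study --reps 25 --iters 6000 --burn 1000 --out study/
ddonmix fixtures --observations observations.csv
```

`study` writes the coverage/MAPE report tables; `fixtures` exports the
packaged two-year songbird case-study observation summary (whose
column totals are checked exactly in the test suite).

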