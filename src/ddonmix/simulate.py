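"""Synthetic dependent double-observer survey data with known truth.

The default configuration reproduces the canonical evaluation design:
four hypothetical species randomly (Poisson) distributed across 20 plots,
three replicate visits in a single closed season, primary-observer
detection 0.3 and secondary-observer detection 0.5. A covariate generator
emulates the two-year, 80-plot public/private study layout used to
exercise the covariate model variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DDOCounts

__all__ = ["SimConfig", "SimulationTruth", "simulate_basic", "simulate_covariate", "empirical_outcome_freqs"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic DDO survey.

    lambda_truth:
        Per-species mean abundances. When None, each species' log mean is
        drawn uniformly on [log(lambda_low), log(lambda_high)], spanning
        rare (~2 per plot) to common (~30 per plot).
    ownership / beta*_truth / sigma_plot_truth / observer pool:
        Only used by :func:`simulate_covariate`.
    """

    n_species: int = 4
    n_plots: int = 20
    n_replicates: int = 3
    n_years: int = 1
    p_primary: float = 0.3
    p_secondary: float = 0.5
    lambda_truth: tuple | None = None
    lambda_low: float = 2.0
    lambda_high: float = 30.0
    seed: int = 0
    # covariate-variant settings
    ownership: tuple | None = None  # default: first half public, second half private
    beta0_truth: tuple | None = None
    beta1_truth: tuple | None = None
    beta2_truth: tuple | None = None
    sigma_plot_truth: float = 0.3
    n_observers: int = 2
    observer_p_truth: tuple | None = None
    observer_p_logit_mean: float = -0.4  # ~0.4 on the probability scale
    observer_p_logit_sd: float = 0.8

    def __post_init__(self):
        if min(self.n_species, self.n_plots, self.n_replicates, self.n_years) < 1:
            raise ValueError("all design dimensions must be >= 1")
        for p in (self.p_primary, self.p_secondary):
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must lie in [0, 1]")
        if self.lambda_truth is not None and len(self.lambda_truth) != self.n_species:
            raise ValueError("lambda_truth must give one mean per species")


@dataclass
class SimulationTruth:
    """Generating parameter values attached to a simulated dataset."""

    N: np.ndarray                       # (S, J, Y)
    lam: np.ndarray                     # (S, J, Y) mean abundance field
    lambda_species: np.ndarray | None   # (S,) species means (basic variant)
    p_primary: float | None = None
    p_secondary: float | None = None
    observer_p: np.ndarray | None = None   # per-identity detection (covariate pool)
    beta0: np.ndarray | None = None
    beta1: np.ndarray | None = None
    beta2: np.ndarray | None = None
    alpha: np.ndarray | None = None
    sigma_plot: float | None = None


def _species_lambda(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.lambda_truth is not None:
        lam = np.asarray(cfg.lambda_truth, dtype=float)
        if (lam <= 0).any():
            raise ValueError("lambda_truth must be positive")
        return lam
    return np.exp(rng.uniform(np.log(cfg.lambda_low), np.log(cfg.lambda_high), size=cfg.n_species))


def _observe(N: np.ndarray, p1, p2, K: int, rng: np.random.Generator):
    """Apply the DDO observation process to latent N for K replicates.

    The two-stage mechanism is the multinomial in sequential form: the
    primary detects each of the N individuals with probability p1; the
    secondary detects each primary miss with probability p2.
    p1/p2 may be scalars or arrays broadcastable to N's shape per replicate.
    """
    y1 = np.empty(N.shape + (K,), dtype=np.int64)
    y2 = np.empty_like(y1)
    for k in range(K):
        p1k = p1[..., k] if np.ndim(p1) > 0 else p1
        p2k = p2[..., k] if np.ndim(p2) > 0 else p2
        y1[..., k] = rng.binomial(N, p1k)
        y2[..., k] = rng.binomial(N - y1[..., k], p2k)
    return y1, y2


def simulate_basic(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate one dataset under the basic (single-season) design.

    Latent abundance N[i, j] ~ Poisson(lambda_i) is shared by all replicate
    visits of a plot (closed population); each replicate's counts follow the
    three-outcome DDO process with the configured detection probabilities.

    Returns ``(DDOCounts, SimulationTruth)``. With the same seed the output
    is identical call to call.
    """
    if cfg.n_years != 1:
        raise ValueError("the basic design is single-season; use simulate_covariate for multi-year data")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    S, J, K = cfg.n_species, cfg.n_plots, cfg.n_replicates
    lam_sp = _species_lambda(cfg, rng)
    lam = np.broadcast_to(lam_sp[:, None, None], (S, J, 1)).copy()
    N = rng.poisson(lam)
    y1, y2 = _observe(N, cfg.p_primary, cfg.p_secondary, K, rng)

    data = DDOCounts(
        species=[f"sp{i + 1}" for i in range(S)],
        plots=[f"plot{j + 1:02d}" for j in range(J)],
        years=[1],
        observers=["obs1", "obs2"],
        y1=y1,
        y2=y2,
        obs_primary=np.zeros((J, 1, K), dtype=np.int64),
        obs_secondary=np.ones((J, 1, K), dtype=np.int64),
    )
    truth = SimulationTruth(
        N=N, lam=lam, lambda_species=lam_sp,
        p_primary=cfg.p_primary, p_secondary=cfg.p_secondary,
    )
    return data, truth


def simulate_covariate(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate a multi-year dataset under the covariate model variant.

    log lambda[i, j, y] = beta0_i + beta1_i * ownership_j + beta2_i * year_y
    + alpha_j, with alpha_j ~ Normal(0, sigma_plot^2). Observer pairs for
    each survey visit are drawn from a pool of ``n_observers`` identities;
    each identity has its own detection probability, used in whichever role
    it is assigned.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    S, J, Y, K = cfg.n_species, cfg.n_plots, cfg.n_years, cfg.n_replicates

    if cfg.ownership is None:
        ownership = np.zeros(J, dtype=np.int64)
        ownership[J // 2:] = 1
    else:
        ownership = np.asarray(cfg.ownership, dtype=np.int64)
        if ownership.shape != (J,):
            raise ValueError("ownership must give one 0/1 code per plot")

    def _coef(values, default_draw):
        if values is None:
            return default_draw()
        arr = np.asarray(values, dtype=float)
        if arr.shape != (S,):
            raise ValueError("coefficient truth must give one value per species")
        return arr

    beta0 = _coef(cfg.beta0_truth, lambda: rng.uniform(np.log(2.0), np.log(20.0), size=S))
    beta1 = _coef(cfg.beta1_truth, lambda: rng.normal(0.0, 0.5, size=S))
    beta2 = _coef(cfg.beta2_truth, lambda: rng.normal(0.0, 0.3, size=S))
    sigma = float(cfg.sigma_plot_truth)
    if sigma < 0:
        raise ValueError("sigma_plot_truth must be nonnegative")
    alpha = rng.normal(0.0, sigma, size=J) if sigma > 0 else np.zeros(J)

    year_codes = np.arange(Y, dtype=np.int64)
    loglam = (
        beta0[:, None, None]
        + beta1[:, None, None] * ownership[None, :, None]
        + beta2[:, None, None] * year_codes[None, None, :]
        + alpha[None, :, None]
    )
    lam = np.exp(loglam)
    N = rng.poisson(lam)

    n_obs = int(cfg.n_observers)
    if n_obs < 2:
        raise ValueError("the DDO protocol needs at least two observers")
    if cfg.observer_p_truth is not None:
        obs_p_truth = np.asarray(cfg.observer_p_truth, dtype=float)
        if obs_p_truth.shape != (n_obs,):
            raise ValueError("observer_p_truth must give one probability per observer")
    elif n_obs == 2:
        obs_p_truth = np.array([cfg.p_primary, cfg.p_secondary])
    else:
        obs_p_truth = 1.0 / (1.0 + np.exp(-rng.normal(cfg.observer_p_logit_mean, cfg.observer_p_logit_sd, size=n_obs)))

    # observer pair per survey visit; a fixed roster of two keeps fixed roles
    if n_obs == 2 and cfg.observer_p_truth is None:
        obs_primary = np.zeros((J, Y, K), dtype=np.int64)
        obs_secondary = np.ones((J, Y, K), dtype=np.int64)
    else:
        obs_primary = np.empty((J, Y, K), dtype=np.int64)
        obs_secondary = np.empty((J, Y, K), dtype=np.int64)
        for j in range(J):
            for t in range(Y):
                for k in range(K):
                    pair = rng.choice(n_obs, size=2, replace=False)
                    obs_primary[j, t, k], obs_secondary[j, t, k] = pair

    p1 = obs_p_truth[obs_primary][None, :, :, :]      # (1, J, Y, K)
    p2 = obs_p_truth[obs_secondary][None, :, :, :]
    y1, y2 = _observe(
        N,
        np.broadcast_to(p1, (S, J, Y, K)),
        np.broadcast_to(p2, (S, J, Y, K)),
        K,
        rng,
    )

    data = DDOCounts(
        species=[f"sp{i + 1}" for i in range(S)],
        plots=[f"plot{j + 1:02d}" for j in range(J)],
        years=list(range(1, Y + 1)),
        observers=[f"obs{m + 1}" for m in range(n_obs)],
        y1=y1,
        y2=y2,
        obs_primary=obs_primary,
        obs_secondary=obs_secondary,
        ownership=ownership,
    )
    truth = SimulationTruth(
        N=N, lam=lam, lambda_species=None,
        observer_p=obs_p_truth,
        beta0=beta0, beta1=beta1, beta2=beta2,
        alpha=alpha, sigma_plot=sigma,
    )
    return data, truth


def empirical_outcome_freqs(data: DDOCounts, truth: SimulationTruth) -> np.ndarray:
    """Pooled empirical frequencies of the three DDO outcomes.

    Each of the N latent individuals is exposed once per replicate visit,
    so the denominator is the latent abundance summed over all
    site-replicates. Returns ``[f1, f2, f3]`` summing to one (all-zero
    datasets return the degenerate [0, 0, 1]).
    """
    exposures = float(truth.N.sum()) * data.n_replicates
    if exposures == 0:
        return np.array([0.0, 0.0, 1.0])
    c1 = float(data.y1.sum())
    c2 = float(data.y2.sum())
    return np.array([c1 / exposures, c2 / exposures, 1.0 - (c1 + c2) / exposures])
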