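"""Metropolis-within-Gibbs sampler for the DDO N-mixture model.

Update scheme per iteration (order fixed for reproducibility; it does not
affect the stationary distribution):

1. latent abundance N[i, j, y] — drawn exactly from its full conditional
   p(N | y, lambda, pi) ~ Poisson(N; lambda) * prod_k Trinomial(y_k; N, pi_k)
   by enumeration over a finite window [floor, floor + U], where floor is
   the largest detected total across replicates and U is sized so the
   truncated tail mass is negligible (< 1e-10 of the window maximum,
   verified and widened adaptively);
2. detection parameters — random-walk Metropolis on the logit scale. The
   trinomial factorises into a primary-observer binomial (y1 of N) and a
   secondary-observer binomial (y2 of N - y1), so each observer slot has
   scalar sufficient statistics and updates independently;
3. abundance parameters — random-walk Metropolis on log lambda (basic) or
   on the regression blocks beta / alpha / sigma_plot (covariate variant).

Proposal step sizes adapt during burn-in only (multiplicative, targeting
acceptance between 0.2 and 0.5) and are frozen afterwards so the kept
draws come from a fixed, detailed-balance-respecting kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from .datasets import DDOCounts
from .model import (
    AbundanceParams,
    CellProbs,
    CovariateParams,
    DetectionParams,
    ModelSpec,
    ModelState,
    Priors,
    detection_logits,
    detection_prior_logpdf,
    joint_logpost,
    log_lambda_field,
)

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "fit",
    "sample_N_conditional",
    "n_conditional_pmf",
    "update_detection",
    "update_abundance_params",
]

_TAIL_EPS = 1e-10

# growable lookup table of log(n!) for the integer-valued window weights
_LOGFACT = gammaln(np.arange(1024) + 1.0)


def _logfact(n: np.ndarray) -> np.ndarray:
    global _LOGFACT
    hi = int(n.max(initial=0))
    if hi >= _LOGFACT.size:
        _LOGFACT = gammaln(np.arange(2 * hi + 1) + 1.0)
    return _LOGFACT[n]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol settings.

    Defaults follow the full-length protocol (3 chains of 50,000
    iterations, 5,000 discarded as burn-in, no thinning); reduce n_iter /
    n_burn for quick fits. ``init_dispersion`` is the standard deviation
    of the over-dispersed jitter applied to starting values so that the
    convergence diagnostic is meaningful.
    """

    n_chains: int = 3
    n_iter: int = 50_000
    n_burn: int = 5_000
    thin: int = 1
    seed: int = 0
    init_dispersion: float = 1.5
    adapt_interval: int = 50
    store_latent: bool = True

    def __post_init__(self):
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


class PosteriorSamples:
    """Kept MCMC draws, indexed chain x iteration x parameter.

    Draws are stored in parameter groups (``lambda``, ``p``, ``N``, ...);
    :meth:`get` returns the (n_chains, n_draws) matrix for one flat
    parameter name such as ``"lambda[sp1]"`` or ``"N[sp2,plot07]"``.
    Detection draws are on the probability scale, abundance draws on the
    natural (lambda) scale.
    """

    def __init__(self, groups, names, acceptance, spec, config):
        self.groups = groups          # group -> (C, T, n_params_in_group)
        self.names = names            # group -> list of flat names
        self.acceptance = acceptance  # block -> mean acceptance rate per chain
        self.spec = spec
        self.config = config
        self._index = {}
        for g, labels in names.items():
            for pos, label in enumerate(labels):
                self._index[label] = (g, pos)

    @property
    def n_chains(self) -> int:
        g = next(iter(self.groups.values()))
        return g.shape[0]

    @property
    def n_draws(self) -> int:
        g = next(iter(self.groups.values()))
        return g.shape[1]

    def param_names(self, monitored_only: bool = False) -> list:
        out = []
        for g, labels in self.names.items():
            if monitored_only and g == "N":
                continue
            out.extend(labels)
        return out

    def get(self, name: str) -> np.ndarray:
        g, pos = self._index[name]
        return self.groups[g][:, :, pos]

    def to_frame(self):
        """Long data frame: chain, draw, parameter, value."""
        import pandas as pd

        frames = []
        C, T = self.n_chains, self.n_draws
        chain = np.repeat(np.arange(C), T)
        draw = np.tile(np.arange(T), C)
        for g, labels in self.names.items():
            arr = self.groups[g]
            for pos, label in enumerate(labels):
                frames.append(
                    pd.DataFrame(
                        {"chain": chain, "draw": draw, "parameter": label,
                         "value": arr[:, :, pos].ravel()}
                    )
                )
        return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# Exact full-conditional update of the latent abundance


def _n_window_logweights(n_vals, d, loglam, logpi3):
    """Unnormalised log weights of the N full conditional on a window.

    n_vals: (..., W) candidate N values (>= per-site floor);
    d: (..., K) detected totals per replicate;
    loglam: (...,) log mean abundance;
    logpi3: (..., K) log both-miss probability per replicate.
    """
    K = d.shape[-1]
    logw = n_vals * loglam[..., None] + (K - 1) * _logfact(n_vals)
    for k in range(K):
        miss = n_vals - d[..., k, None]
        logw += miss * logpi3[..., k, None] - _logfact(miss)
    return logw


def _window_width(lam, pi3_max, floor):
    """Initial enumeration window width above the floor.

    Sized from an upper Poisson tail bound at rate lam * pi3 (individuals
    missed by both observers in a single replicate); the sampler widens
    adaptively if the realised tail is not negligible.
    """
    rate = float(np.max(lam * np.clip(pi3_max, 0.0, 1.0), initial=0.0))
    if rate <= 0:
        return 8
    return int(rate + 8.0 * np.sqrt(rate)) + 12


def _draw_N_all(floor, d, loglam, logpi3, lam, pi3_max, rng):
    """Vectorised exact draw from the N full conditional for every site."""
    width = _window_width(lam, pi3_max, floor)
    while True:
        m = np.arange(width + 1, dtype=np.int64)
        n_vals = floor[..., None] + m
        logw = _n_window_logweights(n_vals, d, loglam, logpi3)
        logw -= logw.max(axis=-1, keepdims=True)
        w = np.exp(logw)
        if width > 4 and float(w[..., -1].max()) > _TAIL_EPS:
            width *= 2
            continue
        cum = np.cumsum(w, axis=-1)
        tot = cum[..., -1]
        u = rng.random(size=tot.shape)[..., None] * tot[..., None]
        idx = (cum < u).sum(axis=-1)
        return floor + idx


def n_conditional_pmf(y: np.ndarray, lam: float, cp: CellProbs):
    """Enumerated full-conditional pmf of latent N for one site.

    Parameters
    ----------
    y:
        Array of shape (K, 2): per-replicate (y1, y2) counts.
    lam, cp:
        Current mean abundance and cell probabilities (shared across
        replicates).

    Returns
    -------
    (values, probs): candidate N values and their normalised conditional
    probabilities (truncated where the tail is numerically zero).
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.int64))
    if y.shape[1] != 2:
        raise ValueError("y must be (K, 2): per-replicate (y1, y2)")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    d = y.sum(axis=1)
    floor = int(d.max(initial=0))
    K = y.shape[0]
    with np.errstate(divide="ignore"):
        logpi3 = np.full(K, np.log(cp.pi3) if cp.pi3 > 0 else -745.0)
    width = _window_width(np.array(lam), np.array(cp.pi3), floor)
    while True:
        n_vals = floor + np.arange(width + 1, dtype=np.int64)
        logw = _n_window_logweights(
            n_vals[None, :], d[None, :], np.log(np.array([lam])), logpi3[None, :]
        )[0]
        logw -= logw.max()
        w = np.exp(logw)
        if width > 4 and w[-1] > _TAIL_EPS:
            width *= 2
            continue
        return n_vals, w / w.sum()


def sample_N_conditional(y: np.ndarray, lam: float, cp: CellProbs, rng: np.random.Generator):
    """Draw one latent abundance from its exact full conditional.

    ``y`` is (K, 2) as in :func:`n_conditional_pmf`. The draw respects the
    floor max_k(y1 + y2) by construction.
    """
    vals, probs = n_conditional_pmf(y, lam, cp)
    u = rng.random()
    return int(vals[np.searchsorted(np.cumsum(probs), u * probs.sum())])


# ----------------------------------------------------------------------
# Sampler engine


def _binom_loglik(eta, A, B):
    """A * log(expit(eta)) + B * log(1 - expit(eta)), numerically stable."""
    # log expit(eta) = -log1p(exp(-eta)); log(1-expit(eta)) = -eta - log1p(exp(-eta))
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -eta + log_p
    return A * log_p + B * log_q


class _Sampler:
    """Holds data-derived constants, step sizes and update routines."""

    def __init__(self, data: DDOCounts, spec: ModelSpec, priors: Priors, init_steps=None):
        self.data = data
        self.spec = spec
        self.priors = priors
        S, J, Y, K = data.shape
        self.K = K
        self.floor = data.n_floor
        self.d = data.detected
        self.y1_total = float(data.y1.sum())
        self.y2_total = float(data.y2.sum())
        # species-summed counts per survey (detection stats never mix species
        # unless species effects are on, handled separately)
        self.y1_sp = data.y1.sum(axis=0)  # (J, Y, K)
        self.y2_sp = data.y2.sum(axis=0)
        self.n_obs = len(data.observers)
        self.n_det = 2 if spec.detection_structure == "by_role" else self.n_obs
        self.steps = {
            "eta_obs": np.full(self.n_det, 0.15),
            "eta_species": np.full(S, 0.15),
            "log_lambda": np.full(S, 0.15),
            "beta": np.full(S, 0.1),
            "alpha": np.full(J, 0.25),
            "sigma_plot": np.array([0.4]),
            "ridge": np.array([0.15]),
        }
        if init_steps:
            self.steps.update({k: np.asarray(v, dtype=float) for k, v in init_steps.items()})
        # fixed direction of the joint ridge move: d eta = -coef * d loglam;
        # coef = 1/(1-p) would hold lambda*p constant, 5/3 matches p ~ 0.4
        self._ridge_coef = np.full(self.n_det, 5.0 / 3.0)
        self.n_ridge_moves = 3
        self.accept_counts = {k: np.zeros_like(v) for k, v in self.steps.items()}
        self.try_counts = {k: np.zeros_like(v) for k, v in self.steps.items()}
        self.accept_kept = {k: 0.0 for k in self.steps}
        self.kept_iters = 0

    # -- bookkeeping ---------------------------------------------------
    def _tally(self, block, accepted, tries=None):
        acc = np.asarray(accepted, dtype=float)
        self.accept_counts[block] += acc
        self.try_counts[block] += 1.0 if tries is None else np.asarray(tries, dtype=float)

    def adapt(self):
        """One burn-in adaptation round; call every adapt_interval iters."""
        for block, step in self.steps.items():
            tries = self.try_counts[block]
            mask = tries > 0
            if not mask.any():
                continue
            rate = np.where(mask, self.accept_counts[block] / np.maximum(tries, 1.0), 0.35)
            factor = np.clip(np.exp(1.5 * (rate - 0.35)), 0.5, 2.5)
            step[mask] = np.clip(step[mask] * factor[mask], 1e-4, 1e4)
            self.accept_counts[block][:] = 0.0
            self.try_counts[block][:] = 0.0

    def reset_counters(self):
        for block in self.steps:
            self.accept_counts[block][:] = 0.0
            self.try_counts[block][:] = 0.0

    def acceptance_rates(self):
        out = {}
        for block, tries in self.try_counts.items():
            tot = float(tries.sum())
            out[block] = float(self.accept_counts[block].sum()) / tot if tot > 0 else np.nan
        return out

    # -- N update ------------------------------------------------------
    def update_N(self, state: ModelState, rng: np.random.Generator):
        if self.data.is_empty or self.K == 0:
            return
        loglam = log_lambda_field(state, self.data, self.spec)
        eta_p, eta_s = detection_logits(state, self.data, self.spec)
        # log pi3 = log(1-p1) + log(1-p2) = -eta - log1p(exp(-eta)) summed
        logpi3 = (-np.logaddexp(0.0, eta_p)) + (-np.logaddexp(0.0, eta_s))
        S, J, Y, K = self.data.shape
        logpi3 = np.broadcast_to(logpi3, (S, J, Y, K))
        pi3_max = np.exp(logpi3.max())
        lam = np.exp(loglam)
        state.N = _draw_N_all(self.floor, self.d, loglam, logpi3, lam, pi3_max, rng)

    # -- detection update ----------------------------------------------
    def _role_stats(self, N):
        """Successes/failures for the two role slots (by_role structure)."""
        n_site_total = float(N.sum()) * self.K
        A_p = self.y1_total
        B_p = n_site_total - self.y1_total
        A_s = self.y2_total
        B_s = n_site_total - self.y1_total - self.y2_total
        return np.array([A_p, A_s]), np.array([B_p, B_s])

    def _observer_stats(self, N):
        """Successes/failures per observer identity (by_observer)."""
        Nrep = np.broadcast_to(N.sum(axis=0)[..., None], self.y1_sp.shape)  # (J,Y,K)
        op = self.data.obs_primary.ravel()
        os_ = self.data.obs_secondary.ravel()
        A = np.bincount(op, weights=self.y1_sp.ravel(), minlength=self.n_obs)
        A += np.bincount(os_, weights=self.y2_sp.ravel(), minlength=self.n_obs)
        B = np.bincount(op, weights=(Nrep - self.y1_sp).ravel(), minlength=self.n_obs)
        B += np.bincount(
            os_, weights=(Nrep - self.y1_sp - self.y2_sp).ravel(), minlength=self.n_obs
        )
        return A, B

    def _observer_species_stats(self, N):
        """Successes/failures per (observer, species) cell."""
        S = self.data.n_species
        A = np.zeros((self.n_obs, S))
        B = np.zeros((self.n_obs, S))
        op = self.data.obs_primary.ravel()
        os_ = self.data.obs_secondary.ravel()
        for i in range(S):
            y1 = self.data.y1[i].ravel()
            y2 = self.data.y2[i].ravel()
            Ni = np.broadcast_to(N[i][..., None], self.data.y1[i].shape).ravel()
            A[:, i] = np.bincount(op, weights=y1, minlength=self.n_obs)
            A[:, i] += np.bincount(os_, weights=y2, minlength=self.n_obs)
            B[:, i] = np.bincount(op, weights=Ni - y1, minlength=self.n_obs)
            B[:, i] += np.bincount(os_, weights=Ni - y1 - y2, minlength=self.n_obs)
        return A, B

    def update_detection(self, state: ModelState, rng: np.random.Generator):
        det = state.detection
        var = self.priors.detection_prior_var
        structure = self.spec.detection_structure
        empty = self.data.is_empty or self.K == 0

        if structure == "by_observer_and_species" and not empty:
            A, B = self._observer_species_stats(state.N)  # (n_obs, S)
        elif structure == "by_observer" and not empty:
            A, B = self._observer_stats(state.N)
        elif not empty:
            A, B = self._role_stats(state.N)
        else:
            A = B = None

        eta = det.eta_obs
        prop = eta + self.steps["eta_obs"] * rng.standard_normal(eta.shape)
        if A is None:
            loglik_cur = np.zeros_like(eta)
            loglik_prop = np.zeros_like(eta)
        elif structure == "by_observer_and_species":
            e_sp = det.eta_species[None, :]
            loglik_cur = _binom_loglik(eta[:, None] + e_sp, A, B).sum(axis=1)
            loglik_prop = _binom_loglik(prop[:, None] + e_sp, A, B).sum(axis=1)
        else:
            loglik_cur = _binom_loglik(eta, A, B)
            loglik_prop = _binom_loglik(prop, A, B)
        logr = (loglik_prop - loglik_cur) + (
            detection_prior_logpdf(prop, self.priors) - detection_prior_logpdf(eta, self.priors)
        )
        accept = np.log(rng.random(eta.shape)) < logr
        eta[accept] = prop[accept]
        self._tally("eta_obs", accept)

        if structure == "by_observer_and_species":
            self._update_species_effects(det, A, B, rng)

    def _update_species_effects(self, det, A, B, rng):
        """Sum-to-zero species detection offsets; last effect = -sum(rest)."""
        S = det.eta_species.shape[0]
        var = self.priors.detection_prior_var
        for i in range(S - 1):
            cur = det.eta_species.copy()
            prop = cur.copy()
            delta = self.steps["eta_species"][i] * rng.standard_normal()
            prop[i] += delta
            prop[-1] -= delta
            cols = [i, S - 1]
            if A is None:
                ll_cur = ll_prop = 0.0
            else:
                eta_obs = det.eta_obs[:, None]
                ll_cur = float(_binom_loglik(eta_obs + cur[cols][None, :], A[:, cols], B[:, cols]).sum())
                ll_prop = float(_binom_loglik(eta_obs + prop[cols][None, :], A[:, cols], B[:, cols]).sum())
            logr = (ll_prop - ll_cur) - 0.5 * float(np.sum(prop[cols] ** 2) - np.sum(cur[cols] ** 2)) / var
            acc = np.log(rng.random()) < logr
            if acc:
                det.eta_species = prop
            arr = np.zeros(S)
            arr[i] = float(acc)
            tries = np.zeros(S)
            tries[i] = 1.0
            self._tally("eta_species", arr, tries)

    # -- abundance update ----------------------------------------------
    def update_abundance(self, state: ModelState, rng: np.random.Generator):
        if self.spec.variant == "basic":
            self._update_log_lambda(state, rng)
        else:
            self._update_betas(state, rng)
            self._update_alpha(state, rng)
            self._update_sigma(state, rng)

    def _update_log_lambda(self, state, rng):
        ab = state.abundance
        var = self.priors.abundance_prior_var
        n_cells = self.data.n_plots * self.data.n_years
        N_i = state.N.sum(axis=(1, 2)) if not self.data.is_empty else np.zeros_like(ab.log_lambda)
        cur = ab.log_lambda
        prop = cur + self.steps["log_lambda"] * rng.standard_normal(cur.shape)
        # Poisson likelihood in log lambda: N_i * loglam - n_cells * exp(loglam)
        ll_cur = N_i * cur - n_cells * np.exp(cur)
        ll_prop = N_i * prop - n_cells * np.exp(prop)
        logr = (ll_prop - ll_cur) - 0.5 * (prop**2 - cur**2) / var
        accept = np.log(rng.random(cur.shape)) < logr
        cur[accept] = prop[accept]
        self._tally("log_lambda", accept)

    def _poisson_ll_by_species(self, state, beta0, beta1, beta2):
        data = self.data
        own = data.ownership[None, :, None]
        yr = data.year_codes[None, None, :]
        loglam = (
            beta0[:, None, None] + beta1[:, None, None] * own
            + beta2[:, None, None] * yr + state.abundance.alpha[None, :, None]
        )
        return (state.N * loglam - np.exp(loglam)).sum(axis=(1, 2))

    def _update_betas(self, state, rng):
        ab = state.abundance
        var = self.priors.abundance_prior_var
        step = self.steps["beta"]
        cur = (ab.beta0, ab.beta1, ab.beta2)
        prop = tuple(b + step * rng.standard_normal(b.shape) for b in cur)
        if self.data.is_empty:
            ll_cur = ll_prop = np.zeros_like(ab.beta0)
        else:
            ll_cur = self._poisson_ll_by_species(state, *cur)
            ll_prop = self._poisson_ll_by_species(state, *prop)
        pen_cur = sum(b**2 for b in cur)
        pen_prop = sum(b**2 for b in prop)
        logr = (ll_prop - ll_cur) - 0.5 * (pen_prop - pen_cur) / var
        accept = np.log(rng.random(ab.beta0.shape)) < logr
        for b, p in zip(cur, prop):
            b[accept] = p[accept]
        self._tally("beta", accept)

    def _update_alpha(self, state, rng):
        ab = state.abundance
        if ab.alpha.size == 0:
            return
        sig = max(float(ab.sigma_plot), 1e-12)
        cur = ab.alpha
        prop = cur + self.steps["alpha"] * rng.standard_normal(cur.shape)
        if self.data.is_empty:
            ll_cur = ll_prop = np.zeros_like(cur)
        else:
            data = self.data
            own = data.ownership[None, :, None]
            yr = data.year_codes[None, None, :]
            base = (
                ab.beta0[:, None, None] + ab.beta1[:, None, None] * own
                + ab.beta2[:, None, None] * yr
            )
            ll_cur = (state.N * (base + cur[None, :, None])
                      - np.exp(base + cur[None, :, None])).sum(axis=(0, 2))
            ll_prop = (state.N * (base + prop[None, :, None])
                       - np.exp(base + prop[None, :, None])).sum(axis=(0, 2))
        logr = (ll_prop - ll_cur) - 0.5 * (prop**2 - cur**2) / (sig * sig)
        accept = np.log(rng.random(cur.shape)) < logr
        cur[accept] = prop[accept]
        self._tally("alpha", accept)

    def _update_sigma(self, state, rng):
        ab = state.abundance
        if ab.alpha.size == 0:
            # no plot effects: sigma has no likelihood term, sample its prior
            prop = float(ab.sigma_plot + self.steps["sigma_plot"][0] * rng.standard_normal())
            acc = 0.0 <= prop <= self.priors.sigma_plot_upper and np.log(rng.random()) < 0.0
            if acc:
                ab.sigma_plot = prop
            self._tally("sigma_plot", np.array([float(acc)]))
            return
        cur = float(ab.sigma_plot)
        prop = cur + float(self.steps["sigma_plot"][0] * rng.standard_normal())
        if not (0.0 < prop <= self.priors.sigma_plot_upper):
            self._tally("sigma_plot", np.array([0.0]))
            return
        J = ab.alpha.size
        ss = float(np.sum(ab.alpha**2))
        ll_cur = -J * np.log(max(cur, 1e-300)) - 0.5 * ss / max(cur, 1e-300) ** 2
        ll_prop = -J * np.log(prop) - 0.5 * ss / prop**2
        acc = np.log(rng.random()) < (ll_prop - ll_cur)
        if acc:
            ab.sigma_plot = prop
        self._tally("sigma_plot", np.array([float(acc)]))

    def update_ridge(self, state: ModelState, rng: np.random.Generator):
        """Joint translation along the abundance-detection ridge.

        The posterior of N-mixture models is strongly correlated along
        "more individuals, all detected less often": the data pin the
        products lambda * pi1 and lambda * pi2 much more tightly than the
        factors. Componentwise random walks cross this ridge slowly, so an
        extra symmetric Metropolis move translates all log means by delta
        while lowering both logit detections (coefficients 1/(1 - p) at
        the design detection values, which keeps lambda * pi roughly
        constant). The move targets the same posterior exactly; it only
        shortens autocorrelation along the ridge.
        """
        delta = float(self.steps["ridge"][0] * rng.standard_normal())
        det = state.detection
        eta_new = det.eta_obs - delta * self._ridge_coef
        ab = state.abundance
        var_a = self.priors.abundance_prior_var

        if self.spec.variant == "basic":
            loglam_cur = ab.log_lambda
        else:
            loglam_cur = ab.beta0
        loglam_new = loglam_cur + delta

        logr = float(
            np.sum(detection_prior_logpdf(eta_new, self.priors)
                   - detection_prior_logpdf(det.eta_obs, self.priors))
        ) - 0.5 * float(np.sum(loglam_new**2 - loglam_cur**2)) / var_a
        if not self.data.is_empty and self.K > 0:
            # Poisson factor: sum_i N_i * dloglam - n_cells * (exp(new) - exp(cur))
            if self.spec.variant == "basic":
                N_i = state.N.sum(axis=(1, 2))
                n_cells = self.data.n_plots * self.data.n_years
                logr += float(np.sum(state.N) * delta
                              - n_cells * np.sum(np.exp(loglam_new) - np.exp(loglam_cur)))
            else:
                field_cur = log_lambda_field(state, self.data, self.spec)
                logr += float(np.sum(state.N) * delta
                              - np.sum(np.exp(field_cur + delta) - np.exp(field_cur)))
            # detection factor via per-slot binomial sufficient statistics
            structure = self.spec.detection_structure
            if structure == "by_role":
                A, B = self._role_stats(state.N)
            elif structure == "by_observer":
                A, B = self._observer_stats(state.N)
            else:
                A, B = self._observer_species_stats(state.N)
            if structure == "by_observer_and_species":
                e_sp = det.eta_species[None, :]
                logr += float(_binom_loglik(eta_new[:, None] + e_sp, A, B).sum()
                              - _binom_loglik(det.eta_obs[:, None] + e_sp, A, B).sum())
            else:
                logr += float(_binom_loglik(eta_new, A, B).sum()
                              - _binom_loglik(det.eta_obs, A, B).sum())
        acc = np.log(rng.random()) < logr
        if acc:
            det.eta_obs = eta_new
            if self.spec.variant == "basic":
                ab.log_lambda = loglam_new
            else:
                ab.beta0 = loglam_new
        self._tally("ridge", np.array([float(acc)]))

    def sweep(self, state: ModelState, rng: np.random.Generator):
        self.update_N(state, rng)
        self.update_detection(state, rng)
        self.update_abundance(state, rng)
        for _ in range(self.n_ridge_moves):
            self.update_ridge(state, rng)


# ----------------------------------------------------------------------
# Public single-update wrappers (thin, for direct use and testing)


def update_detection(state: ModelState, data: DDOCounts, spec: ModelSpec,
                     priors: Priors, rng: np.random.Generator) -> DetectionParams:
    """One Metropolis update of the detection block; returns the new params."""
    _Sampler(data, spec, priors).update_detection(state, rng)
    return state.detection


def update_abundance_params(state: ModelState, data: DDOCounts, spec: ModelSpec,
                            priors: Priors, rng: np.random.Generator):
    """One Metropolis update of the abundance block; returns the new params."""
    _Sampler(data, spec, priors).update_abundance(state, rng)
    return state.abundance


# ----------------------------------------------------------------------
# Initialisation


def _initial_state(data: DDOCounts, spec: ModelSpec, disp: float,
                   rng: np.random.Generator) -> ModelState:
    S, J, Y, K = data.shape
    floor = data.n_floor

    # crude per-species abundance scale from the detected totals; the
    # jitter keeps chains over-dispersed relative to the posterior
    if data.is_empty or K == 0:
        crude = np.ones(S)
    else:
        crude = np.maximum(floor.mean(axis=(1, 2)), 0.5)

    n_det = 2 if spec.detection_structure == "by_role" else len(data.observers)
    eta_obs = rng.normal(0.0, disp, size=n_det)
    eta_species = None
    if spec.detection_structure == "by_observer_and_species":
        eta_species = rng.normal(0.0, 0.5 * disp, size=S)
        eta_species -= eta_species.mean()
    detection = DetectionParams(eta_obs=eta_obs, eta_species=eta_species)

    if spec.variant == "basic":
        abundance = AbundanceParams(
            log_lambda=np.log(crude) + rng.normal(0.0, disp, size=S)
        )
    else:
        abundance = CovariateParams(
            beta0=np.log(crude) + rng.normal(0.0, disp, size=S),
            beta1=rng.normal(0.0, 0.5 * disp, size=S),
            beta2=rng.normal(0.0, 0.5 * disp, size=S),
            alpha=rng.normal(0.0, 0.1, size=J),
            sigma_plot=float(np.abs(rng.normal(0.5, 0.3))) + 0.05,
        )
    N = floor + rng.poisson(2.0, size=floor.shape)
    return ModelState(N=N, detection=detection, abundance=abundance)


# ----------------------------------------------------------------------
# Recording


def _param_layout(data: DDOCounts, spec: ModelSpec, config: MCMCConfig):
    """Group -> (size, labels) for the stored draws."""
    S, J, Y, K = data.shape
    layout = {}
    if spec.variant == "basic":
        layout["lambda"] = [f"lambda[{s}]" for s in data.species]
    else:
        layout["beta0"] = [f"beta0[{s}]" for s in data.species]
        layout["beta1"] = [f"beta1[{s}]" for s in data.species]
        layout["beta2"] = [f"beta2[{s}]" for s in data.species]
        layout["alpha"] = [f"alpha[{p}]" for p in data.plots]
        layout["sigma_plot"] = ["sigma_plot"]
        layout["lambda"] = [
            f"lambda[{s},{p},{y}]"
            for s in data.species for p in data.plots for y in data.years
        ]
    if spec.detection_structure == "by_role":
        layout["p"] = ["p[primary]", "p[secondary]"]
    else:
        layout["p"] = [f"p[{o}]" for o in data.observers]
        if spec.detection_structure == "by_observer_and_species":
            layout["eta_species"] = [f"eta_species[{s}]" for s in data.species]
    if config.store_latent and not data.is_empty:
        if Y == 1:
            layout["N"] = [f"N[{s},{p}]" for s in data.species for p in data.plots]
        else:
            layout["N"] = [
                f"N[{s},{p},{y}]"
                for s in data.species for p in data.plots for y in data.years
            ]
    return layout


def _record(state: ModelState, data, spec, config, groups, c, t):
    if spec.variant == "basic":
        groups["lambda"][c, t] = np.exp(state.abundance.log_lambda)
    else:
        ab = state.abundance
        groups["beta0"][c, t] = ab.beta0
        groups["beta1"][c, t] = ab.beta1
        groups["beta2"][c, t] = ab.beta2
        groups["alpha"][c, t] = ab.alpha
        groups["sigma_plot"][c, t] = ab.sigma_plot
        groups["lambda"][c, t] = np.exp(
            log_lambda_field(state, data, spec)
        ).ravel()
    groups["p"][c, t] = expit(state.detection.eta_obs)
    if "eta_species" in groups:
        groups["eta_species"][c, t] = state.detection.eta_species
    if "N" in groups:
        groups["N"][c, t] = state.N.ravel()


# ----------------------------------------------------------------------


def fit(data: DDOCounts, spec: ModelSpec | None = None, priors: Priors | None = None,
        config: MCMCConfig | None = None) -> PosteriorSamples:
    """Fit the DDO N-mixture model by Metropolis-within-Gibbs MCMC.

    Runs ``config.n_chains`` chains from over-dispersed starting values,
    discards ``config.n_burn`` iterations of each, and returns the kept
    draws (thinned by ``config.thin``). Deterministic given
    ``config.seed``. A dataset with zero plots yields prior-only draws.
    """
    spec = spec or ModelSpec()
    priors = priors or Priors()
    config = config or MCMCConfig()
    if spec.variant == "covariate" and not data.is_empty and data.ownership is None:
        raise ValueError("covariate variant requires plot ownership metadata")

    n_kept = (config.n_iter - config.n_burn + config.thin - 1) // config.thin
    layout = _param_layout(data, spec, config)
    groups = {
        g: np.empty((config.n_chains, n_kept, len(labels)))
        for g, labels in layout.items()
    }

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)
    acceptance = {}

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        sampler = _Sampler(data, spec, priors)
        state = None
        disp = config.init_dispersion
        for _ in range(6):
            state = _initial_state(data, spec, disp, rng)
            if np.isfinite(joint_logpost(state, data, spec, priors)):
                break
            disp *= 0.5
        else:
            raise RuntimeError("could not find a finite-density starting state")

        t = 0
        for it in range(config.n_iter):
            sampler.sweep(state, rng)
            if it < config.n_burn:
                if (it + 1) % config.adapt_interval == 0:
                    sampler.adapt()
                if it + 1 == config.n_burn:
                    sampler.reset_counters()
            else:
                if (it - config.n_burn) % config.thin == 0:
                    _record(state, data, spec, config, groups, c, t)
                    t += 1
        rates = sampler.acceptance_rates()
        for block, rate in rates.items():
            acceptance.setdefault(block, []).append(rate)

    acceptance = {k: np.asarray(v) for k, v in acceptance.items()}
    return PosteriorSamples(groups, layout, acceptance, spec, config)
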