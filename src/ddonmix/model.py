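"""Probability structure of the multispecies DDO N-mixture abundance model.

The model has two hierarchical layers:

* biological process — latent abundance of species i at plot j (and year y)
  is Poisson, ``N ~ Poisson(lambda)``, with the log mean either a
  species-level effect (basic variant) or a linear predictor in land
  ownership, year and a plot random effect (covariate variant);
* observation process — on each replicate visit, every one of the N
  individuals falls into one of three dependent double-observer outcomes
  (primary detects; secondary detects what primary missed; both miss), so
  the observed pair of counts is trinomial in N with cell probabilities
  driven by the two observers' detection probabilities.

This module defines the parameter containers, the cell-probability map,
the likelihood factors and the joint log posterior. It is consumed by the
sampler and the simulator and performs no sampling itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "CellProbs",
    "DetectionParams",
    "AbundanceParams",
    "CovariateParams",
    "Priors",
    "ModelSpec",
    "ModelState",
    "ddo_cell_probs",
    "multinomial_loglik",
    "marginal_loglik_single_replicate",
    "joint_logpost",
]

_LOG_TINY = -745.0  # stand-in for log(0) that keeps 0 * log(0) = 0 finite


@dataclass(frozen=True)
class CellProbs:
    """The three DDO outcome probabilities (a point on the 2-simplex).

    pi1: primary observer detects an individual;
    pi2: secondary observer detects an individual the primary missed;
    pi3: both observers miss it.
    Components may be scalars or broadcasting arrays.
    """

    pi1: np.ndarray | float
    pi2: np.ndarray | float
    pi3: np.ndarray | float

    def as_tuple(self):
        return (self.pi1, self.pi2, self.pi3)


def ddo_cell_probs(p1, p2) -> CellProbs:
    """Map observer detection probabilities to DDO outcome probabilities.

    Parameters
    ----------
    p1, p2:
        Detection probability of the primary and the secondary observer
        (scalars or arrays in [0, 1]).

    Returns
    -------
    CellProbs
        ``(p1, (1 - p1) * p2, (1 - p1) * (1 - p2))``; the components sum
        to one for any valid input.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if not (((p1 >= 0) & (p1 <= 1)).all() and ((p2 >= 0) & (p2 <= 1)).all()):
        raise ValueError("detection probabilities must lie in [0, 1]")
    out = CellProbs(p1 + 0.0, (1.0 - p1) * p2, (1.0 - p1) * (1.0 - p2))
    if p1.ndim == 0 and p2.ndim == 0:
        out = CellProbs(float(out.pi1), float(out.pi2), float(out.pi3))
    return out


def _safe_log(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log(x)
    return np.where(np.isneginf(out), _LOG_TINY, out)


def multinomial_loglik(y1, y2, N, cp: CellProbs):
    """Log pmf of the trinomial DDO observation for one replicate.

    The cells are (y1, y2, N - y1 - y2): primary detections, secondary-only
    detections, and individuals missed by both. Accepts broadcasting arrays.

    Raises
    ------
    ValueError
        If counts are negative or ``y1 + y2 > N`` (an inconsistent latent
        state, not merely an improbable one).
    """
    y1 = np.asarray(y1, dtype=np.int64)
    y2 = np.asarray(y2, dtype=np.int64)
    N = np.asarray(N, dtype=np.int64)
    if (y1 < 0).any() or (y2 < 0).any() or (N < 0).any():
        raise ValueError("counts must be nonnegative")
    miss = N - y1 - y2
    if (miss < 0).any():
        raise ValueError("y1 + y2 exceeds N: inconsistent latent abundance")
    lp1, lp2, lp3 = (_safe_log(p) for p in cp.as_tuple())
    out = (
        gammaln(N + 1.0)
        - gammaln(y1 + 1.0)
        - gammaln(y2 + 1.0)
        - gammaln(miss + 1.0)
        + y1 * lp1
        + y2 * lp2
        + miss * lp3
    )
    return out if out.ndim else float(out)


def marginal_loglik_single_replicate(y1, y2, lam, cp: CellProbs):
    """Marginal log likelihood of a single-replicate survey, N integrated out.

    With one replicate, Poisson thinning factorises the marginal into two
    independent Poisson counts: ``y1 ~ Poisson(lam * pi1)`` and
    ``y2 ~ Poisson(lam * pi2)``. Used as an analytic oracle for the joint
    Poisson x trinomial construction, not by the sampler.
    """
    lam = np.asarray(lam, dtype=float)
    if (lam <= 0).any():
        raise ValueError("lambda must be positive")
    y1 = np.asarray(y1, dtype=np.int64)
    y2 = np.asarray(y2, dtype=np.int64)
    if (y1 < 0).any() or (y2 < 0).any():
        raise ValueError("counts must be nonnegative")
    out = 0.0
    for y, pi in ((y1, cp.pi1), (y2, cp.pi2)):
        mu = lam * np.asarray(pi, dtype=float)
        # Poisson logpmf, with the mu == 0 limit handled exactly
        term = np.where(mu > 0, y * _safe_log(mu) - mu - gammaln(y + 1.0), np.where(y == 0, 0.0, -np.inf))
        out = out + term
    out = np.asarray(out)
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# Parameter containers


@dataclass
class DetectionParams:
    """Observation-process parameters on the logit scale.

    ``eta_obs`` holds one logit-detection per observer *slot*: for the
    ``by_role`` structure there are exactly two slots (primary role,
    secondary role); for ``by_observer`` one per observer identity. With
    the ``by_observer_and_species`` structure, ``eta_species`` adds a
    sum-to-zero species offset so that species effects are separated from
    observer baselines.
    """

    eta_obs: np.ndarray
    eta_species: np.ndarray | None = None

    def copy(self) -> "DetectionParams":
        return DetectionParams(
            self.eta_obs.copy(),
            None if self.eta_species is None else self.eta_species.copy(),
        )


@dataclass
class AbundanceParams:
    """Basic-variant abundance parameters: one log mean per species."""

    log_lambda: np.ndarray

    @property
    def lam(self) -> np.ndarray:
        return np.exp(self.log_lambda)

    def copy(self) -> "AbundanceParams":
        return AbundanceParams(self.log_lambda.copy())


@dataclass
class CovariateParams:
    """Covariate-variant abundance parameters.

    log lambda[i, j, y] = beta0[i] + beta1[i] * ownership[j]
                          + beta2[i] * year_code[y] + alpha[j],
    with alpha ~ Normal(0, sigma_plot^2) and sigma_plot uniform on
    [0, sigma_plot_upper].
    """

    beta0: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    alpha: np.ndarray
    sigma_plot: float

    def copy(self) -> "CovariateParams":
        return CovariateParams(
            self.beta0.copy(), self.beta1.copy(), self.beta2.copy(),
            self.alpha.copy(), float(self.sigma_plot),
        )


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the vague priors.

    abundance_prior_var:
        Variance of the Normal(0, .) prior on log-mean abundance (basic) or
        on each regression coefficient (covariate variant). Default 1000.
    detection_prior:
        "uniform" (default) — detection probabilities are Uniform(0, 1),
        i.e. standard-logistic on the logit scale; "logit_normal" — logit
        detection is Normal(0, detection_prior_var). The vague logit-normal
        concentrates nearly all prior mass at p near 0 or 1, so the
        uniform is the better default for weakly identified designs.
    detection_prior_var:
        Variance of the Normal(0, .) prior on logit detection when
        ``detection_prior="logit_normal"``; also the variance of the
        species detection offsets in the observer x species structure.
        Default 10000.
    sigma_plot_upper:
        Upper bound of the Uniform(0, .) prior on the plot-effect standard
        deviation. Default 100.
    """

    abundance_prior_var: float = 1000.0
    detection_prior_var: float = 10000.0
    sigma_plot_upper: float = 100.0
    detection_prior: str = "uniform"

    def __post_init__(self):
        if min(self.abundance_prior_var, self.detection_prior_var, self.sigma_plot_upper) <= 0:
            raise ValueError("prior variances and bounds must be strictly positive")
        if self.detection_prior not in ("uniform", "logit_normal"):
            raise ValueError("detection_prior must be 'uniform' or 'logit_normal'")


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant and detection structure to fit.

    variant:
        "basic" — species-level log-mean abundance, no covariates;
        "covariate" — ownership + year fixed effects and a plot random
        effect on the log mean (requires ownership codes in the data).
    detection_structure:
        "by_role" — one detection probability per observer role (primary /
        secondary), shared across species (the basic design);
        "by_observer" — one per observer identity;
        "by_observer_and_species" — additive observer and (sum-to-zero)
        species effects on the logit scale.
    """

    variant: str = "basic"
    detection_structure: str = "by_role"

    def __post_init__(self):
        if self.variant not in ("basic", "covariate"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.detection_structure not in ("by_role", "by_observer", "by_observer_and_species"):
            raise ValueError(f"unknown detection structure {self.detection_structure!r}")


@dataclass
class ModelState:
    """Full parameter state of one MCMC chain.

    N has shape (S, J, Y); the abundance block is an AbundanceParams or
    CovariateParams matching the ModelSpec variant.
    """

    N: np.ndarray
    detection: DetectionParams
    abundance: AbundanceParams | CovariateParams

    def copy(self) -> "ModelState":
        return ModelState(self.N.copy(), self.detection.copy(), self.abundance.copy())


# ----------------------------------------------------------------------
# Field builders shared by the posterior and the sampler


def detection_logits(state: ModelState, data, spec: ModelSpec):
    """Per-survey logit detection for primary and secondary observers.

    Returns a pair of arrays broadcastable against (S, J, Y, K).
    """
    det = state.detection
    if spec.detection_structure == "by_role":
        eta_p = det.eta_obs[0]
        eta_s = det.eta_obs[1]
    else:
        eta_p = det.eta_obs[data.obs_primary]  # (J, Y, K)
        eta_s = det.eta_obs[data.obs_secondary]
        if spec.detection_structure == "by_observer_and_species":
            sp = det.eta_species[:, None, None, None]
            eta_p = eta_p[None] + sp
            eta_s = eta_s[None] + sp
    return eta_p, eta_s


def log_lambda_field(state: ModelState, data, spec: ModelSpec) -> np.ndarray:
    """log mean abundance per (species, plot, year), shape (S, J, Y)."""
    ab = state.abundance
    if spec.variant == "basic":
        return np.broadcast_to(
            ab.log_lambda[:, None, None],
            (data.n_species, data.n_plots, data.n_years),
        )
    own = data.ownership
    if own is None:
        raise ValueError("covariate variant requires plot ownership codes")
    yr = data.year_codes
    return (
        ab.beta0[:, None, None]
        + ab.beta1[:, None, None] * own[None, :, None]
        + ab.beta2[:, None, None] * yr[None, None, :]
        + ab.alpha[None, :, None]
    )


def _normal_logpdf(x, var) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * var) - 0.5 * x * x / var))


def detection_prior_logpdf(eta, priors: Priors) -> np.ndarray:
    """Elementwise log prior density of logit-detection values.

    Under the "uniform" prior, p ~ Uniform(0, 1) is equivalent to a
    standard-logistic density on eta = logit(p).
    """
    eta = np.asarray(eta, dtype=float)
    if priors.detection_prior == "uniform":
        log_p = -np.logaddexp(0.0, -eta)
        return log_p + (-eta + log_p)
    var = priors.detection_prior_var
    return -0.5 * np.log(2.0 * np.pi * var) - 0.5 * eta * eta / var


def prior_logdensity(state: ModelState, spec: ModelSpec, priors: Priors) -> float:
    """Log density of all priors at the current state (transformed scales)."""
    lp = float(np.sum(detection_prior_logpdf(state.detection.eta_obs, priors)))
    if state.detection.eta_species is not None:
        lp += _normal_logpdf(state.detection.eta_species, priors.detection_prior_var)
    ab = state.abundance
    if spec.variant == "basic":
        lp += _normal_logpdf(ab.log_lambda, priors.abundance_prior_var)
    else:
        for b in (ab.beta0, ab.beta1, ab.beta2):
            lp += _normal_logpdf(b, priors.abundance_prior_var)
        sig = float(ab.sigma_plot)
        if not (0.0 <= sig <= priors.sigma_plot_upper):
            return -np.inf
        lp += -np.log(priors.sigma_plot_upper)
        if ab.alpha.size:
            if sig == 0.0:
                lp += 0.0 if np.allclose(ab.alpha, 0.0) else -np.inf
            else:
                lp += _normal_logpdf(ab.alpha, sig * sig)
    return lp


def joint_logpost(state: ModelState, data, spec: ModelSpec, priors: Priors) -> float:
    """Joint log posterior density (up to the data-only normalising constant).

    Sum of the Poisson log pmf of the latent N given the abundance field,
    the trinomial log pmf of every replicate's counts given N and the
    observer pair's cell probabilities, and all prior log densities.

    Raises
    ------
    ValueError
        If the latent state is inconsistent with the data (some N below
        the detected total of a replicate).
    """
    N = np.asarray(state.N, dtype=np.int64)
    if N.shape != (data.n_species, data.n_plots, data.n_years):
        raise ValueError("latent N has the wrong shape")
    if (N < data.n_floor).any():
        raise ValueError("latent N below the maximum detected total of a replicate")

    lp = prior_logdensity(state, spec, priors)
    if not np.isfinite(lp):
        return -np.inf
    if data.is_empty:
        return lp

    loglam = log_lambda_field(state, data, spec)
    lp += float(np.sum(N * loglam - np.exp(loglam) - gammaln(N + 1.0)))

    eta_p, eta_s = detection_logits(state, data, spec)
    cp = ddo_cell_probs(expit(eta_p), expit(eta_s))
    lp += float(
        np.sum(multinomial_loglik(data.y1, data.y2, N[..., None], cp))
    )
    return lp
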