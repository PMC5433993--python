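"""Model layer: cell probabilities, likelihood factors, joint posterior."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import logsumexp
from scipy.stats import norm, poisson

import ddonmix as dx
from ddonmix.model import prior_logdensity


class TestCellProbs:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            (0.3, 0.5, (0.30, 0.35, 0.35)),
            (0.0, 0.0, (0.0, 0.0, 1.0)),
            (1.0, 0.7, (1.0, 0.0, 0.0)),
        ],
    )
    def test_known_values(self, p1, p2, expected):
        cp = dx.ddo_cell_probs(p1, p2)
        assert cp.as_tuple() == pytest.approx(expected, abs=1e-15)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_simplex_identity(self, p1, p2):
        cp = dx.ddo_cell_probs(p1, p2)
        assert all(0.0 <= c <= 1.0 for c in cp.as_tuple())
        assert cp.pi1 + cp.pi2 + cp.pi3 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("p1, p2", [(-0.1, 0.5), (0.3, 1.2), (np.nan, 0.5)])
    def test_out_of_range_rejected(self, p1, p2):
        with pytest.raises(ValueError):
            dx.ddo_cell_probs(p1, p2)


def _brute_force_trinomial(y1, y2, N, cp):
    """Enumerate every assignment of N individuals to the three outcomes."""
    total = 0.0
    for seq in itertools.product((0, 1, 2), repeat=N):
        if seq.count(0) == y1 and seq.count(1) == y2:
            total += cp.pi1 ** y1 * cp.pi2 ** y2 * cp.pi3 ** (N - y1 - y2)
    return np.log(total)


class TestMultinomialLoglik:
    def test_empty_trial(self):
        cp = dx.ddo_cell_probs(0.3, 0.5)
        assert dx.multinomial_loglik(0, 0, 0, cp) == 0.0

    def test_single_trial_equals_cell_probability(self):
        cp = dx.ddo_cell_probs(0.3, 0.5)
        assert dx.multinomial_loglik(1, 0, 1, cp) == pytest.approx(np.log(0.3))
        assert dx.multinomial_loglik(0, 1, 1, cp) == pytest.approx(np.log(0.35))

    def test_matches_exhaustive_enumeration(self):
        cp = dx.ddo_cell_probs(0.3, 0.5)
        expected = _brute_force_trinomial(2, 1, 5, cp)
        assert dx.multinomial_loglik(2, 1, 5, cp) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("N", [1, 3, 6])
    @pytest.mark.parametrize("p1, p2", [(0.3, 0.5), (0.9, 0.1), (0.5, 0.5)])
    def test_normalises_over_all_outcomes(self, N, p1, p2):
        cp = dx.ddo_cell_probs(p1, p2)
        lps = [
            dx.multinomial_loglik(y1, y2, N, cp)
            for y1 in range(N + 1)
            for y2 in range(N + 1 - y1)
        ]
        assert logsumexp(lps) == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        cp = dx.ddo_cell_probs(0.3, 0.5)
        with pytest.raises(ValueError):
            dx.multinomial_loglik(3, 3, 5, cp)
        with pytest.raises(ValueError):
            dx.multinomial_loglik(-1, 0, 5, cp)


class TestMarginalSingleReplicate:
    def test_thinning_identity(self):
        cp = dx.ddo_cell_probs(0.3, 0.5)
        got = dx.marginal_loglik_single_replicate(3, 2, 10.0, cp)
        expected = poisson.logpmf(3, 3.0) + poisson.logpmf(2, 3.5)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_vanishing_lambda_limit(self):
        cp = dx.ddo_cell_probs(0.3, 0.5)
        assert dx.marginal_loglik_single_replicate(0, 0, 1e-12, cp) == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_lambda_rejected(self):
        cp = dx.ddo_cell_probs(0.3, 0.5)
        with pytest.raises(ValueError):
            dx.marginal_loglik_single_replicate(0, 0, 0.0, cp)

    @pytest.mark.parametrize("lam", [0.5, 3.0, 12.0])
    @pytest.mark.parametrize("p1", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("p2", [0.2, 0.7])
    def test_matches_truncated_poisson_multinomial_sum(self, lam, p1, p2):
        """Marginalising N by truncated summation reproduces the identity."""
        cp = dx.ddo_cell_probs(p1, p2)
        for y1, y2 in [(0, 0), (1, 2), (4, 1)]:
            upper = int(poisson.isf(1e-13, lam)) + y1 + y2 + 30
            Ns = np.arange(y1 + y2, upper)
            terms = poisson.logpmf(Ns, lam) + dx.multinomial_loglik(
                np.full_like(Ns, y1), np.full_like(Ns, y2), Ns, cp
            )
            expected = logsumexp(terms)
            got = dx.marginal_loglik_single_replicate(y1, y2, lam, cp)
            assert got == pytest.approx(expected, rel=1e-10)


def _single_site_data(y1, y2, observers=("obs1", "obs2")):
    return dx.DDOCounts(
        species=["spA"],
        plots=["p1"],
        years=[1],
        observers=list(observers),
        y1=np.array(y1).reshape(1, 1, 1, -1),
        y2=np.array(y2).reshape(1, 1, 1, -1),
        obs_primary=np.zeros((1, 1, np.size(y1)), dtype=int),
        obs_secondary=np.ones((1, 1, np.size(y1)), dtype=int),
    )


def _basic_state(N, log_lambda, eta_p, eta_s):
    return dx.ModelState(
        N=np.array(N).reshape(1, 1, 1),
        detection=dx.DetectionParams(eta_obs=np.array([eta_p, eta_s], dtype=float)),
        abundance=dx.AbundanceParams(log_lambda=np.array([log_lambda], dtype=float)),
    )


class TestJointLogpost:
    priors = dx.Priors(detection_prior="logit_normal")

    def test_empty_data_is_prior_only(self):
        data = dx.DDOCounts.empty(["spA"])
        state = dx.ModelState(
            N=np.zeros((1, 0, 1), dtype=int),
            detection=dx.DetectionParams(eta_obs=np.array([0.2, -0.3])),
            abundance=dx.AbundanceParams(log_lambda=np.array([0.7])),
        )
        lp = dx.joint_logpost(state, data, dx.ModelSpec(), self.priors)
        expected = (
            norm.logpdf(0.7, 0, np.sqrt(1000))
            + norm.logpdf(0.2, 0, 100)
            + norm.logpdf(-0.3, 0, 100)
        )
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_single_site_hand_composition(self):
        from scipy.special import expit

        data = _single_site_data([2], [1])
        state = _basic_state(6, np.log(5.0), 0.1, -0.4)
        lp = dx.joint_logpost(state, data, dx.ModelSpec(), self.priors)
        cp = dx.ddo_cell_probs(expit(0.1), expit(-0.4))
        expected = (
            poisson.logpmf(6, 5.0)
            + dx.multinomial_loglik(2, 1, 6, cp)
            + norm.logpdf(np.log(5.0), 0, np.sqrt(1000))
            + norm.logpdf(0.1, 0, 100)
            + norm.logpdf(-0.4, 0, 100)
        )
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_factor_additivity(self):
        """Changing one block changes the posterior by exactly that factor."""
        data = _single_site_data([2, 0], [1, 3])
        spec = dx.ModelSpec()
        s1 = _basic_state(7, np.log(4.0), 0.0, 0.0)
        s2 = s1.copy()
        s2.abundance.log_lambda[:] = np.log(9.0)
        diff = dx.joint_logpost(s2, data, spec, self.priors) - dx.joint_logpost(
            s1, data, spec, self.priors
        )
        expected = (
            poisson.logpmf(7, 9.0)
            - poisson.logpmf(7, 4.0)
            + norm.logpdf(np.log(9.0), 0, np.sqrt(1000))
            - norm.logpdf(np.log(4.0), 0, np.sqrt(1000))
        )
        assert diff == pytest.approx(expected, rel=1e-10)

    def test_inconsistent_latent_state_rejected(self):
        data = _single_site_data([2], [1])
        state = _basic_state(2, np.log(5.0), 0.0, 0.0)  # floor is 3
        with pytest.raises(ValueError):
            dx.joint_logpost(state, data, dx.ModelSpec(), self.priors)

    def test_invariant_to_table_row_order(self, basic_sim, rng):
        data, _ = basic_sim
        frame = data.to_frame()
        shuffled = frame.sample(frac=1.0, random_state=123).reset_index(drop=True)
        data2 = dx.DDOCounts.from_frame(shuffled)
        state = _basic_state(0, 0, 0, 0)
        state.N = data.n_floor + 1
        state.abundance = dx.AbundanceParams(log_lambda=np.full(data.n_species, 1.5))
        lp1 = dx.joint_logpost(state, data, dx.ModelSpec(), self.priors)
        state2 = state.copy()
        state2.N = data2.n_floor + 1
        lp2 = dx.joint_logpost(state2, data2, dx.ModelSpec(), self.priors)
        assert lp1 == pytest.approx(lp2, rel=1e-12)


class TestPriors:
    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            dx.Priors(abundance_prior_var=0.0)
        with pytest.raises(ValueError):
            dx.Priors(detection_prior="beta")

    def test_uniform_detection_prior_integrates_to_one(self):
        """The standard-logistic density on logit(p) is a proper prior."""
        from scipy.integrate import quad
        from ddonmix.model import detection_prior_logpdf

        pr = dx.Priors(detection_prior="uniform")
        val, _ = quad(lambda e: np.exp(detection_prior_logpdf(e, pr)), -40, 40)
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_sigma_outside_support_gives_minus_inf(self):
        data = dx.DDOCounts.empty(["spA"])
        state = dx.ModelState(
            N=np.zeros((1, 0, 1), dtype=int),
            detection=dx.DetectionParams(eta_obs=np.zeros(2)),
            abundance=dx.CovariateParams(
                beta0=np.zeros(1), beta1=np.zeros(1), beta2=np.zeros(1),
                alpha=np.zeros(0), sigma_plot=150.0,
            ),
        )
        spec = dx.ModelSpec(variant="covariate")
        assert prior_logdensity(state, spec, dx.Priors()) == -np.inf
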