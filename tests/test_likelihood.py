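"""Tree log-likelihoods under the three sampling schemes."""

import numpy as np
import pytest
from scipy.special import gammaln

from bdiv import (
    ProcessWindow,
    ReconstructedTree,
    SamplingScheme,
    SpeciationTimeDistribution,
    fit_mle,
    loglik,
    loglik_complete,
    loglik_diversified,
    loglik_diversified_given_n,
    loglik_uniform,
    make_model,
)
from bdiv.core import log_q


class TestReconstructedTree:
    def test_validation(self):
        with pytest.raises(ValueError, match="MRCA"):
            ReconstructedTree(np.array([0.5, 1.0]), 2.0)
        with pytest.raises(ValueError, match="\\[0, age\\]"):
            ReconstructedTree(np.array([0.0, 3.0]), 2.0)
        with pytest.raises(ValueError, match="n="):
            ReconstructedTree(np.array([0.0, 1.0]), 2.0, n=2)

    def test_counts(self, hand_trees):
        t = hand_trees["five_tip"]
        assert t.m == 5 and t.n == 5 and t.t_star == 1.5

    def test_snake_style_sampling_fraction(self, hand_trees):
        t = hand_trees["snake_style"]
        assert t.m == 41 and t.n == 3500
        assert t.sampling_fraction == pytest.approx(41 / 3500)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            SamplingScheme("complete", 0.5)
        with pytest.raises(ValueError):
            SamplingScheme("uniform", 0.0)
        with pytest.raises(ValueError):
            SamplingScheme("nonsense")


class TestCompleteSampling:
    def test_two_tip_yule_closed_form(self):
        """Both root lineages leave exactly one descendant: e^{-2 lam T}."""
        lam, T = 0.5, 3.0
        tree = ReconstructedTree(np.array([0.0]), T)
        assert loglik_complete(tree, make_model("M1", [lam])) == pytest.approx(
            -2 * lam * T, abs=1e-12
        )

    def test_exchangeability(self, hand_trees, six_models):
        """Divergence-time order does not affect the likelihood."""
        t = hand_trees["five_tip"]
        shuffled = ReconstructedTree(t.divergence_times[::-1].copy(), t.age)
        for m in six_models.values():
            assert loglik_complete(t, m) == loglik_complete(shuffled, m)

    def test_brute_force_factorized_oracle(self, hand_trees):
        """Linear-space product of constant-rate closed forms (5 tips, M3)."""
        t5 = hand_trees["five_tip"]
        lam, mu, T = 1.0, 0.5, t5.age
        b = lam - mu

        def ps(s):
            return b * np.exp(b * (T - s)) / (lam * np.exp(b * (T - s)) - mu)

        def q(s):
            return ps(s) * np.exp(-b * (T - s))

        m = t5.m
        L = (m - 1) * q(0) ** 2 * (1 - q(0)) ** (m - 2) * np.exp(gammaln(m - 1))
        for ti in t5.divergence_times[1:]:
            L *= lam * ps(ti) ** 2 * np.exp(-b * (T - ti)) / (1 - q(0))
        impl = loglik_complete(t5, make_model("M3", [lam, mu]))
        assert impl == pytest.approx(np.log(L), abs=1e-10)

    def test_requires_complete_tree(self, hand_trees):
        with pytest.raises(ValueError, match="n == m"):
            loglik_complete(hand_trees["snake_style"], make_model("M1", [0.5]))

    def test_unconditioned_variant_is_flagged_and_lower(self, hand_trees):
        tree = hand_trees["five_tip"]
        m = make_model("M3", [1.0, 0.5])
        cond = loglik_complete(tree, m, condition_on_survival=True)
        uncond = loglik_complete(tree, m, condition_on_survival=False)
        # unconditioned density = conditional * P(both survive)^... < conditional
        assert uncond < cond


class TestUniformSampling:
    def test_rho_one_identity(self, hand_trees, six_models):
        for t in hand_trees.values():
            if t.n != t.m:
                continue
            for m in six_models.values():
                assert loglik_uniform(t, m, 1.0) == pytest.approx(
                    loglik_complete(t, m), abs=1e-12
                )

    def test_constant_rate_literature_closed_form(self, hand_trees):
        """Independent sampled p0/p1 construction (Yang-Rannala form)."""
        lam, mu, rho = 0.8, 0.3, 0.4
        t4 = hand_trees["four_tip"]
        T, b = t4.age, lam - mu

        def den(tau):
            return rho * lam + (lam * (1 - rho) - mu) * np.exp(-b * tau)

        p0 = lambda tau: 1 - rho * b / den(tau)
        p1 = lambda tau: rho * b * b * np.exp(-b * tau) / den(tau) ** 2
        m = t4.m
        independent = (
            np.log(m - 1) + gammaln(m - 1) + 2 * np.log(p1(T) / (1 - p0(T)))
            + sum(np.log(lam * p1(T - ti)) for ti in t4.divergence_times[1:])
        )
        got = loglik_uniform(t4, make_model("M3", [lam, mu]), rho)
        assert got == pytest.approx(independent, abs=1e-10)

    def test_invalid_rho(self, hand_trees):
        with pytest.raises(ValueError):
            loglik_uniform(hand_trees["four_tip"], make_model("M1", [0.5]), 0.0)

    def test_mle_compensates_for_thinning(self, hand_trees):
        """Unsampled speciation events push the inferred rate up."""
        t = hand_trees["five_tip"]
        full = fit_mle(t, "M1", SamplingScheme("uniform", 1.0), restarts=3, seed=0)
        half = fit_mle(t, "M1", SamplingScheme("uniform", 0.5), restarts=3, seed=0)
        assert half.params_hat[0] > full.params_hat[0]


class TestDiversifiedSampling:
    def test_rho_one_identity(self, hand_trees, six_models):
        for t in hand_trees.values():
            if t.n != t.m:
                continue
            for m in six_models.values():
                assert loglik_diversified(t, m, 1.0) == pytest.approx(
                    loglik_complete(t, m), abs=1e-12
                )

    def test_missing_event_power_law(self, hand_trees):
        """Each extra missing species multiplies by (1 - F(t*)) and the
        count combinatorics shift accordingly (exact log difference)."""
        base = hand_trees["five_tip"]
        model = make_model("M3", [1.0, 0.5])
        t8 = ReconstructedTree(base.divergence_times, base.age, n=8)
        t11 = ReconstructedTree(base.divergence_times, base.age, n=11)
        dist = SpeciationTimeDistribution(ProcessWindow(model, 0.0, base.age))
        lsf = float(dist.log_sf(np.float64(base.t_star)))
        expected = 3 * lsf + (gammaln(10) - gammaln(7)) - (gammaln(7) - gammaln(4))
        got = loglik_diversified_given_n(t11, model) - loglik_diversified_given_n(t8, model)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_given_n_reduces_when_n_equals_m(self, hand_trees):
        """No unobserved events: the given-n density is the i.i.d. product."""
        t = hand_trees["five_tip"]
        model = make_model("M3", [1.0, 0.5])
        dist = SpeciationTimeDistribution(ProcessWindow(model, 0.0, t.age))
        expected = float(np.sum(dist.log_density(t.divergence_times[1:]))) + float(
            gammaln(t.m - 1)
        )
        assert loglik_diversified_given_n(t, model) == pytest.approx(expected, abs=1e-10)

    def test_marginalization_identity(self, hand_trees):
        """Conditioning only on the MRCA = given-n density times the
        survival-conditioned geometric probability of n."""
        base = hand_trees["five_tip"]
        model = make_model("M3", [1.0, 0.5])
        t8 = ReconstructedTree(base.divergence_times, base.age, n=8)
        lq0 = float(log_q(model, np.float64(0.0), base.age, 1.0))
        count_term = np.log(7) + 2 * lq0 + 6 * np.log1p(-np.exp(lq0))
        manual = count_term + loglik_diversified_given_n(t8, model)
        assert loglik_diversified(t8, model) == pytest.approx(manual, abs=1e-12)

    def test_n_from_rho(self, hand_trees):
        t = hand_trees["five_tip"]
        model = make_model("M1", [0.5])
        explicit = loglik_diversified(
            ReconstructedTree(t.divergence_times, t.age, n=10), model
        )
        assert loglik_diversified(t, model, rho=0.5) == pytest.approx(explicit, abs=1e-12)

    def test_n_less_than_m_rejected(self, hand_trees):
        t = hand_trees["five_tip"]
        with pytest.raises(ValueError):
            ReconstructedTree(t.divergence_times, t.age, n=3)


def test_likelihood_smooth_in_parameters(hand_trees):
    """Finite-difference smoothness of the log-likelihood on a grid."""
    t = hand_trees["five_tip"]
    lams = np.linspace(0.4, 1.6, 25)
    vals = np.array([
        loglik_diversified(
            ReconstructedTree(t.divergence_times, t.age, n=9),
            make_model("M3", [lam, 0.3]),
        )
        for lam in lams
    ])
    second = np.diff(vals, 2)
    assert np.all(np.isfinite(vals))
    assert np.max(np.abs(second)) < 0.1  # no kinks at this resolution


def test_dispatcher_matches_direct_calls(hand_trees):
    t = hand_trees["five_tip"]
    m = make_model("M3", [1.0, 0.5])
    assert loglik(t, m, SamplingScheme("complete")) == loglik_complete(t, m)
    assert loglik(t, m, SamplingScheme("uniform", 0.7)) == loglik_uniform(t, m, 0.7)
    t8 = ReconstructedTree(t.divergence_times, t.age, n=8)
    assert loglik(t8, m, SamplingScheme("diversified", 0.625)) == loglik_diversified(
        t8, m, 0.625
    )
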