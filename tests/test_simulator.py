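"""Simulator: distributional correctness, sampling operations, reproducibility."""

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from bdiv import (
    ProcessWindow,
    ReconstructedTree,
    SamplingScheme,
    SimulationSpec,
    SpeciationTimeDistribution,
    apply_diversified_sampling,
    apply_uniform_sampling,
    make_model,
    simulate_reconstructed,
    tree_to_newick,
)
from bdiv.adequacy import gamma_statistic


def _sim(model, T, reps, seed, **kw):
    return simulate_reconstructed(
        SimulationSpec(model=model, conditioning="age", value=T,
                       replicates=reps, seed=seed, **kw)
    )


class TestSimulateReconstructed:
    def test_seed_reproducibility(self):
        m = make_model("M3", [1.0, 0.5])
        a = _sim(m, 5.0, 20, 42)
        b = _sim(m, 5.0, 20, 42)
        for ta, tb in zip(a, b):
            assert ta.age == tb.age and ta.m == tb.m
            np.testing.assert_array_equal(ta.divergence_times, tb.divergence_times)

    def test_requires_seed_or_rng(self):
        spec = SimulationSpec(model=make_model("M1", [0.5]), conditioning="age",
                              value=3.0)
        with pytest.raises(ValueError, match="seed"):
            simulate_reconstructed(spec)

    def test_impossible_conditioning(self):
        with pytest.raises(ValueError):
            SimulationSpec(model=make_model("M1", [0.5]), conditioning="taxa",
                           value=1)
        with pytest.raises(ValueError, match="survive"):
            SimulationSpec(model=make_model("M1", [0.5]), conditioning="age",
                           value=3.0, survival_conditioning=False)

    def test_yule_tip_counts_follow_geometric_pair_law(self):
        lam, T = 0.5, 4.0
        trees = _sim(make_model("M1", [lam]), T, 4000, 7)
        counts = np.array([t.m for t in trees])
        q = np.exp(-lam * T)
        ns = np.arange(2, counts.max() + 40)
        expected = (ns - 1) * q**2 * (1 - q) ** (ns - 2) * len(trees)
        observed = np.bincount(counts, minlength=ns.max() + 1)[2:ns.max() + 1]
        mask = expected >= 5
        obs = np.append(observed[mask], observed[~mask].sum()).astype(float)
        exp = np.append(expected[mask], expected[~mask].sum())
        obs *= exp.sum() / obs.sum()
        assert chisquare(obs, exp).pvalue > 0.01

    def test_divergence_times_match_density(self):
        """Simulated times pass a KS test against the analytic CDF (M2, the
        strongly time-varying family)."""
        m = make_model("M2", [2.0, 0.3])
        trees = _sim(m, 6.0, 40, 3)
        pool = np.concatenate([t.divergence_times[1:] for t in trees])
        dist = SpeciationTimeDistribution(ProcessWindow(m, 0.0, 6.0))
        assert kstest(pool, lambda x: dist.cdf(x)).pvalue > 0.01

    def test_critical_process_survives_and_grows(self):
        """lambda = mu: conditioning keeps every replicate alive and the mean
        clade size grows with the process age."""
        m = make_model("M3", [1.0, 1.0])
        small = _sim(m, 2.0, 400, 5)
        large = _sim(m, 6.0, 400, 6)
        assert all(t.m >= 2 for t in small + large)
        assert np.mean([t.m for t in large]) > np.mean([t.m for t in small])

    def test_taxa_conditioning_fixes_size(self):
        trees = simulate_reconstructed(
            SimulationSpec(model=make_model("M1", [0.4]), conditioning="taxa",
                           value=30, replicates=50, seed=9)
        )
        assert all(t.m == 30 for t in trees)
        ages = np.array([t.age for t in trees])
        assert ages.std() > 0  # the age is drawn, not fixed

    def test_yule_fixed_n_gamma_near_zero(self):
        """Classical pure-birth null: mean gamma ~ 0 for fixed-size trees."""
        trees = simulate_reconstructed(
            SimulationSpec(model=make_model("M1", [0.4]), conditioning="taxa",
                           value=50, replicates=1500, seed=13)
        )
        g = np.array([gamma_statistic(t) for t in trees])
        se = g.std(ddof=1) / np.sqrt(len(g))
        assert abs(g.mean()) < 3 * se + 0.005


class TestUniformSampling:
    def test_rho_one_is_identity(self):
        tree = _sim(make_model("M1", [0.5]), 4.0, 1, 3, topology=True)[0]
        assert apply_uniform_sampling(tree, 1.0, seed=0) is tree

    def test_binomial_mean_and_subset_property(self):
        tree = _sim(make_model("M1", [0.6]), 6.0, 1, 21, topology=True)[0]
        assert tree.m > 50
        rng = np.random.default_rng(0)
        kept = []
        for _ in range(300):
            thinned = apply_uniform_sampling(tree, 0.3, rng=rng)
            kept.append(thinned.m)
            # retained divergence times are a subset of the original ones
            t_mrca = tree.age - thinned.age
            for t in thinned.divergence_times[1:] + t_mrca:
                assert np.min(np.abs(tree.divergence_times - t)) < 1e-9
        mean = np.mean(kept)
        se = np.std(kept, ddof=1) / np.sqrt(len(kept))
        assert abs(mean - 0.3 * tree.m) < 3 * se + 1.0

    def test_invalid_rho(self):
        tree = _sim(make_model("M1", [0.5]), 4.0, 1, 3, topology=True)[0]
        with pytest.raises(ValueError):
            apply_uniform_sampling(tree, 1.5, seed=0)

    def test_rejection_counting(self):
        tree = _sim(make_model("M1", [0.4]), 3.0, 1, 8, topology=True)[0]
        thinned, rej = apply_uniform_sampling(
            tree, 0.05, seed=4, return_rejections=True
        )
        assert thinned.m >= 2 and rej >= 0

    def test_thinning_matches_rho_modified_law(self):
        """Mechanical tip thinning + pruning reproduces the analytic
        rho-modified speciation-time distribution (independent cross-check
        of the uniform-sampling mathematics)."""
        m1 = make_model("M1", [0.5])
        T, rho = 6.0, 0.4
        trees = simulate_reconstructed(
            SimulationSpec(model=m1, conditioning="age", value=T, replicates=800,
                           seed=17, scheme=SamplingScheme("uniform", rho))
        )
        keep = [t for t in trees if abs(t.age - T) < 1e-9]  # sampled MRCA = root
        pool = np.concatenate([t.divergence_times[1:] for t in keep])
        dist = SpeciationTimeDistribution(ProcessWindow(m1, 0.0, T), rho=rho)
        assert kstest(pool, lambda x: dist.cdf(x)).pvalue > 0.01


class TestDiversifiedSampling:
    def test_identity_when_m_equals_n(self, hand_trees):
        t = hand_trees["five_tip"]
        assert apply_diversified_sampling(t, 5) is t

    def test_keeps_oldest_events(self, hand_trees):
        t = hand_trees["five_tip"]  # times 0, 0.3, 0.8, 1.5
        pruned = apply_diversified_sampling(t, 3)
        np.testing.assert_allclose(pruned.divergence_times, [0.0, 0.3])
        assert pruned.age == t.age and pruned.m == 3

    def test_cut_point_ordering(self):
        trees = _sim(make_model("M3", [1.0, 0.3]), 5.0, 30, 31)
        for t in trees:
            if t.m < 6:
                continue
            m = t.m // 2
            pruned = apply_diversified_sampling(t, m)
            removed = t.divergence_times[m - 1:]
            assert pruned.divergence_times.max() <= removed.min() + 1e-12

    def test_bounds(self, hand_trees):
        t = hand_trees["five_tip"]
        with pytest.raises(ValueError):
            apply_diversified_sampling(t, 6)
        with pytest.raises(ValueError):
            apply_diversified_sampling(t, 1)


def test_newick_roundtrip_through_treeio():
    from bdiv.treeio import read_newick, to_reconstructed

    tree = _sim(make_model("M3", [1.0, 0.5]), 5.0, 1, 77, topology=True)[0]
    text = tree_to_newick(tree)
    rec = to_reconstructed(read_newick(text))
    assert rec.m == tree.m
    np.testing.assert_allclose(
        rec.divergence_times, tree.divergence_times, atol=1e-8
    )
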