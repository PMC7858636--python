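import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

from multicoloc import (
    CorrelationModel,
    PriorSpec,
    alignment_probability,
    exhaustive_posterior,
    full_hypothesis,
    ppfc,
    refined_regional,
    regional_probability,
    variant_prior,
)
from multicoloc.priors import config_prior_odds
from tests.conftest import make_region


def coloc_pairwise_posteriors(z1, z2, v, w, p1, p2, p12):
    """Independent re-implementation of the classic five-hypothesis pairwise
    colocalization sums (H0: neither associated ... H4: shared variant)."""
    def labf(z):
        r = w * w / (w * w + v * v)
        return 0.5 * np.log1p(-r) + 0.5 * np.asarray(z) ** 2 * r

    l1, l2 = labf(z1), labf(z2)
    s1, s2 = logsumexp(l1), logsumexp(l2)
    same = logsumexp(l1 + l2)
    lh = {
        "H0": 0.0,
        "H1": math.log(p1) + s1,
        "H2": math.log(p2) + s2,
        "H3": math.log(p1) + math.log(p2) + (s1 + s2) + math.log1p(-math.exp(same - s1 - s2)),
        "H4": math.log(p12) + same,
    }
    tot = logsumexp(list(lh.values()))
    return {k: math.exp(v_ - tot) for k, v_ in lh.items()}


class TestRegionalProbability:
    def test_single_snp_two_traits_closed_form(self, default_priors):
        # Q = 1, both z = 0 and v = w: four configurations, ABF = sqrt(1/2)
        # per associated trait
        region = make_region(np.zeros((2, 1)), se=0.15, prior_sd=0.15)
        p = default_priors.p
        pc = default_priors.pc
        h1 = p * math.sqrt(0.5)
        h4 = p * pc * 0.5
        expected = h4 / (1.0 + 2 * h1 + h4)
        p_r, _ = regional_probability(region, default_priors)
        assert p_r == pytest.approx(expected, rel=1e-12)
        exact = exhaustive_posterior(region, default_priors)
        assert exact.posterior[full_hypothesis(2)] == pytest.approx(expected, rel=1e-12)

    def test_no_data_limit_is_pure_prior_arithmetic(self, default_priors):
        # a practically zero prior SD makes every ABF 1, so P_R reduces to
        # the ratio of class prior masses
        m, q = 3, 5
        region = make_region(np.zeros((m, q)), se=0.02, prior_sd=1e-9)
        pf = variant_prior(m, default_priors)
        pd_ = variant_prior(m - 1, default_priors)
        expected = q * pf / (1.0 + m * q * pd_ + q * pf)
        p_r, evidence = regional_probability(region, default_priors)
        assert p_r == pytest.approx(expected, rel=1e-6)
        np.testing.assert_allclose(
            evidence, q * pd_ / (1.0 + m * q * pd_ + q * pf), rtol=1e-6
        )

    def test_strong_shared_signal_matches_oracle(self, default_priors):
        z = np.zeros((2, 100))
        z[:, 40] = 12.0
        region = make_region(z)
        p_r, _ = regional_probability(region, default_priors)
        assert p_r > 0.99
        exact = exhaustive_posterior(region, default_priors)
        bd = ppfc(region, default_priors)
        assert bd.ppfc == pytest.approx(exact.posterior[full_hypothesis(2)], rel=1e-6)


class TestAlignmentProbability:
    def test_single_snp_region_has_alignment_one(self, default_priors):
        region = make_region(np.array([[3.0], [2.0]]))
        p_a, evidence = alignment_probability(region, default_priors)
        assert p_a == 1.0
        assert np.all(evidence == 0)
        bd = ppfc(region, default_priors)
        assert bd.p_a == 1.0
        assert bd.ppfc == pytest.approx(bd.p_r)

    def test_distinct_uncorrelated_lead_snps_give_near_zero(self, default_priors):
        z = np.array([[12.0, 0.0], [0.0, 12.0]])
        region = make_region(z)
        p_a, _ = alignment_probability(region, default_priors)
        assert p_a < 1e-6
        # and agrees exactly with the exhaustive class ratio
        exact = exhaustive_posterior(region, default_priors)
        hm = exact.posterior[full_hypothesis(2)]
        h11 = exact.hypothesis_class((1, 1))
        assert p_a == pytest.approx(hm / (hm + h11), rel=1e-10)

    def test_identical_traits_align(self, shared_signal_region, default_priors):
        p_a, _ = alignment_probability(shared_signal_region, default_priors)
        assert p_a > 0.9


class TestPpfcBreakdown:
    def test_snp_share_concentrates_on_the_signal(self, shared_signal_region, default_priors):
        bd = ppfc(shared_signal_region, default_priors)
        assert bd.snp_share.sum() == pytest.approx(1.0, abs=1e-8)
        assert bd.top_snp_index == 7
        assert bd.ppe > 0.99
        assert bd.best_config.assignment == (7, 7)

    def test_snp_share_matches_per_configuration_enumeration(self, rng, default_priors):
        from multicoloc import config_log_abf

        z = rng.normal(0, 1, size=(3, 6))
        z[:, 2] += 7.0
        region = make_region(z)
        lp = math.log(config_prior_odds("Hk", 3, 3, 6, default_priors))
        terms = np.array(
            [config_log_abf(region, [j, j, j]) + lp for j in range(6)]
        )
        share = np.exp(terms - logsumexp(terms))
        bd = ppfc(region, default_priors)
        np.testing.assert_allclose(bd.snp_share, share, atol=1e-12)
        exact = exhaustive_posterior(region, default_priors)
        np.testing.assert_allclose(exact.snp_share, share, atol=1e-12)

    def test_trait_order_invariance(self, rng, default_priors):
        z = rng.normal(0, 1, size=(4, 15))
        z[:, 5] += 6.0
        region = make_region(z)
        perm = [2, 0, 3, 1]
        bd1 = ppfc(region, default_priors)
        bd2 = ppfc(region.subset_traits(perm), default_priors)
        assert bd2.p_r == pytest.approx(bd1.p_r, abs=1e-12)
        assert bd2.p_a == pytest.approx(bd1.p_a, abs=1e-12)
        assert bd2.ppfc == pytest.approx(bd1.ppfc, abs=1e-12)

    def test_ppfc_monotone_in_pc_for_fixed_data(self, rng):
        z = rng.normal(0, 1, size=(2, 30))
        z[:, 12] += 5.0
        region = make_region(z)
        vals = [ppfc(region, PriorSpec(pc=pc)).ppfc for pc in (0.005, 0.01, 0.02, 0.05, 0.1)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_exact_tie_prefers_lowest_snp_index(self, default_priors):
        z = np.zeros((2, 8))
        z[:, 2] = 9.0
        z[:, 5] = 9.0
        bd = ppfc(make_region(z), default_priors)
        assert bd.best_config.assignment == (2, 2)


class TestRefinedRegional:
    def test_two_traits_identical_to_regional(self, rng, default_priors):
        z = rng.normal(0, 1, size=(2, 12))
        region = make_region(z)
        p_r, _ = regional_probability(region, default_priors)
        assert refined_regional(region, default_priors) == pytest.approx(p_r, rel=1e-12)

    def test_strong_colocalization_changes_little(self, default_priors):
        z = np.zeros((3, 40))
        z[:, 18] = 11.0
        region = make_region(z)
        p_r, _ = regional_probability(region, default_priors)
        p_r_ref = refined_regional(region, default_priors)
        assert abs(p_r_ref - p_r) / p_r < 0.01

    def test_superset_denominator_never_exceeds_regional(self, rng, default_priors):
        for _ in range(10):
            z = rng.normal(0, 1.5, size=(3, 10))
            region = make_region(z)
            p_r, _ = regional_probability(region, default_priors)
            assert refined_regional(region, default_priors) <= p_r + 1e-12


class TestExhaustiveOracle:
    def test_posterior_sums_to_one(self, rng, default_priors):
        z = rng.normal(0, 2, size=(3, 8))
        exact = exhaustive_posterior(make_region(z), default_priors)
        assert exact.total == pytest.approx(1.0, abs=1e-10)

    def test_null_data_is_prior_dominated(self, default_priors):
        region = make_region(np.zeros((2, 20)), se=1.0)
        exact = exhaustive_posterior(region, default_priors)
        assert exact.posterior[frozenset()] > 0.99

    def test_matches_independent_pairwise_reimplementation(self, rng):
        z = rng.normal(0, 1, size=(2, 10))
        z[:, 4] += 6.0
        v, w = 0.02, 0.15
        region = make_region(z, se=v, prior_sd=w)
        spec = PriorSpec(p=1e-4, pc=0.02)
        oracle = coloc_pairwise_posteriors(
            z[0], z[1], v, w, p1=spec.p, p2=spec.p, p12=spec.p * spec.pc
        )
        exact = exhaustive_posterior(region, spec)
        assert exact.posterior[full_hypothesis(2)] == pytest.approx(oracle["H4"], rel=1e-10)
        assert exact.posterior[frozenset()] == pytest.approx(oracle["H0"], rel=1e-10)
        assert exact.posterior[frozenset({frozenset({0})})] == pytest.approx(
            oracle["H1"], rel=1e-10
        )
        assert exact.hypothesis_class((1, 1)) == pytest.approx(oracle["H3"], rel=1e-10)

    def test_budget_guard(self, default_priors):
        region = make_region(np.zeros((4, 60)))
        with pytest.raises(ValueError, match="budget"):
            exhaustive_posterior(region, default_priors, budget=1e5)

    def test_uniform_prior_scheme_also_normalizes(self, rng):
        z = rng.normal(0, 1, size=(2, 6))
        spec = PriorSpec(scheme="conditionally_uniform")
        exact = exhaustive_posterior(make_region(z), spec)
        assert exact.total == pytest.approx(1.0, abs=1e-10)


class TestApproximationError:
    def test_error_bound_on_confident_instances(self, default_priors):
        """|P_R*P_A - exact| stays within the second-order bound
        delta_A^2 + delta_R*delta_A (+ slack) whenever both probabilities
        are high — the regime where colocalization would be declared.
        Fixtures come from the generative model (a genuinely shared causal
        variant under LD), where the neglected-class mass is controlled by
        the deltas."""
        from multicoloc import SimScenario, simulate_region

        checked = 0
        root = np.random.SeedSequence(20240917)
        for stream in root.spawn(250):
            rng = np.random.default_rng(stream)
            m = int(rng.integers(2, 4))
            scn = SimScenario(m=m, Q=12, clusters=(tuple(range(m)),))
            region, _ = simulate_region(scn, rng=rng)
            bd = ppfc(region, default_priors)
            if bd.p_r < 0.8 or bd.p_a < 0.8:
                continue
            exact = exhaustive_posterior(region, default_priors).posterior[
                full_hypothesis(m)
            ]
            delta_r, delta_a = 1 - bd.p_r, 1 - bd.p_a
            assert abs(bd.ppfc - exact) <= delta_a**2 + delta_r * delta_a + 0.01
            checked += 1
        assert checked >= 100


class TestCorrelatedStudies:
    def test_identity_correlation_equals_independent_path(self, rng, default_priors):
        z = rng.normal(0, 1, size=(3, 5))
        z[:, 1] += 5.0
        region = make_region(z)
        corr = CorrelationModel(np.eye(3))
        bd_ind = ppfc(region, default_priors)
        bd_corr = ppfc(region, default_priors, corr)
        assert bd_corr.p_r == pytest.approx(bd_ind.p_r, abs=1e-10)
        assert bd_corr.p_a == pytest.approx(bd_ind.p_a, abs=1e-10)
        ex_ind = exhaustive_posterior(region, default_priors)
        ex_corr = exhaustive_posterior(region, default_priors, corr)
        for key, val in ex_ind.posterior.items():
            assert ex_corr.posterior[key] == pytest.approx(val, abs=1e-10)

    def test_overlap_correlation_shifts_the_posterior(self, rng, default_priors):
        z = rng.normal(0, 1, size=(2, 5))
        z[:, 2] += 5.0
        region = make_region(z)
        corr = CorrelationModel(np.array([[1.0, 0.6], [0.6, 1.0]]))
        bd = ppfc(region, default_priors, corr)
        exact = exhaustive_posterior(region, default_priors, corr)
        assert bd.ppfc == pytest.approx(
            exact.posterior[full_hypothesis(2)], abs=0.01
        )
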