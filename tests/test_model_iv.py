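"""Mutation-vector combinatorics and the Monte-Carlo pathway posterior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsforecast import model_iv as m4
from wsforecast import networks as nw

SMALL = m4.SamplingConfig(n_parameter_sets=60, seed=11)


@pytest.fixture(scope="module")
def mws_sampler():
    return m4.ModelIVSampler(nw.build_pathway("Mws"), SMALL)


@pytest.fixture(scope="module")
def aws_sampler():
    return m4.ModelIVSampler(nw.build_pathway("Aws"), SMALL)


class TestEnumeration:
    @pytest.mark.parametrize("name, total", [("Wsp", 729), ("Aws", 81), ("Mws", 27)])
    def test_all_combinations_enumerated(self, name, total):
        net = nw.build_pathway(name)
        vecs = m4.enumerate_vectors(net)
        assert len(vecs) == total
        assert len(set(vecs)) == total
        assert (0,) * net.n_mutable in vecs

    def test_printed_counterexamples_inadmissible(self, wsp):
        # r3 shares no genetic component with r5 or r6
        assert not m4.is_admissible(wsp, (0, 0, 1, 0, 1, 0))
        assert not m4.is_admissible(wsp, (0, 0, 1, 0, 0, 1))

    def test_single_component_example_admissible(self, wsp):
        # WspA spans r1 and r2
        assert m4.is_admissible(wsp, (1, -1, 0, 0, 0, 0))

    def test_baseline_vector_admissible(self, all_networks):
        for net in all_networks.values():
            assert m4.is_admissible(net, (0,) * net.n_mutable)

    @pytest.mark.parametrize("name, n_admissible", [("Wsp", 109), ("Aws", 21), ("Mws", 27)])
    def test_admissible_counts_match_brute_force(self, name, n_admissible):
        """Regression constants verified by inclusion-exclusion over the
        protein map: vectors supported within {r1-r4}, {r4-r6} or {r2,r6}
        for Wsp; {r1,r2}, {r2,r3} or {r3,r4} for Aws; everything for Mws."""
        net = nw.build_pathway(name)
        count = sum(m4.is_admissible(net, m) for m in m4.enumerate_vectors(net))
        assert count == n_admissible

    def test_admissibility_monotone_under_support_restriction(self, wsp, rng):
        vecs = m4.enumerate_vectors(wsp)
        for m in vecs:
            if not m4.is_admissible(wsp, m):
                continue
            sub = tuple(mi if rng.random() > 0.4 else 0 for mi in m)
            assert m4.is_admissible(wsp, sub)


class TestPrior:
    def test_published_example_probability(self, wsp):
        prior = m4.MutationPrior(p_e=0.01, p_d=0.02)
        expected = 0.01 * 0.02 * (1 - 0.03) ** 4
        got = m4.vector_prior((1, -1, 0, 0, 0, 0), prior, wsp)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_baseline_prior(self, wsp):
        prior = m4.MutationPrior(p_e=0.001, p_d=0.002)
        got = m4.vector_prior((0,) * 6, prior, wsp)
        assert got == pytest.approx((1 - 0.003) ** 6, rel=1e-12)

    @given(
        pe=st.floats(1e-6, 0.2),
        pd_=st.floats(1e-6, 0.2),
        k=st.floats(0.5, 3.0),
    )
    @settings(max_examples=25)
    def test_priors_sum_to_one_over_all_vectors(self, pe, pd_, k):
        net = nw.build_pathway("Aws")
        if k * (pe + pd_) >= 1:
            return
        prior = m4.MutationPrior(p_e=pe, p_d=pd_, hotspot_multipliers={"r2": k})
        total = sum(
            m4.vector_prior(m, prior, net) for m in m4.enumerate_vectors(net)
        )
        assert total == pytest.approx(1.0, rel=1e-10)

    def test_invalid_prior_rejected(self, wsp):
        with pytest.raises(ValueError, match="k\\*\\(p_e \\+ p_d\\)"):
            m4.MutationPrior(p_e=0.5, p_d=0.6).reaction_probs(wsp)


class TestConditional:
    def test_baseline_vector_never_ws(self, mws_sampler):
        p, se = mws_sampler.conditional((0, 0, 0))
        assert p == 0.0 and se == 0.0

    def test_disabling_deactivation_usually_makes_ws(self, mws_sampler):
        # crushing r2 (D* -> M) raises the active form in most parameter draws
        p, _ = mws_sampler.conditional((0, -1, 0))
        assert p > 0.5

    def test_disabling_beats_enabling_on_disabling_reaction(self, aws_sampler):
        p_dis, _ = aws_sampler.conditional((0, 0, -1, 0))
        p_en, _ = aws_sampler.conditional((0, 0, 1, 0))
        assert p_dis > p_en

    def test_wsp_demethylation_knockdown_probability(self, wsp):
        """Disabling r2 (WspF-mediated demethylation) is a strong WS route:
        it clearly dominates the enabling direction of the same reaction."""
        sampler = m4.ModelIVSampler(wsp, m4.SamplingConfig(n_parameter_sets=50, seed=5))
        p_dis, _ = sampler.conditional((0, -1, 0, 0, 0, 0))
        p_en, _ = sampler.conditional((0, 1, 0, 0, 0, 0))
        assert p_dis > 0.3
        assert p_dis > 3 * p_en

    def test_inadmissible_vector_rejected(self, wsp):
        sampler = m4.ModelIVSampler(wsp, SMALL)
        with pytest.raises(ValueError, match="not admissible"):
            sampler.conditional((0, 0, 1, 0, 1, 0))

    def test_estimates_stable_in_sample_size(self):
        """Estimates at n and 2n draws agree within 3 joint standard errors."""
        net = nw.build_pathway("Mws")
        m = (1, -1, 0)
        p1, se1 = m4.ModelIVSampler(
            net, m4.SamplingConfig(n_parameter_sets=150, seed=3)
        ).conditional(m)
        p2, se2 = m4.ModelIVSampler(
            net, m4.SamplingConfig(n_parameter_sets=300, seed=4)
        ).conditional(m)
        assert abs(p1 - p2) <= 3 * np.hypot(se1, se2) + 1e-9

    def test_bit_reproducible_with_fixed_seed(self, mws):
        cfg = m4.SamplingConfig(n_parameter_sets=30, seed=77)
        a = m4.ModelIVSampler(mws, cfg).conditional((1, 0, 0))
        b = m4.ModelIVSampler(mws, cfg).conditional((1, 0, 0))
        assert a == b


class TestPosterior:
    def test_zero_prior_gives_zero_total(self, mws_sampler):
        post = mws_sampler.posterior(m4.MutationPrior(p_e=0.0, p_d=0.0))
        assert post.total == 0.0

    def test_total_is_dot_product_of_vector_table(self, aws_sampler):
        post = aws_sampler.posterior(m4.MutationPrior(p_e=0.0001, p_d=0.001))
        brute = sum(pr * cond for _, pr, cond, _ in post.vectors)
        assert post.total == pytest.approx(brute, rel=1e-12)

    def test_contribution_shares_sum_to_one(self, aws_sampler):
        post = aws_sampler.posterior(m4.MutationPrior(p_e=0.0001, p_d=0.001))
        assert sum(post.reaction_contributions.values()) == pytest.approx(1.0)

    def test_total_nondecreasing_in_pd(self, aws_sampler):
        prior_lo = m4.MutationPrior(p_e=0.0001, p_d=0.0005)
        prior_hi = m4.MutationPrior(p_e=0.0001, p_d=0.002)
        assert (
            aws_sampler.posterior(prior_hi).total
            >= aws_sampler.posterior(prior_lo).total
        )

    def test_aws_r3_dominates_under_disabling_prior(self, aws_sampler):
        # the AwsX-AwsR inhibition is the main route when p_d >> p_e
        post = aws_sampler.posterior(m4.MutationPrior(p_e=0.0001, p_d=0.001))
        contrib = post.reaction_contributions
        assert contrib["r3"] == max(contrib.values())

    def test_hotspot_k1_identical_to_plain_posterior(self, aws_sampler):
        prior = m4.MutationPrior(p_e=0.0001, p_d=0.001)
        plain = aws_sampler.posterior(prior)
        hot = m4.hotspot_posterior(
            aws_sampler.network, prior, SMALL, k=1.0, sampler=aws_sampler
        )
        assert hot.total == pytest.approx(plain.total, rel=1e-12)

    def test_hotspot_raises_aws_total(self, aws_sampler):
        prior = m4.MutationPrior(p_e=0.0001, p_d=0.001)
        plain = aws_sampler.posterior(prior).total
        hot = m4.hotspot_posterior(
            aws_sampler.network, prior, SMALL, k=5.0, sampler=aws_sampler
        ).total
        assert hot > plain

    def test_hotspot_k_below_one_rejected(self, aws_sampler):
        prior = m4.MutationPrior(p_e=0.0001, p_d=0.001)
        with pytest.raises(ValueError, match="k must be >= 1"):
            m4.hotspot_posterior(aws_sampler.network, prior, SMALL, k=0.5)


class TestSensitivity:
    def test_regimes_preserve_pathway_ordering(self):
        """Wsp > Mws posterior ordering holds under all sampling regimes."""
        cfg = m4.SamplingConfig(n_parameter_sets=40, seed=21)
        nets = [nw.build_pathway("Wsp"), nw.build_pathway("Mws")]
        prior = m4.MutationPrior(p_e=0.0001, p_d=0.001)
        table = m4.sensitivity_suite(nets, prior, cfg)
        assert set(table["regime"]) == set(m4.SENSITIVITY_REGIMES)
        assert (table["ranking"] == "Wsp>Mws").all()
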