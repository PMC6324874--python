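"""Structure, dynamics and reaction classification of the pathway networks."""

import numpy as np
import pytest

from wsforecast import networks as nw


class TestStructure:
    @pytest.mark.parametrize(
        "name, bp, genes, n_mutable, reporter",
        [("Wsp", 8400, 7, 6, "Rp"), ("Aws", 2300, 3, 4, "RR"), ("Mws", 3900, 1, 3, "Dp")],
    )
    def test_canonical_annotation(self, name, bp, genes, n_mutable, reporter):
        net = nw.build_pathway(name)
        assert net.annotation == (bp, genes)
        assert net.n_mutable == n_mutable
        assert net.reporter == reporter

    def test_unknown_pathway_names_valid_ones(self):
        with pytest.raises(ValueError, match="Wsp.*Aws.*Mws"):
            nw.build_pathway("Pel")

    def test_mutable_reactions_contiguous_and_covered(self, all_networks):
        for net in all_networks.values():
            assert net.mutable_ids == tuple(f"r{i+1}" for i in range(net.n_mutable))
            covered = set().union(*net.protein_map.values())
            assert set(net.mutable_ids) <= covered

    def test_wsp_protein_map_matches_pathway_biology(self, wsp):
        pm = wsp.protein_map
        assert pm["WspA"] == {"r1", "r2", "r3", "r4"}
        assert pm["WspF"] == {"r2", "r6"}
        assert pm["WspE"] == {"r4", "r5", "r6"}
        assert pm["WspC"] == {"r1"}
        assert pm["WspR"] == {"r5"}
        assert pm["WspB"] == pm["WspD"] == {"r3", "r4"}

    def test_single_reporter_per_network(self, all_networks):
        for net in all_networks.values():
            assert sum(s.is_reporter for s in net.species) == 1

    def test_json_round_trip(self, aws):
        clone = nw.ReactionNetwork.from_json(aws.to_json())
        assert clone.name == aws.name
        assert clone.mutable_ids == aws.mutable_ids
        assert clone.protein_map == aws.protein_map
        assert clone.annotation == aws.annotation


class TestDynamics:
    def test_mws_steady_state_matches_closed_form(self, mws):
        # linear 2-species system: M = r3/(r1+d - r1*r2/(r2+d)), D* = r1*M/(r2+d)
        r1, r2, r3, d = 1.0, 1.0, 1.0, 1.0
        params = nw.ParameterSample(
            np.array([r1, r2, r3]), np.array([d, d]), np.array([5.0])
        )
        res = nw.integrate_to_steady_state(mws, params)
        m_exp = r3 / (r1 + d - r1 * r2 / (r2 + d))
        d_exp = r1 * m_exp / (r2 + d)
        assert res.converged
        assert res.reporter_level == pytest.approx(d_exp, rel=1e-6)
        assert res.state[0] == pytest.approx(m_exp, rel=1e-6)

    def test_mws_closed_form_holds_for_random_rates(self, mws, rng):
        for _ in range(20):
            k = 10.0 ** rng.uniform(-2, 2, size=5)
            params = nw.ParameterSample(k[:3], k[3:], np.array([rng.uniform(0, 10)]))
            res = nw.integrate_to_steady_state(mws, params)
            r1, r2, r3, dm, dd = k
            m_exp = r3 / (r1 + dm - r1 * r2 / (r2 + dd))
            d_exp = r1 * m_exp / (r2 + dd)
            assert res.converged
            # slow-rate draws stop at the steady-state criterion with a
            # truncation error up to ~1e-5 relative
            assert res.reporter_level == pytest.approx(d_exp, rel=1e-4)

    def test_zero_totals_give_zero_reporter(self, all_networks, rng):
        for net in all_networks.values():
            params = nw.sample_parameters(net, rng)
            params = nw.ParameterSample(
                params.mutable_rates, params.relaxation_rates,
                np.zeros_like(params.totals),
            )
            res = nw.integrate_to_steady_state(net, params)
            if net.name == "Mws":
                # open system: production r3 still fills the pool
                continue
            assert res.converged
            assert res.reporter_level == pytest.approx(0.0, abs=1e-9)

    def test_disabling_demethylation_raises_wsp_reporter(self, wsp, rng):
        raised = 0
        n = 20
        for _ in range(n):
            params = nw.sample_parameters(wsp, rng)
            base = nw.integrate_to_steady_state(wsp, params)
            mult = np.ones(6)
            mult[1] = 0.01  # crush r2
            mut = nw.integrate_to_steady_state(wsp, params, mult)
            if base.converged and mut.converged:
                raised += mut.reporter_level > base.reporter_level
        assert raised >= 0.9 * n

    def test_conservation_of_protein_pools(self, all_networks, rng):
        for net in all_networks.values():
            if not net.conserved_groups:
                continue
            params = nw.sample_parameters(net, rng)
            res = nw.integrate_to_steady_state(net, params)
            y0 = nw.initial_state(net, params.totals)
            for group, members in net.conserved_groups.items():
                tot0 = sum(w * y0[i] for i, w in members)
                tot_ss = sum(w * res.state[i] for i, w in members)
                assert tot_ss == pytest.approx(tot0, rel=1e-5, abs=1e-8)

    def test_states_non_negative(self, all_networks, rng):
        for net in all_networks.values():
            for _ in range(10):
                params = nw.sample_parameters(net, rng)
                res = nw.integrate_to_steady_state(net, params)
                assert np.all(res.state >= 0)

    def test_integration_deterministic(self, aws):
        params = nw.sample_parameters(aws, 42)
        r1 = nw.integrate_to_steady_state(aws, params)
        r2 = nw.integrate_to_steady_state(aws, params)
        assert np.array_equal(r1.state, r2.state)
        assert r1.t_ss == r2.t_ss

    def test_dimension_mismatch_rejected(self, aws, mws):
        params = nw.sample_parameters(mws, 0)
        with pytest.raises(ValueError, match="dimensions"):
            aws.rate_vector(params)

    def test_negative_multipliers_rejected(self, mws):
        params = nw.sample_parameters(mws, 0)
        with pytest.raises(ValueError, match="positive"):
            nw.integrate_to_steady_state(mws, params, np.array([1.0, -2.0, 1.0]))


class TestClassification:
    @pytest.mark.parametrize(
        "name, disabling, enabling",
        [
            ("Wsp", {"r2", "r6"}, {"r1", "r3", "r4", "r5"}),
            ("Aws", {"r3"}, {"r1", "r2", "r4"}),
            ("Mws", {"r2"}, {"r1", "r3"}),
        ],
    )
    def test_printed_enabling_disabling_structure(self, name, disabling, enabling):
        net = nw.build_pathway(name)
        en, dis = nw.classify_reactions(net, n_probe_samples=60, seed=7)
        assert dis == disabling
        assert en == enabling

    def test_classification_stable_across_seeds(self, mws):
        for seed in range(5):
            en, dis = nw.classify_reactions(mws, n_probe_samples=40, seed=seed)
            assert (dis, en) == ({"r2"}, {"r1", "r3"})

    def test_monotone_response_to_enabling_and_disabling_rates(self, all_networks, rng):
        """Reporter rises with enabling rates and falls with disabling ones."""
        expected = {
            "Wsp": ({"r2", "r6"}, {"r1", "r3", "r4", "r5"}),
            "Aws": ({"r3"}, {"r1", "r2", "r4"}),
            "Mws": ({"r2"}, {"r1", "r3"}),
        }
        n_draws = {"Wsp": 15, "Aws": 25, "Mws": 60}
        for net in all_networks.values():
            dis, en = expected[net.name]
            violations = 0
            checks = 0
            for _ in range(n_draws[net.name]):
                params = nw.sample_parameters(net, rng)
                base = nw.integrate_to_steady_state(net, params)
                if not base.converged:
                    continue
                for j, rid in enumerate(net.mutable_ids):
                    up = np.ones(net.n_mutable)
                    up[j] = 10.0
                    down = np.ones(net.n_mutable)
                    down[j] = 0.1
                    r_up = nw.integrate_to_steady_state(net, params, up)
                    r_down = nw.integrate_to_steady_state(net, params, down)
                    if not (r_up.converged and r_down.converged):
                        continue
                    checks += 1
                    hi, lo = r_up.reporter_level, r_down.reporter_level
                    if rid in dis:
                        hi, lo = lo, hi
                    # allow integrator-noise-scale inversions
                    if hi < lo * (1 - 1e-3) - 1e-9:
                        violations += 1
            assert checks > 0
            assert violations <= 0.02 * checks
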