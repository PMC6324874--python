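"""Synthetic generators: distributional oracles and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from wsforecast import rates as rt
from wsforecast import spectra as sp
from wsforecast import synthetic_data as syn


class TestFluctuationGenerator:
    def test_zero_rate_gives_all_zero(self):
        data = syn.simulate_fluctuation_cultures(
            syn.FluctuationSimSpec(mu=0.0, n_cultures=30, seed=1)
        )
        assert all(c == 0 for c in data.mutant_counts)

    def test_zero_fraction_matches_poisson_law(self):
        """P(no mutants) = exp(-m); at m = 0.5 about 60.7% of cultures."""
        m = 0.5
        spec = syn.FluctuationSimSpec(mu=m / (5e7 - 1e2), n_cultures=5000, seed=4)
        data = syn.simulate_fluctuation_cultures(spec)
        frac0 = np.mean(np.array(data.mutant_counts) == 0)
        p0 = np.exp(-m)
        sigma = np.sqrt(p0 * (1 - p0) / 5000)
        assert abs(frac0 - p0) < 3 * sigma

    def test_count_distribution_matches_ld_pmf(self):
        """Empirical counts at m=1 over 1e5 cultures agree with the MSS
        recursion pmf (chi-square p > 0.01)."""
        m = 1.0
        spec = syn.FluctuationSimSpec(mu=m / (5e7 - 1e2), n_cultures=100_000, seed=8)
        counts = np.array(syn.simulate_fluctuation_cultures(spec).mutant_counts)
        r_cut = 20
        observed = np.bincount(np.minimum(counts, r_cut), minlength=r_cut + 1)
        pmf = rt.ld_pmf(m, r_cut - 1)
        expected = np.append(pmf, 1.0 - pmf.sum()) * len(counts)
        stat, p = chisquare(observed, expected)
        assert p > 0.01

    def test_discrete_generation_simulator_agrees(self):
        """The per-generation cross-check simulator yields MSS estimates
        compatible with the Lea-Coulson sampler's."""
        mu = 0.5 / (5e7 - 1e2)
        a = rt.mss_mle(syn.simulate_fluctuation_cultures(
            syn.FluctuationSimSpec(mu=mu, n_cultures=300, seed=5)))
        b = rt.mss_mle(syn.simulate_fluctuation_discrete(
            syn.FluctuationSimSpec(mu=mu, n_cultures=300, seed=6)))
        z = abs(np.log(a.m_hat) - np.log(b.m_hat)) / np.hypot(
            a.sigma_ln_m, b.sigma_ln_m
        )
        assert z < 3

    def test_end_to_end_rate_recovery(self):
        mu = 6.5e-9
        data = syn.simulate_fluctuation_cultures(
            syn.FluctuationSimSpec(mu=mu, n_cultures=200, seed=12, label="Aws")
        )
        est = rt.mss_mle(data)
        assert est.mu_hat == pytest.approx(mu, rel=0.3)

    def test_regime_guard(self):
        with pytest.raises(ValueError, match="> 100"):
            syn.simulate_fluctuation_cultures(
                syn.FluctuationSimSpec(mu=1e-5, n_cultures=10, seed=0)
            )

    def test_deterministic_under_seed(self):
        spec = syn.FluctuationSimSpec(mu=1e-8, n_cultures=50, seed=99)
        assert (
            syn.simulate_fluctuation_cultures(spec).mutant_counts
            == syn.simulate_fluctuation_cultures(spec).mutant_counts
        )


class TestSpectrumGenerator:
    def _sites(self, n, hotspot_weight=None):
        rows = [("Aws", "awsX", f"s{i}", 1.0) for i in range(n)]
        if hotspot_weight:
            rows[0] = ("Aws", "awsX", "s0", hotspot_weight)
        return pd.DataFrame(rows, columns=["pathway", "gene", "mutation_id",
                                           "weight"])

    def test_single_site_takes_all(self):
        spec = syn.SpectrumSimSpec(self._sites(1), n_mutants=17, seed=0)
        out = syn.simulate_spectrum(spec)
        assert out.total == 17 and len(out.records) == 1

    def test_hotspot_expected_count(self):
        """A 10.3x hotspot among 41 sites draws 41*(10.3/50.3) ≈ 8.4 of 41
        mutants on average."""
        sites = self._sites(41, hotspot_weight=10.3)
        means = []
        for rep in range(300):
            out = syn.simulate_spectrum(
                syn.SpectrumSimSpec(sites, n_mutants=41, seed=rep)
            )
            hot = next((r.count for r in out.records if r.mutation_id == "s0"), 0)
            means.append(hot)
        expected = 41 * 10.3 / 50.3
        p = 10.3 / 50.3
        sigma = np.sqrt(41 * p * (1 - p) / 300)
        assert abs(np.mean(means) - expected) < 3 * sigma

    def test_null_calibration_of_hotspot_test(self):
        """On equal-weight spectra the resampling test rejects at most ~5%
        of the time at alpha = 0.05."""
        sites = self._sites(20)
        rejections = 0
        n_sim = 60
        for rep in range(n_sim):
            out = syn.simulate_spectrum(
                syn.SpectrumSimSpec(sites, n_mutants=40, seed=1000 + rep)
            )
            res = sp.hotspot_resampling_test(out, n_reps=2000, seed=rep,
                                             n_types=20)
            rejections += res.p_estimate < 0.05
        assert rejections <= 0.12 * n_sim  # 5% nominal + binomial slack

    def test_empty_site_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            syn.SpectrumSimSpec(self._sites(0), n_mutants=5)


class TestCompetitionGenerator:
    def test_noiseless_recovery_exact(self):
        from wsforecast.fitness import selection_coefficient

        assays = syn.simulate_competition(0.07, 8.0, 0.0, 5, seed=1)
        for a in assays:
            assert selection_coefficient(a) == pytest.approx(0.07, rel=1e-12)

    def test_neutral_mean_near_zero(self):
        from wsforecast.fitness import selection_coefficient

        assays = syn.simulate_competition(0.0, 8.0, 0.05, 200, seed=2)
        s = [selection_coefficient(a) for a in assays]
        assert abs(np.mean(s)) < 3 * 0.05 / 8.0 / np.sqrt(200)

    def test_marker_cost_shifts_apparent_s(self):
        from wsforecast.fitness import selection_coefficient

        assays = syn.simulate_competition(0.1, 8.0, 0.0, 3, seed=3,
                                          marker_cost=0.02)
        for a in assays:
            assert selection_coefficient(a) == pytest.approx(0.08, rel=1e-9)


class TestBundle:
    def test_bundle_files_and_shapes(self, tmp_path):
        paths = syn.paper_like_bundle(tmp_path, seed=0)
        assert set(paths) == {
            "fluctuation_Wsp", "fluctuation_Aws", "fluctuation_Mws",
            "spectrum", "competitions",
        }
        aws = rt.FluctuationDataset.from_tsv(paths["fluctuation_Aws"])
        assert aws.n_cultures == 200
        mws = rt.FluctuationDataset.from_tsv(paths["fluctuation_Mws"])
        assert mws.n_cultures == 400
        spectrum = sp.MutationSpectrum.from_tsv(paths["spectrum"])
        assert spectrum.total == 105

    def test_bundle_rates_near_reference(self, tmp_path):
        paths = syn.paper_like_bundle(tmp_path, seed=1)
        est = rt.mss_mle(rt.FluctuationDataset.from_tsv(paths["fluctuation_Aws"]))
        assert est.mu_hat == pytest.approx(6.5e-9, rel=0.4)

    def test_bundle_deterministic(self, tmp_path):
        p1 = syn.paper_like_bundle(tmp_path / "a", seed=7)
        p2 = syn.paper_like_bundle(tmp_path / "b", seed=7)
        assert p1["spectrum"].read_text() == p2["spectrum"].read_text()
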