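"""Synthetic panels and phenotypes with oracle-pinned signal strength."""

import numpy as np
import pytest
from scipy import stats

from cladescan.egrm import build_psi_omega, threshold_from_mu
from cladescan.hmm import decode_locus
from cladescan.panel import read_panel, write_panel
from cladescan.simulate import (
    InfeasibleSpec,
    PhenotypeSpec,
    PlantedClade,
    oracle_anova_neglog10,
    rank_match,
    select_causal_variants,
    simulate_panel,
    simulate_phenotype,
)


class TestPanelGenerator:
    def test_deterministic_given_seed(self):
        a = simulate_panel(20, 40, seed=5)
        b = simulate_panel(20, 40, seed=5)
        assert np.array_equal(a.H, b.H)
        assert np.array_equal(a.positions, b.positions)

    def test_single_founder_no_mutation_degenerates(self):
        """One founder, no mutations: all haplotypes identical, every donor
        ties at distance log(N-1), and with the canonical mu = 1e-8 the
        threshold c = 3.68 exceeds that gap, so Omega vanishes entirely."""
        panel = simulate_panel(8, 20, seed=1, n_founders=1, mutation_rate=0.0, mu=1e-8)
        assert (panel.H == panel.H[0]).all()
        dec = decode_locus(panel, 10)
        d_off = dec.d[~np.eye(16, dtype=bool)]
        assert np.allclose(d_off, np.log(15))  # fully degenerate columns
        rel, _ = build_psi_omega(dec.d, threshold_from_mu(panel.mu[10]))
        assert np.allclose(rel.Omega, 0.0)

    def test_infeasible_planted_spec_rejected(self):
        with pytest.raises(InfeasibleSpec):
            simulate_panel(
                10, 30, seed=0,
                planted=PlantedClade(haplotypes=(1, 1), focal=5, span=(0, 10)),
            )
        with pytest.raises(InfeasibleSpec):
            simulate_panel(
                10, 30, seed=0,
                planted=PlantedClade(haplotypes=(1, 2), focal=20, span=(0, 10)),
            )

    def test_population_stratification_runs(self):
        panel = simulate_panel(30, 40, seed=2, n_populations=3)
        assert panel.H.shape == (60, 40)

    def test_round_trip_through_tsv(self, tmp_path):
        panel = simulate_panel(6, 15, seed=3)
        write_panel(panel, tmp_path / "p")
        back = read_panel(tmp_path / "p")
        assert np.array_equal(panel.H, back.H)
        assert np.allclose(panel.rho, back.rho)
        assert np.allclose(panel.mu, back.mu)


class TestCausalSelection:
    def test_doubleton_class_respected(self, rng):
        panel = simulate_panel(100, 80, seed=6)
        spec = PhenotypeSpec(s=3, n_causal=2, count_class="doubleton")
        causal = select_causal_variants(panel, spec, rng)
        assert (panel.H[:, causal].sum(axis=0) == 2).all()

    def test_count_interval_class(self, rng):
        panel = simulate_panel(100, 80, seed=6)
        spec = PhenotypeSpec(s=3, n_causal=3, count_class=(20, 120))
        causal = select_causal_variants(panel, spec, rng)
        counts = panel.H[:, causal].sum(axis=0)
        assert ((counts >= 20) & (counts < 120)).all()

    def test_absent_class_raises_reject_contract(self, rng):
        panel = simulate_panel(10, 20, seed=7)
        spec = PhenotypeSpec(s=3, n_causal=5, count_class="doubleton", causal_window=(0, 3))
        with pytest.raises(InfeasibleSpec):
            select_causal_variants(panel, spec, rng)


class TestPhenotypeOracle:
    @pytest.mark.parametrize("s", [2.0, 5.0, 8.0])
    @pytest.mark.parametrize("k", [3, 9])
    def test_oracle_identity_every_replicate(self, s, k):
        """The spine of the power experiments: the oracle ANOVA -log10 p
        equals the requested signal strength to 6 decimals, replicate by
        replicate."""
        panel = simulate_panel(300, 120, seed=3)
        spec = PhenotypeSpec(s=s, n_causal=k, causal_window=(40, 80))
        for rep in range(4):
            Y, A, truth = simulate_phenotype(panel, spec, seed=1000 + rep)
            X_A = np.column_stack([panel.genotypes(v) for v in truth["causal"]])
            assert oracle_anova_neglog10(Y, A, X_A) == pytest.approx(s, abs=1e-6)

    def test_zero_strength_is_pure_null(self):
        panel = simulate_panel(200, 30, seed=4)
        Y, A, truth = simulate_phenotype(panel, PhenotypeSpec(s=0), seed=9)
        assert truth["beta"] == []
        resid = Y - A @ np.ones(2)
        assert stats.kstest(resid, "norm").pvalue > 0.01

    def test_null_covariate_model_matches_contract(self):
        """Y ~ N(a1 + a2, I): residuals off the fixed unit effects are
        standard normal across replicates."""
        panel = simulate_panel(150, 30, seed=5)
        devs = []
        for rep in range(40):
            Y, A, _ = simulate_phenotype(panel, PhenotypeSpec(s=0), seed=rep)
            devs.append(Y - A @ np.ones(2))
        devs = np.concatenate(devs)
        assert abs(devs.mean()) < 0.03
        assert devs.var() == pytest.approx(1.0, abs=0.03)

    def test_signal_split_evenly(self):
        """Every entry of R beta has the same magnitude (even splitting)."""
        panel = simulate_panel(250, 60, seed=6)
        spec = PhenotypeSpec(s=4, n_causal=5, causal_window=(10, 50))
        Y, A, truth = simulate_phenotype(panel, spec, seed=2)
        X_A = np.column_stack([panel.genotypes(v).astype(float) for v in truth["causal"]])
        Qa, _ = np.linalg.qr(A)
        Xt = X_A - Qa @ (Qa.T @ X_A)
        Xt /= np.linalg.norm(Xt, axis=0)
        Q, R = np.linalg.qr(Xt)
        rb = R @ np.asarray(truth["beta"])
        assert np.allclose(rb, rb[0])


class TestRankMatch:
    def test_gaussian_input_nearly_unchanged(self, rng):
        n = 1000
        A = rng.standard_normal((n, 2))
        Y = A @ [1.0, -0.5] + rng.standard_normal(n)
        Ym = rank_match(Y, A, rng=1)
        assert np.corrcoef(Y, Ym)[0, 1] > 0.99

    def test_monotone_transform_recovers_gaussian_residuals(self, rng):
        n = 800
        A = rng.standard_normal((n, 1))
        Y = np.exp(0.5 * (A[:, 0] + rng.standard_normal(n)))  # skewed trait
        Ym = rank_match(Y, A, rng=2)
        D = np.column_stack([np.ones(n), A])
        resid = Ym - D @ np.linalg.lstsq(D, Ym, rcond=None)[0]
        assert stats.kstest(resid / resid.std(), "norm").pvalue > 0.01

    def test_residual_variance_approaches_one(self, rng):
        n = 4000
        Y = rng.standard_exponential(n)
        Ym = rank_match(Y, None, rng=3)
        resid = Ym - Ym.mean()
        assert resid.var() == pytest.approx(1.0, abs=0.05)

    def test_null_residuals_exactly_gaussian_vector(self, rng):
        """The matched residual is a fresh Gaussian sample rearranged by the
        data's ranks — so its sorted values are exactly a sorted normal
        sample, whatever the input distribution."""
        n = 500
        Y = rng.standard_cauchy(n)  # heavy-tailed input
        Ym = rank_match(Y, None, rng=4)
        resid = np.sort(Ym - Ym.mean() + (Ym - Ym.mean()).mean())
        ref = np.sort(np.random.default_rng(4).standard_normal(n))
        # same multiset up to the mean shift from the intercept fit
        assert np.allclose(np.diff(resid), np.diff(ref), atol=1e-10)

    def test_heavy_ties_flagged(self, rng):
        Y = np.repeat([1.0, 2.0], 25)
        with pytest.warns(UserWarning, match="ties"):
            rank_match(Y, None, rng=5)

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError):
            rank_match(np.arange(5.0))
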