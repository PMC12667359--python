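"""Quadratic-form score test: statistic, traces, DCS tail, CF inversion."""

import numpy as np
import pytest
from scipy import optimize, stats

from cladescan.qform import (
    TailApprox,
    adaptive_eigendecomposition,
    background_basis,
    dcs_parameters,
    fast_traces,
    fast_traces_flop_bound,
    qform_pvalue,
    qform_test,
    satterthwaite_parameters,
    score_statistic,
)


def _dense_pop(Omega, Q):
    P = np.eye(Omega.shape[0]) - Q @ Q.T
    return P @ Omega @ P


class TestScoreStatistic:
    def test_identity_kernel_gives_projected_norm(self, rng):
        n = 30
        A = rng.standard_normal((n, 2))
        G = rng.integers(0, 3, n).astype(float)
        y = rng.standard_normal(n)
        Q = background_basis(n, A, G)
        stat = score_statistic(y, np.eye(n), A, G)
        Py = y - Q @ (Q.T @ y)
        assert stat == pytest.approx(Py @ Py, rel=1e-12)

    def test_empty_background_projector_kernel(self, rng):
        n = 25
        y = rng.standard_normal(n)
        assert score_statistic(y, np.eye(n)) == pytest.approx(y @ y, rel=1e-12)

    def test_matches_dense_evaluation(self, rng):
        n = 20
        A = rng.standard_normal((n, 3))
        G = rng.integers(0, 3, n).astype(float)
        M = rng.standard_normal((n, n))
        Omega = (M + M.T) / 2
        y = rng.standard_normal(n)
        Q = background_basis(n, A, G)
        assert score_statistic(y, Omega, A, G) == pytest.approx(
            y @ _dense_pop(Omega, Q) @ y, rel=1e-10
        )

    def test_rank_deficient_background_warns(self, rng):
        n = 30
        A = rng.standard_normal((n, 2))
        A2 = np.column_stack([A, A[:, 0]])  # duplicated column
        with pytest.warns(UserWarning, match="rank-deficient"):
            background_basis(n, A2, None)


class TestFastTraces:
    def test_identity_projector_rank(self, rng):
        n, q1 = 40, 3
        Q = np.linalg.qr(rng.standard_normal((n, q1)))[0]
        tr, hs = fast_traces(np.eye(n), Q)
        assert tr == pytest.approx(n - q1, rel=1e-10)
        assert hs == pytest.approx(n - q1, rel=1e-10)

    def test_matches_dense(self, rng):
        n = 30
        Q = np.linalg.qr(rng.standard_normal((n, 3)))[0]
        M = rng.standard_normal((n, n))
        Omega = (M + M.T) / 2
        dense = _dense_pop(Omega, Q)
        tr, hs = fast_traces(Omega, Q)
        assert tr == pytest.approx(np.trace(dense), rel=1e-10)
        assert hs == pytest.approx(np.sum(dense * dense), rel=1e-10)

    def test_annihilated_kernel(self, rng):
        n = 20
        Q = np.linalg.qr(rng.standard_normal((n, 2)))[0]
        q = Q[:, 0]
        tr, hs = fast_traces(np.outer(q, q), Q)
        assert abs(tr) < 1e-10 and abs(hs) < 1e-10

    def test_non_symmetric_rejected(self, rng):
        n = 10
        with pytest.raises(ValueError):
            fast_traces(rng.standard_normal((n, n)), np.zeros((n, 0)))

    def test_flop_count_within_reference_bound(self):
        for n, q1 in [(100, 3), (1000, 5), (5000, 11)]:
            used, bound = fast_traces_flop_bound(n, q1)
            assert used <= bound


class TestDCSParameters:
    def test_small_mean_gives_zero_shift(self):
        t = dcs_parameters(eta1=1.0, eta2=8.0, lambda_k=1.0)  # |m| <= v/2
        assert t.mu_shift == 0.0
        assert t.a + t.b == pytest.approx(4.0)
        assert t.a - t.b == pytest.approx(1.0)

    def test_psd_heavy_remainder_degenerates(self):
        # m = v: all mass in one arm plus a shift
        t = dcs_parameters(eta1=4.0, eta2=4.0, lambda_k=1.0)
        assert t.b == pytest.approx(0.0)
        assert t.mu_shift == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "eta1,eta2,lam", [(5.0, 8.0, 0.9), (-3.0, 4.0, 0.5), (10.0, 2.0, 1.1), (0.0, 6.0, 0.7)]
    )
    def test_sampled_moments_match(self, eta1, eta2, lam, rng):
        t = dcs_parameters(eta1, eta2, lam)
        n = 10**6
        draws = np.full(n, abs(lam) * t.mu_shift)
        if t.a > 0:
            draws = draws + abs(lam) * rng.chisquare(t.a, n)
        if t.b > 0:
            draws = draws - abs(lam) * rng.chisquare(t.b, n)
        assert draws.mean() == pytest.approx(eta1, abs=4 * np.sqrt(eta2 / n))
        assert draws.var() == pytest.approx(eta2, rel=0.02)

    def test_zero_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            dcs_parameters(1.0, 1.0, 0.0)

    def test_empty_remainder(self):
        assert dcs_parameters(1.0, -1e-9, 1.0).kind == "none"


class TestPvalue:
    def test_chi_square_closed_form(self, rng):
        """Full spectrum of Omega = P: the statistic is chi-square and the
        CF inversion must agree to 1e-6 relative."""
        n, q1 = 120, 3
        Q = np.linalg.qr(rng.standard_normal((n, q1)))[0]
        m = n - q1
        lam = np.ones(m)
        for p_true in (0.5, 1e-2, 1e-4, 1e-6):
            x = stats.chi2.ppf(1 - p_true, m)
            assert qform_pvalue(float(x), lam, None) == pytest.approx(p_true, rel=1e-6)

    def test_monte_carlo_agreement_indefinite(self, rng):
        """Small indefinite kernel: CF inversion within MC error."""
        n = 50
        M = rng.standard_normal((n, n))
        Omega = (M + M.T) / 2
        Q = np.linalg.qr(rng.standard_normal((n, 3)))[0]
        lam = np.linalg.eigvalsh(_dense_pop(Omega, Q))
        lam = lam[np.abs(lam) > 1e-10]
        draws = 2_000_000
        T = (rng.standard_normal((draws, lam.size)) ** 2 @ lam)
        for q in (0.99, 0.999):
            x = np.quantile(T, q)
            p_mc = (T >= x).mean()
            p_cf = qform_pvalue(float(x), lam, None)
            se = np.sqrt(p_mc * (1 - p_mc) / draws)
            assert abs(p_cf - p_mc) < 3.5 * se

    def test_dcs_conservative_where_satterthwaite_anticonservative(self):
        """Remainder with moderate arms over dust below a separated retained
        block: DCS sits at or above the exact tail where Satterthwaite
        undershoots."""
        lam = np.concatenate([np.full(5, 1.0), [0.4], np.full(194, 0.002)])
        k = 5
        lead, rest = lam[:k], lam[k:]
        e1, e2 = rest.sum(), (rest**2).sum()
        dcs = dcs_parameters(e1, e2, lam[k - 1])
        sat = satterthwaite_parameters(e1, e2)
        f = lambda x: qform_pvalue(float(x), lam, None) - 1e-6
        x = optimize.brentq(f, 1.0, 200.0, xtol=1e-9)
        p_exact = qform_pvalue(float(x), lam, None)
        assert qform_pvalue(float(x), lead, dcs) >= p_exact
        assert qform_pvalue(float(x), lead, sat) < p_exact

    def test_dcs_tail_rate_bounds_remainder(self):
        """log-survival slope of the DCS remainder is shallower (heavier)
        than the true remainder's asymptotic rate 1/(2 max_j>k |lambda_j|)."""
        rest = 0.8 ** np.arange(1, 40)
        lam_k = 1.0
        t = dcs_parameters(rest.sum(), (rest**2).sum(), lam_k)
        xs = np.array([60.0, 80.0])
        logp_dcs = np.log([qform_pvalue(float(x), np.zeros(0), t) for x in xs])
        slope_dcs = (logp_dcs[1] - logp_dcs[0]) / (xs[1] - xs[0])
        true_rate = 1.0 / (2 * np.abs(rest).max())
        assert -slope_dcs <= true_rate + 0.01

    def test_empty_everything_rejected(self):
        with pytest.raises(ValueError):
            qform_pvalue(1.0, np.zeros(0), TailApprox("none"))


class TestAdaptive:
    def _instance(self, rng, n=120, signal=0.0):
        M = rng.standard_normal((n, n))
        Omega = (M + M.T) / 2 + 0.3 * np.eye(n)
        A = rng.standard_normal((n, 2))
        G = rng.integers(0, 3, n).astype(float)
        Q = background_basis(n, A, G)
        y = rng.standard_normal(n)
        if signal:
            w = np.linalg.eigh(_dense_pop(Omega, Q))[1][:, -1]
            y = y + signal * w
        return Omega, Q, y

    def test_null_locus_early_exit(self, rng):
        Omega, Q, y = self._instance(rng)
        stat = score_statistic(y, Omega, Q=Q)
        kern = adaptive_eigendecomposition(Omega, Q, stat, p_threshold=1e-3)
        assert kern.k == 0 and len(kern.p_path) == 1

    def test_strong_signal_matches_dense(self, rng):
        Omega, Q, y = self._instance(rng, n=300, signal=8.0)
        stat = score_statistic(y, Omega, Q=Q)
        kern = adaptive_eigendecomposition(Omega, Q, stat, p_threshold=1e-3)
        assert kern.k > 0
        p_adapt = kern.p_path[-1][1]
        lam = np.linalg.eigvalsh(_dense_pop(Omega, Q))
        lam = lam[np.abs(lam) > 1e-9]
        p_dense = qform_pvalue(float(stat), lam, None)
        # the stopping rule guarantees stability between blocks (0.05 in
        # log10); closeness to the dense oracle is a little looser
        assert abs(np.log10(p_adapt) - np.log10(p_dense)) < 0.35

    def test_pvalue_path_stabilizes(self, rng):
        Omega, Q, y = self._instance(rng, n=200, signal=6.0)
        stat = score_statistic(y, Omega, Q=Q)
        kern = adaptive_eigendecomposition(Omega, Q, stat, p_threshold=0.5)
        logs = [np.log10(max(p, 1e-300)) for _, p in kern.p_path]
        assert abs(logs[-1] - logs[-2]) < 0.05

    def test_moments_exactly_in_kernel(self, rng):
        Omega, Q, y = self._instance(rng, n=80)
        kern = adaptive_eigendecomposition(Omega, Q, 1e9, p_threshold=1.1)
        lam_all = np.linalg.eigvalsh(_dense_pop(Omega, Q))
        assert kern.trace == pytest.approx(lam_all.sum(), rel=1e-8)
        assert kern.hs_sq == pytest.approx((lam_all**2).sum(), rel=1e-8)

    def test_inflation_defaults_are_identity_and_orthogonal(self):
        """The genomic-control-style triple leaves (a, b, mu) untouched,
        reduces to the plain test at its defaults, and softens p-values when
        the remainder df is inflated."""
        lead = np.array([2.0, 1.5, 1.0])
        base = dcs_parameters(4.0, 6.0, 1.0)
        p0 = qform_pvalue(18.0, lead, base)
        p_default = qform_pvalue(
            18.0, lead, dcs_parameters(4.0, 6.0, 1.0, inflation=(1.0, 0.0, 0.0))
        )
        assert p0 == pytest.approx(p_default, rel=1e-12)
        inflated = dcs_parameters(4.0, 6.0, 1.0, inflation=(1.5, 0.5, 0.5))
        assert (inflated.a, inflated.b, inflated.mu_shift) == (base.a, base.b, base.mu_shift)
        assert qform_pvalue(18.0, lead, inflated) > p0
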