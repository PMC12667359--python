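"""Generalized eGRM: regularizer, gap clustering, Psi/Omega, sprig removal."""

import numpy as np
import pytest

from cladescan.egrm import (
    build_psi_omega,
    cluster_column,
    regularizer,
    remove_sprig_structure,
    threshold_from_mu,
)
from cladescan.hmm import MAX_DISTANCE, decode_locus
from cladescan.panel import HaplotypePanel
from cladescan.sprigs import call_sprigs

from conftest import sort_split_labels


class TestRegularizer:
    def test_piecewise_values(self):
        c = 0.5
        assert regularizer(0.0, c) == 0.0
        assert regularizer(c / 2, c) == 0.0
        assert regularizer(0.7, c) == 0.7  # min(x, 1) branch
        assert regularizer(5.0, c) == 1.0
        assert regularizer(c, c) == c  # threshold itself passes

    def test_threshold_from_mutation_rate(self):
        # c = -0.2 log(mu), natural log: mu = 1e-8 -> ~3.684
        assert threshold_from_mu(1e-8) == pytest.approx(3.6841361, abs=1e-6)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            regularizer(-0.1, 0.5)
        with pytest.raises(ValueError):
            regularizer(1.0, 0.0)


class TestClusterColumn:
    def test_all_equal_one_cluster(self):
        cl = cluster_column(np.full(7, 3.3), 1.0)
        assert cl.n_clusters == 1 and (cl.labels == 0).all()

    def test_gap_rule_example(self):
        cl = cluster_column(np.array([0.0, 0.1, 5.0, 5.2]), 1.0)
        assert cl.labels.tolist() == [0, 0, 1, 1]
        assert cl.gaps.tolist() == [pytest.approx(4.9)]

    def test_exact_threshold_gap_splits(self):
        cl = cluster_column(np.array([0.0, 1.0]), 1.0)
        assert cl.n_clusters == 2  # gap >= c starts a new cluster

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_sort_then_split(self, trial, rng):
        n = int(rng.integers(2, 400))
        c = float(rng.uniform(0.2, 6.0))
        x = rng.uniform(0, min(MAX_DISTANCE, 60), size=n)
        if trial % 3 == 0:
            x = np.round(x, 1)  # ties and exact bucket-boundary cases
        cl = cluster_column(x, c)
        assert np.array_equal(cl.labels, sort_split_labels(x, c))

    def test_cluster_count_bound(self, rng):
        c = 2.0
        x = rng.uniform(0, MAX_DISTANCE, size=500)
        cl = cluster_column(x, c)
        assert cl.n_clusters <= int(np.ceil(MAX_DISTANCE / c + 1))


class TestPsiOmega:
    def test_all_gaps_below_threshold_zero_matrix(self, rng):
        d = rng.uniform(0, 0.3, size=(8, 8))
        np.fill_diagonal(d, 0.0)
        rel, _ = build_psi_omega(d, c=5.0)
        assert (rel.Omega == 0).all()

    def test_hand_worked_four_haplotypes(self):
        """N=4 (n=2) column set evaluated by hand through the definitions.

        Column 0 distances (0, 2, 2, 4) with c=1: levels {0},{1,2},{3} at
        cumulative counts 1,3; boundary gaps both 2, g(2)=1, so
        psi = 1/1 and 1/3: Psi[:,0] = (1+1/3, 1/3, 1/3, 0).
        """
        d = np.array(
            [
                [0.0, 2.0, 2.0, 4.0],
                [2.0, 0.0, 2.0, 4.0],
                [2.0, 2.0, 0.0, 4.0],
                [4.0, 4.0, 4.0, 0.0],
            ]
        )
        rel, eta = build_psi_omega(d, c=1.0, return_psi=True)
        expect_col0 = np.array([4.0 / 3, 1.0 / 3, 1.0 / 3, 0.0])
        assert np.allclose(rel.Psi[:, 0], expect_col0)
        # column 3: all donors share one level at distance 4, so only the
        # innermost boundary psi(1) = g(4)/1 = 1 exists and accrues to
        # haplotype 3 itself; every far donor gets 0
        assert np.allclose(rel.Psi[:, 3], [0.0, 0.0, 0.0, 1.0])
        B = np.kron(np.eye(2), np.ones((2, 1)))
        omega_hand = B.T @ rel.Psi @ B
        omega_hand = 0.5 * (omega_hand + omega_hand.T)
        assert np.allclose(rel.Omega, omega_hand)

    def test_outermost_level_contributes_nothing(self, rng):
        """psi_j(N) = 0: the farthest level set of every column has Psi 0."""
        d = rng.uniform(0, 20, size=(10, 10))
        np.fill_diagonal(d, 0.0)
        rel, _ = build_psi_omega(d, c=1.0, return_psi=True)
        for j in range(10):
            far = np.argmax(d[:, j])
            assert rel.Psi[far, j] == 0.0

    def test_streaming_equals_dense_collapse(self, rng):
        d = rng.uniform(0, 10, size=(12, 12))
        np.fill_diagonal(d, 0.0)
        rel, _ = build_psi_omega(d, c=0.8, return_psi=True)
        B = np.kron(np.eye(6), np.ones((2, 1)))
        dense = B.T @ rel.Psi @ B
        assert np.allclose(rel.Omega, 0.5 * (dense + dense.T))

    def test_symmetry_and_nonnegativity(self, mosaic_decoding):
        rel, _ = build_psi_omega(mosaic_decoding.d, c=1.8, return_psi=True)
        assert np.array_equal(rel.Omega, rel.Omega.T)
        assert (rel.Psi >= 0).all()

    def test_closer_donor_never_loses_psi(self):
        """Monotonicity: moving a donor into a nearer level set cannot
        decrease that donor's Psi entry."""
        base = np.array([0.0, 3.0, 6.0, 9.0, 12.0, 15.0])
        d0 = np.tile(base, (6, 1)).T
        np.fill_diagonal(d0, 0.0)
        rel0, _ = build_psi_omega(d0, c=1.0, return_psi=True)
        d1 = d0.copy()
        d1[4, 0] = 3.0  # donor 4 moves from level 4 to level 1 of column 0
        rel1, _ = build_psi_omega(d1, c=1.0, return_psi=True)
        assert rel1.Psi[4, 0] >= rel0.Psi[4, 0]

    def test_odd_haplotype_count_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            build_psi_omega(d, c=1.0)

    def test_per_level_regularizer_hook(self, rng):
        """Eq-5 generality: a custom g changes Psi as prescribed."""
        d = rng.uniform(0, 10, size=(8, 8))
        np.fill_diagonal(d, 0.0)
        rel_step, _ = build_psi_omega(d, c=1.0, g=lambda x, c: (np.asarray(x) >= c) * 2.0)
        rel_def, _ = build_psi_omega(d, c=1.0)
        assert not np.allclose(rel_step.Omega, rel_def.Omega)


class TestSprigRemoval:
    def test_no_sprigs_unchanged(self, mosaic_decoding):
        from cladescan.sprigs import SprigCalls

        rel, _ = build_psi_omega(mosaic_decoding.d, c=1.8)
        empty = SprigCalls(
            assignment=np.full(120, -1),
            X=np.zeros((60, 0), dtype=np.int8),
            flagged=np.zeros(0, dtype=bool),
        )
        rel2 = remove_sprig_structure(rel, empty)
        assert np.allclose(rel.Omega, rel2.Omega)

    def test_structure_only_panel_drops_to_background(self):
        """In a panel whose only relatedness is one planted sprig, removal
        sends within-sprig Omega entries down to the non-member level."""
        r = np.random.default_rng(3)
        N, V = 40, 60
        H = r.integers(0, 2, size=(N, V))  # unrelated haplotypes
        members = (4, 11, 26, 33)
        H[list(members)] = H[members[0]]  # identical everywhere
        H[:, 30] = 0
        H[list(members), 30] = 1  # private allele at the focal variant
        panel = HaplotypePanel(
            H=H, positions=np.arange(1, V + 1) * 10, rho=np.full(V - 1, 0.01), mu=1e-4
        )
        dec = decode_locus(panel, 30)
        c = threshold_from_mu(1e-4)
        rel, eta = build_psi_omega(dec.d, c)
        calls = call_sprigs(eta)
        got = {tuple(sorted(int(x) for x in calls.members(j))) for j in range(calls.n_sprigs)}
        assert members in got
        rel2 = remove_sprig_structure(rel, calls)
        msamp = sorted({h // 2 for h in members})
        within_pairs = [(a, b) for a in msamp for b in msamp if a < b]
        others = [
            (a, b)
            for a in range(20)
            for b in range(20)
            if a < b and a not in msamp and b not in msamp
        ]
        before = np.mean([rel.Omega[p] for p in within_pairs])
        after = np.mean([rel2.Omega[p] for p in within_pairs])
        background = np.mean([rel2.Omega[p] for p in others])
        assert before > background + 0.1  # planted structure visible
        assert abs(after - background) < 0.1  # removed down to background

    def test_non_member_columns_untouched(self, mosaic_decoding):
        rel, eta = build_psi_omega(mosaic_decoding.d, c=1.8, return_psi=True)
        calls = call_sprigs(eta)
        rel2 = remove_sprig_structure(rel, calls)
        non_members = np.flatnonzero(calls.assignment < 0)
        assert np.allclose(rel.Psi[:, non_members], rel2.Psi[:, non_members])
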