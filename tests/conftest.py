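"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cladescan.panel import HaplotypePanel


def brute_posterior(panel: HaplotypePanel, locus: int) -> np.ndarray:
    """Posterior copying probabilities by exhaustive donor-path enumeration.

    Independent of the forward/backward implementation: sums the probability
    of every donor path of the copying HMM (feasible for N <= 4, V <= 6).
    """
    H, V = panel.H, panel.n_variants
    N = H.shape[0]
    post = np.zeros((N, N))
    for j in range(N):
        donors = [i for i in range(N) if i != j]
        mass: dict[int, float] = {}
        for path in itertools.product(donors, repeat=V):
            p = 1.0 / (N - 1)
            for v in range(V):
                if v:
                    rho = panel.rho[v - 1]
                    p *= (1.0 - rho) * (path[v] == path[v - 1]) + rho / (N - 1)
                mu = panel.mu[v]
                p *= (1.0 - mu) if H[path[v], v] == H[j, v] else mu
            mass[path[locus]] = mass.get(path[locus], 0.0) + p
        total = sum(mass.values())
        for i, val in mass.items():
            post[i, j] = val / total
    return post


def brute_forward(panel: HaplotypePanel, locus: int) -> np.ndarray:
    """Unscaled forward probabilities by path enumeration up to ``locus``."""
    H = panel.H
    N = H.shape[0]
    f = np.zeros((N, N))
    for j in range(N):
        donors = [i for i in range(N) if i != j]
        for path in itertools.product(donors, repeat=locus + 1):
            p = 1.0 / (N - 1)
            for v in range(locus + 1):
                if v:
                    rho = panel.rho[v - 1]
                    p *= (1.0 - rho) * (path[v] == path[v - 1]) + rho / (N - 1)
                mu = panel.mu[v]
                p *= (1.0 - mu) if H[path[v], v] == H[j, v] else mu
            f[path[locus], j] += p
    return f


def sort_split_labels(x: np.ndarray, c: float) -> np.ndarray:
    """Reference gap clustering: sort ascending, split at gaps >= c."""
    order = np.argsort(x, kind="stable")
    labels = np.empty(len(x), dtype=int)
    cur = 0
    prev = None
    for idx in order:
        if prev is not None and x[idx] - prev >= c:
            cur += 1
        labels[idx] = cur
        prev = x[idx]
    return labels


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped so each test sees the same stream regardless of the
    # order the suite runs in
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_panel() -> HaplotypePanel:
    """4 haplotypes x 5 variants with irregular rho/mu; enumeration-sized."""
    r = np.random.default_rng(7)
    return HaplotypePanel(
        H=r.integers(0, 2, size=(4, 5)),
        positions=np.arange(1, 6) * 100,
        rho=np.array([0.3, 0.05, 0.8, 0.4]),
        mu=np.array([0.05, 0.2, 0.1, 0.3, 0.15]),
        ancestral=np.zeros(5, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def mosaic_panel():
    """Medium mosaic panel shared by sprig/eGRM/pipeline tests (n=60, V=80)."""
    from cladescan.simulate import simulate_panel

    return simulate_panel(60, 80, seed=12)


@pytest.fixture(scope="session")
def mosaic_decoding(mosaic_panel):
    from cladescan.hmm import decode_locus

    return decode_locus(mosaic_panel, 40)
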