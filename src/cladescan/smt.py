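"""Single-marker association test and the shared residual basis.

The phenotype is assumed rank-matched (unit residual variance under the
null), so the standardized coefficient of the genotype after projecting out
the background covariates is exactly standard normal under H0 and a
known-variance Gaussian test (not a t test) applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LocusRegression", "smt_test", "smt_screen"]


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


@dataclass
class LocusRegression:
    """QR basis of ``(A, G)`` and the per-phenotype single-marker p-value."""

    Q: np.ndarray
    R: np.ndarray
    p_smt: np.ndarray
    z: np.ndarray
    monomorphic: bool = False


def smt_test(Y: np.ndarray, A: np.ndarray | None, G: np.ndarray) -> LocusRegression:
    """Test one genotype vector against one or more phenotypes.

    ``p_smt`` is the two-sided Gaussian p-value of the standardized
    coefficient of ``G`` after projecting out ``A``. A monomorphic (or
    covariate-collinear) genotype yields ``p_smt = 1`` and is flagged.
    """
    Y = _as_2d(Y)
    n, T = Y.shape
    G = np.asarray(G, dtype=float).reshape(n, 1)
    A = np.zeros((n, 0)) if A is None else np.asarray(A, dtype=float)
    design = np.hstack([A, G])
    Q, R = np.linalg.qr(design)
    # residualize G against A only
    if A.shape[1]:
        Qa, _ = np.linalg.qr(A)
        g = G[:, 0] - Qa @ (Qa.T @ G[:, 0])
    else:
        g = G[:, 0].copy()
    norm = np.linalg.norm(g)
    if norm <= 1e-10 * max(1.0, np.linalg.norm(G)):
        warnings.warn("monomorphic or covariate-collinear genotype; p_SMT = 1")
        z = np.zeros(T)
        return LocusRegression(Q, R, np.ones(T), z, monomorphic=True)
    z = (g / norm) @ Y
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LocusRegression(Q, R, p, z)


def smt_screen(
    H_or_genotypes: np.ndarray,
    Y: np.ndarray,
    A: np.ndarray | None,
    *,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Genome-pass single-marker scan over every variant, vectorized.

    ``H_or_genotypes`` is either an ``(N, V)`` haplotype matrix (collapsed to
    diploid dosages) or an ``(n, V)`` genotype dosage matrix. Returns a tidy
    table (locus, position, and per-phenotype ``p_smt``/``z`` columns) used to
    pick target loci for ancestry-based testing.
    """
    M = np.asarray(H_or_genotypes, dtype=float)
    Y = _as_2d(Y)
    n, T = Y.shape
    if M.shape[0] == 2 * n:
        G = M[0::2] + M[1::2]
    elif M.shape[0] == n:
        G = M
    else:
        raise ValueError("row count matches neither haplotypes (2n) nor samples (n)")
    V = G.shape[1]
    if A is not None and A.shape[1]:
        Qa, _ = np.linalg.qr(np.asarray(A, dtype=float))
        Gr = G - Qa @ (Qa.T @ G)
        Yr = Y - Qa @ (Qa.T @ Y)
    else:
        Gr, Yr = G, Y
    norms = np.linalg.norm(Gr, axis=0)
    ok = norms > 1e-10
    Z = np.zeros((V, T))
    Z[ok] = (Gr[:, ok] / norms[ok]).T @ Yr
    P = 2.0 * stats.norm.sf(np.abs(Z))
    P[~ok] = 1.0
    out = {"locus": np.arange(V)}
    if positions is not None:
        out["position"] = np.asarray(positions)
    for t in range(T):
        suffix = "" if T == 1 else f"_{t}"
        out[f"z{suffix}"] = Z[:, t]
        out[f"p_smt{suffix}"] = P[:, t]
    return pd.DataFrame(out)
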