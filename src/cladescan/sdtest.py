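"""Stable distillation over inferred clade genotypes with a quantile filter.

One predictor is distilled at a time: the clade genotype column is
residualized against the background covariates (and every previously
distilled direction), the standardized coefficient along the resulting unit
direction gives an exact two-sided Gaussian p-value, and the direction is
then removed from the working response. Because orthogonal projections of a
spherical Gaussian are independent, the per-clade p-values are i.i.d.
uniform under the global null and the post-distillation response carries no
information about them — so anything computed on it downstream (e.g. the
quadratic-form test) is independent of the combined p-value.

The per-clade p-values are combined with a Renyi outlier test built from the
exponential-spacings representation of uniform order statistics, restricted
to the smallest ``max_outliers`` order statistics, with an optional censoring
(quantile-filter) threshold: coefficients whose p-value exceeds the
threshold are still distilled but contribute nothing to the combined
statistic. The combined statistic

    T = sum_{k <= min(K, m)} log(anchor / p_(k)),
    anchor = p_(m+1) if K > m else the censoring threshold,

where ``K`` counts uncensored p-values and ``m = min(max_outliers, p)``, is
exactly Gamma(min(K, m), 1) distributed conditional on ``K`` under the
uniform null, giving an exactly calibrated yet outlier-sensitive combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaincc

__all__ = ["SDResult", "distill", "renyi_outlier_combine", "quantile_filter_threshold"]

#: Default upper bound on the number of causal clades at one locus.
DEFAULT_C_MAX = 16


def quantile_filter_threshold(p: int, c_max: int = DEFAULT_C_MAX, prob: float = 0.01) -> float:
    """Quantile-filter threshold ``t = InverseBetaCDF(c_max, p - c_max + 1, prob)``.

    This is the ``prob`` quantile of the ``c_max``-th order statistic of
    ``p`` independent uniforms. Requires ``p >= c_max`` (shape2 >= 1).
    """
    if p < c_max:
        raise ValueError("Beta parameterization needs p >= c_max")
    return float(stats.beta.ppf(prob, c_max, p - c_max + 1))


@dataclass
class SDResult:
    """Output of one distillation pass.

    ``p_clade`` has shape ``(p, T)`` (clades x phenotypes); ``p_sd`` is the
    combined p-value per phenotype; ``Y_out`` is the post-distillation
    response, independent of ``p_sd`` under the null; ``basis`` stacks the
    distilled orthonormal directions (columns), needed to extend the
    projector of downstream tests; ``order`` is the processing order of the
    clade columns and ``skipped`` marks collinear columns that contributed
    ``p = 1`` without a direction.
    """

    p_clade: np.ndarray
    p_sd: np.ndarray
    Y_out: np.ndarray
    basis: np.ndarray
    order: np.ndarray
    skipped: np.ndarray
    t_filter: float
    c_max: int = DEFAULT_C_MAX


def renyi_outlier_combine(
    p_values: np.ndarray,
    max_outliers: int = DEFAULT_C_MAX,
    *,
    censor: float = 1.0,
) -> np.ndarray | float:
    """Combine independent uniform-null p-values, sensitive to a few outliers.

    ``p_values`` has shape ``(p,)`` or ``(p, T)``. Values ``>= censor`` are
    treated as censored (they enter only through the count of uncensored
    values); ``censor = 1`` means no censoring. Empty input or no uncensored
    value yields 1. Exactly calibrated under the uniform null conditional on
    the uncensored count; a single (uncensored) input p-value is returned
    unchanged.
    """
    P = np.asarray(p_values, dtype=float)
    scalar_in = P.ndim == 1
    if P.ndim == 1:
        P = P[:, None]
    p, T = P.shape
    if p == 0:
        out = np.ones(T)
        return float(out[0]) if scalar_in else out
    if not 0 < censor <= 1:
        raise ValueError("censor must lie in (0, 1]")
    m = min(max_outliers, p)
    S = np.sort(P, axis=0)
    K = (S < censor).sum(axis=0)  # uncensored count per phenotype
    mm = np.minimum(K, m)
    # anchor: the (m+1)-th order statistic when available uncensored, else censor
    anchor = np.full(T, censor)
    deep = K > m
    if p > m:
        anchor[deep] = S[m, deep]
    logs = np.log(np.maximum(S, np.finfo(float).tiny))
    ranks = np.arange(p)[:, None]
    use = ranks < mm[None, :]
    T_stat = (np.log(anchor)[None, :] - logs) * use
    T_stat = T_stat.sum(axis=0)
    out = np.where(mm > 0, gammaincc(np.maximum(mm, 1), np.maximum(T_stat, 0.0)), 1.0)
    return float(out[0]) if scalar_in else out


def distill(
    Y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray | None = None,
    G: np.ndarray | None = None,
    *,
    c_max: int = DEFAULT_C_MAX,
    filter_prob: float = 0.01,
) -> SDResult:
    """Distill clade genotype columns one at a time and combine their p-values.

    ``Y``: ``(n,)`` or ``(n, T)`` rank-matched response(s); ``X``: ``(n, p)``
    clade genotypes; ``A``/``G``: background covariates and the core-marker
    genotype, jointly projected out of every tested direction. Columns are
    processed in ascending allele-count then index order (the documented
    deterministic choice — under the null the order is immaterial). All steps
    are matrix-level, so ``T`` phenotypes are distilled in one pass and the
    result is columnwise identical to looping phenotypes one at a time.

    When ``p < c_max`` the Beta quantile filter is undefined (shape2 < 1);
    the combination then falls back to the unfiltered test with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, T = Y.shape
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("X rows must match phenotype length")
    p = X.shape[1]
    parts = []
    if A is not None and np.size(A):
        parts.append(np.asarray(A, dtype=float).reshape(n, -1))
    if G is not None and np.size(G):
        parts.append(np.asarray(G, dtype=float).reshape(n, -1))
    Qbg = np.linalg.qr(np.hstack(parts))[0] if parts else np.zeros((n, 0))

    if p == 0:
        return SDResult(
            p_clade=np.zeros((0, T)),
            p_sd=np.ones(T),
            Y_out=Y[:, 0] if squeeze else Y.copy(),
            basis=np.zeros((n, 0)),
            order=np.zeros(0, dtype=int),
            skipped=np.zeros(0, dtype=bool),
            t_filter=1.0,
            c_max=c_max,
        )

    if p >= c_max:
        t_filter = quantile_filter_threshold(p, c_max, filter_prob)
    else:
        warnings.warn(
            f"only {p} clades < c_max={c_max}: quantile filter undefined, "
            "falling back to the unfiltered combination"
        )
        t_filter = 1.0

    order = np.lexsort((np.arange(p), X.sum(axis=0)))
    Yw = Y.copy()
    basis = np.zeros((n, p))
    n_dir = 0
    p_clade = np.ones((p, T))
    skipped = np.zeros(p, dtype=bool)
    for j in order:
        v = X[:, j].astype(float)
        v = v - Qbg @ (Qbg.T @ v)
        if n_dir:
            U = basis[:, :n_dir]
            v = v - U @ (U.T @ v)
        norm = np.linalg.norm(v)
        if norm <= 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            skipped[j] = True  # collinear with background/previous: p = 1
            continue
        u = v / norm
        z = u @ Yw
        p_clade[j] = 2.0 * stats.norm.sf(np.abs(z))
        Yw -= np.outer(u, z)
        basis[:, n_dir] = u
        n_dir += 1
    p_sd = renyi_outlier_combine(p_clade, c_max, censor=t_filter)
    return SDResult(
        p_clade=p_clade,
        p_sd=np.atleast_1d(p_sd),
        Y_out=Yw[:, 0] if squeeze else Yw,
        basis=basis[:, :n_dir],
        order=order,
        skipped=skipped,
        t_filter=t_filter,
        c_max=c_max,
    )
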