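"""Generalized expected genetic relatedness matrix (eGRM) from asymmetric distances.

Each recipient column of the local distance matrix ``d`` is clustered into
nested level sets of donors: sorted distances are split wherever the gap to
the next value is at least ``c`` (the regularization threshold, by default
``c = -0.2 log(mu)`` with ``mu`` the copying model's mutation probability and
natural log throughout). Writing ``K_t`` for the number of donors within the
``t``-th level set boundary of column ``j`` and ``gap_t`` for the distance gap
to the next level set, the haplotype relatedness matrix is

    Psi[i, j] = sum over level-set boundaries at or beyond i's level of
                (1 / K_t) * g(gap_t),       g(x) = 0 if x < c else min(x, 1)

which is the level-set form of the per-rank sum ``Psi[i, j] =
sum_{k >= rank_j(i)} (1/k) g(d_(k+1)j - d_(k)j)`` — interior gaps are below
``c`` by construction, so only boundary gaps contribute, and the outermost
level contributes nothing (``psi_j(N) = 0``). Collapsing haplotypes to
diploid samples and symmetrising gives the sample-level relatedness

    Omega = sym(B' Psi B),    B = I_n (x) 1_2,   sym(M) = (M + M') / 2.

The innermost level set of each column is the tied-nearest-neighbour set used
for sprig calling, and the innermost boundary's contribution can be removed
for sprig-member columns so called sprigs are not double-tested in both the
clade genotypes and Omega.

The clustering is a single-pass bucket algorithm: with bucket width ``c`` no
split can occur inside a bucket and only adjacent nonempty buckets can merge,
so level sets follow from per-bucket counts/extrema in O(N) per column with
at most ``ceil(D_max / c) + 1`` preallocated buckets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import MAX_DISTANCE
from .sprigs import NeighborhoodSet, SprigCalls

__all__ = [
    "regularizer",
    "threshold_from_mu",
    "ColumnClustering",
    "cluster_column",
    "RelatednessMatrix",
    "build_psi_omega",
    "remove_sprig_structure",
]


def threshold_from_mu(mu: float) -> float:
    """Regularization threshold ``c = -0.2 log(mu)`` (natural log)."""
    if not 0 < mu < 1:
        raise ValueError("mu must lie in (0, 1)")
    return -0.2 * float(np.log(mu))


def regularizer(x: np.ndarray | float, c: float) -> np.ndarray | float:
    """Gap regularizer ``g(x) = 0 for x < c, min(x, 1) for x >= c``; ``g(0) = 0``."""
    if c <= 0:
        raise ValueError("threshold c must be positive")
    x_arr = np.asarray(x, dtype=float)
    if (x_arr < 0).any():
        raise ValueError("gaps must be nonnegative")
    out = np.where(x_arr < c, 0.0, np.minimum(x_arr, 1.0))
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


@dataclass
class ColumnClustering:
    """Level sets of one recipient column, innermost first.

    ``labels[i]`` is the level-set index of donor ``i`` (0 = innermost);
    ``sizes``, ``mins``, ``maxs`` describe the ``T`` level sets in distance
    order and ``gaps[t] = mins[t + 1] - maxs[t]`` (length ``T - 1``, each
    ``>= c``).
    """

    labels: np.ndarray
    sizes: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    c: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def gaps(self) -> np.ndarray:
        return self.mins[1:] - self.maxs[:-1]

    @property
    def cumulative(self) -> np.ndarray:
        """``K_t``: number of donors within level-set boundary ``t``."""
        return np.cumsum(self.sizes)


def cluster_column(d_col: np.ndarray, c: float) -> ColumnClustering:
    """Single-pass gap-constrained clustering of one distance column.

    Level sets are identical to the sort-then-split rule (sort ascending,
    start a new cluster whenever the gap to the previous value is >= ``c``)
    but are found without a full sort via fixed-width buckets.
    """
    x = np.asarray(d_col, dtype=float)
    if c <= 0:
        raise ValueError("threshold c must be positive")
    if (x < 0).any() or (x > MAX_DISTANCE).any():
        raise ValueError("distances must lie in [0, MAX_DISTANCE]")
    n_buckets = int(np.ceil(MAX_DISTANCE / c)) + 1
    idx = np.minimum((x / c).astype(np.int64), n_buckets - 1)
    counts = np.bincount(idx, minlength=n_buckets)
    bmin = np.full(n_buckets, np.inf)
    bmax = np.full(n_buckets, -np.inf)
    np.minimum.at(bmin, idx, x)
    np.maximum.at(bmax, idx, x)
    nonempty = np.flatnonzero(counts)
    # merge runs of adjacent nonempty buckets whose boundary gap is < c
    cluster_of_bucket = np.full(n_buckets, -1, dtype=np.int64)
    sizes: list[int] = []
    mins: list[float] = []
    maxs: list[float] = []
    for b in nonempty:
        if sizes and b - prev_b == 1 and bmin[b] - maxs[-1] < c:
            sizes[-1] += int(counts[b])
            maxs[-1] = float(bmax[b])
        else:
            sizes.append(int(counts[b]))
            mins.append(float(bmin[b]))
            maxs.append(float(bmax[b]))
        cluster_of_bucket[b] = len(sizes) - 1
        prev_b = b
    labels = cluster_of_bucket[idx]
    return ColumnClustering(
        labels=labels,
        sizes=np.asarray(sizes, dtype=np.int64),
        mins=np.asarray(mins),
        maxs=np.asarray(maxs),
        c=c,
    )


@dataclass
class RelatednessMatrix:
    """Sample-level generalized eGRM with enough by-products to edit it.

    ``Omega`` is the symmetric ``(n, n)`` matrix; ``Psi`` (haplotype level)
    is only retained when requested at build time. ``innermost`` stores, per
    recipient column, the members and psi-value of the innermost level-set
    boundary so sprig structure can be subtracted without rebuilding.
    """

    Omega: np.ndarray
    c: float
    Psi: np.ndarray | None = None
    innermost: list[tuple[np.ndarray, float]] = field(default_factory=list, repr=False)
    removed_columns: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.Omega.shape[0]


def _psi_column(cl: ColumnClustering, g=regularizer, *, drop_innermost: bool = False):
    """Per-donor Psi values of one column plus the innermost boundary term."""
    T = cl.n_clusters
    if T == 1:
        psi_levels = np.zeros(1)
    else:
        K = cl.cumulative[:-1].astype(float)
        psi_levels = np.concatenate([g(cl.gaps, cl.c) / K, [0.0]])
    inner_val = float(psi_levels[0]) if T > 1 else 0.0
    if drop_innermost and T > 1:
        psi_levels = psi_levels.copy()
        psi_levels[0] = 0.0
    # Psi value of a donor in level t is the tail sum of psi_levels from t
    tail = np.cumsum(psi_levels[::-1])[::-1]
    return tail[cl.labels], inner_val


def build_psi_omega(
    d: np.ndarray,
    c: float,
    *,
    g=regularizer,
    return_psi: bool = False,
    drop_innermost_columns: np.ndarray | None = None,
) -> tuple[RelatednessMatrix, NeighborhoodSet]:
    """Build ``Psi``/``Omega`` from a distance matrix, column-streaming.

    Also returns the innermost level set of each column as the neighbourhood
    by-product used for sprig calling. ``g`` may be any gap regularizer with
    ``g(0) = 0`` (signature ``g(gaps, c)``); the default is the thresholded
    identity above. ``drop_innermost_columns`` pre-removes the innermost
    boundary contribution of the flagged columns (used when rebuilding after
    sprig calls; normally prefer :func:`remove_sprig_structure`).
    """
    d = np.asarray(d, dtype=float)
    N = d.shape[0]
    if d.shape != (N, N):
        raise ValueError("d must be square")
    if N % 2:
        raise ValueError("number of haplotypes must be even (diploid collapse)")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("self-distances must be zero")
    n = N // 2
    asym = np.zeros((n, n))
    eta: list[np.ndarray] = []
    innermost: list[tuple[np.ndarray, float]] = []
    psi_full = np.zeros((N, N)) if return_psi else None
    drop = (
        np.zeros(N, dtype=bool)
        if drop_innermost_columns is None
        else np.asarray(drop_innermost_columns, dtype=bool)
    )
    for j in range(N):
        cl = cluster_column(d[:, j], c)
        psi_col, inner_val = _psi_column(cl, g, drop_innermost=drop[j])
        members = np.flatnonzero(cl.labels == 0)
        eta.append(members)
        innermost.append((members, inner_val))
        if psi_full is not None:
            psi_full[:, j] = psi_col
        asym[:, j // 2] += psi_col[0::2] + psi_col[1::2]
    omega = 0.5 * (asym + asym.T)
    rel = RelatednessMatrix(Omega=omega, c=c, Psi=psi_full, innermost=innermost)
    return rel, NeighborhoodSet(eta)


def remove_sprig_structure(rel: RelatednessMatrix, sprigs: SprigCalls) -> RelatednessMatrix:
    """Remove called-sprig structure from ``Omega`` before testing.

    For every sprig-member column ``j``, the contribution of the innermost
    level set (the one that defined ``j``'s neighbourhood and hence the
    sprig) is subtracted from ``Psi[:, j]``, and ``Omega`` is updated
    accordingly — called sprigs are then tested only through the clade
    genotype matrix, not twice. Non-member columns are untouched.
    """
    N = len(rel.innermost)
    if sprigs.assignment.shape[0] != N:
        raise ValueError("sprig calls do not match the relatedness matrix")
    member = sprigs.assignment >= 0
    n = rel.n_samples
    delta = np.zeros((n, n))
    psi = None if rel.Psi is None else rel.Psi.copy()
    for j in np.flatnonzero(member):
        rows, val = rel.innermost[j]
        if val == 0.0:
            continue
        contrib = np.bincount(rows // 2, minlength=n) * val
        delta[:, j // 2] += contrib
        if psi is not None:
            psi[rows, j] -= val
    omega = rel.Omega - 0.5 * (delta + delta.T)
    return RelatednessMatrix(
        Omega=omega,
        c=rel.c,
        Psi=psi,
        innermost=rel.innermost,
        removed_columns=member.copy(),
    )
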