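"""Sprig calling: tied-nearest-neighbour sets and mutual-clique clades.

A "sprig" is a very small inferred clade (typically 2-10 haplotypes) called
from the local distance matrix. Each haplotype's neighbourhood is its set of
tied nearest neighbours (itself included); haplotypes that agree on being in
each other's neighbourhood are joined by an edge, and greedily extracted
maximal cliques of that mutual-agreement graph become sprigs. Collapsing
haplotypes to diploid samples yields the clade genotype matrix ``X`` with
``X[i, j]`` = number of haplotypes of sample ``i`` assigned to sprig ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeighborhoodSet", "SprigCalls", "neighborhoods", "call_sprigs"]

#: Sprigs larger than this are still emitted but flagged (the size range is
#: descriptive of typical data, not a hard filter).
TYPICAL_MAX_SPRIG = 10


@dataclass
class NeighborhoodSet:
    """Tied-nearest-neighbour set ``eta[j]`` per haplotype ``j`` (``j`` included)."""

    eta: list[np.ndarray]

    @property
    def n_haplotypes(self) -> int:
        return len(self.eta)


@dataclass
class SprigCalls:
    """Disjoint sprig assignment and the sample-level clade genotype matrix.

    ``assignment[h]`` is the sprig id of haplotype ``h`` or -1;
    ``X`` is ``(n_samples, n_sprigs)`` with entries in {0, 1, 2};
    ``flagged`` marks sprigs larger than the typical 2-10 haplotype range.
    """

    assignment: np.ndarray
    X: np.ndarray
    flagged: np.ndarray

    @property
    def n_sprigs(self) -> int:
        return self.X.shape[1]

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == j)

    def to_triplets(self):
        """Sparse triplet (sample, sprig, dosage) representation as a DataFrame."""
        import pandas as pd

        rows, cols = np.nonzero(self.X)
        return pd.DataFrame(
            {"sample": rows, "sprig": cols, "dosage": self.X[rows, cols]}
        )


def neighborhoods(d: np.ndarray, *, atol: float = 0.0) -> NeighborhoodSet:
    """Tied-nearest-neighbour set of each recipient column of ``d``.

    ``eta[j] = {j} ∪ argmin_{i != j} d[i, j]`` with all ties included; an
    absolute tolerance ``atol`` can widen the tie band to absorb floating
    point noise in the decoded distances.
    """
    d = np.asarray(d, dtype=float)
    N = d.shape[0]
    if d.shape != (N, N):
        raise ValueError("d must be square")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("self-distances must be zero")
    eta = []
    offdiag = d + np.diag(np.full(N, np.inf))
    mins = offdiag.min(axis=0)
    for j in range(N):
        tied = np.flatnonzero(offdiag[:, j] <= mins[j] + atol)
        eta.append(np.unique(np.concatenate([[j], tied])))
    return NeighborhoodSet(eta)


def mutual_graph(eta: NeighborhoodSet) -> list[set[int]]:
    """Adjacency sets of the mutual-agreement graph (edge iff i in eta[j] and j in eta[i])."""
    N = eta.n_haplotypes
    member = [set(a.tolist()) for a in eta.eta]
    adj: list[set[int]] = [set() for _ in range(N)]
    for j in range(N):
        for i in member[j]:
            if i != j and j in member[i]:
                adj[j].add(i)
                adj[i].add(j)
    return adj


def call_sprigs(eta: NeighborhoodSet, *, n_samples: int | None = None) -> SprigCalls:
    """Greedy maximal-clique extraction over the mutual-agreement graph.

    Vertices are processed by ascending haplotype index; an unassigned seed
    grows a clique by scanning its unassigned neighbours in ascending order
    and adding each one adjacent to every current member. Accepted cliques
    (size >= 2) become disjoint sprigs; singletons are discarded (a size-1
    "clade" is just the haplotype itself). The greedy order is the
    documented deterministic tie-break.
    """
    N = eta.n_haplotypes
    if N % 2:
        raise ValueError("number of haplotypes must be even")
    if n_samples is None:
        n_samples = N // 2
    adj = mutual_graph(eta)
    assignment = np.full(N, -1, dtype=np.int64)
    cliques: list[list[int]] = []
    for seed in range(N):
        if assignment[seed] >= 0:
            continue
        clique = [seed]
        for cand in sorted(adj[seed]):
            if assignment[cand] >= 0:
                continue
            if all(cand in adj[m] for m in clique):
                clique.append(cand)
        if len(clique) >= 2:
            sid = len(cliques)
            cliques.append(sorted(clique))
            assignment[np.asarray(clique)] = sid
    X = np.zeros((n_samples, len(cliques)), dtype=np.int8)
    for sid, clique in enumerate(cliques):
        for h in clique:
            X[h // 2, sid] += 1
    flagged = np.asarray([len(c) > TYPICAL_MAX_SPRIG for c in cliques], dtype=bool)
    return SprigCalls(assignment=assignment, X=X, flagged=flagged)
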