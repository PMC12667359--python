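"""Li & Stephens haplotype-copying HMM: forward/backward decoding and distances.

Each recipient haplotype ``j`` is modelled as a mosaic of the other ``N - 1``
haplotypes. Column ``j`` of the forward matrix ``f`` (backward matrix ``b``)
is the forward (backward) state of an independent HMM whose hidden state is
the donor haplotype currently being copied. The product ``f[i, j] * b[i, j]``
is proportional to the posterior probability that recipient ``j`` copies from
donor ``i`` at the decoded variant, and the per-locus distance is

    d[i, j] = -log(max(f[i, j] b[i, j] / sum_k f[k, j] b[k, j], tiny))

with ``tiny`` the smallest positive subnormal double, so distances live in
``[0, -log(tiny)] ~ [0, 744.44]``. The ratio is invariant to any per-column
rescaling of ``f`` and ``b``, which is what permits the underflow-guarding
rescaling used below.

Transition model: with probability ``1 - rho`` the copied donor is retained
across a variant interval; with probability ``rho`` it is redrawn uniformly
from the ``N - 1`` donors. Emission: a copied allele matches the donor with
probability ``1 - mu`` and miscopies with probability ``mu`` (symmetric mode).
The ancestral-aware mode only penalises copying a *derived* recipient allele
from a donor carrying the ancestral allele; a donor's private derived allele
can be "copied over" at no cost. It is an option, not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "TINY",
    "MAX_DISTANCE",
    "ForwardState",
    "BackwardState",
    "LocusDecoding",
    "forward_init",
    "forward_step",
    "forward_to",
    "backward_init",
    "backward_step",
    "backward_to",
    "distances",
    "decode_locus",
]

#: Smallest positive (subnormal) double; the underflow clamp of the distance.
TINY: float = float(np.nextafter(0.0, 1.0))  # 4.94e-324

#: Largest attainable distance, -log(TINY) ~ 744.44.
MAX_DISTANCE: float = float(-np.log(TINY))


@dataclass
class ForwardState:
    """Forward matrix at variant ``v`` with per-column log scale factors.

    ``f[:, j]`` is the (rescaled) forward vector of recipient ``j``;
    ``f[j, j] = 0`` always. The true, unscaled forward probabilities are
    ``f[:, j] * exp(logscale[j])``.
    """

    v: int
    f: np.ndarray
    logscale: np.ndarray

    def copy(self) -> "ForwardState":
        return ForwardState(self.v, self.f.copy(), self.logscale.copy())


@dataclass
class BackwardState:
    """Backward matrix at variant ``v``; same scaling contract as the forward."""

    v: int
    b: np.ndarray
    logscale: np.ndarray

    def copy(self) -> "BackwardState":
        return BackwardState(self.v, self.b.copy(), self.logscale.copy())


@dataclass
class LocusDecoding:
    """Forward/backward matrices and the derived distance matrix at one locus."""

    locus: int
    f: np.ndarray
    b: np.ndarray
    d: np.ndarray


def _emission(panel: HaplotypePanel, v: int, ancestral_mode: bool) -> np.ndarray:
    """(N, N) emission factor: donor ``i`` (row) emitting recipient ``j``'s allele."""
    h = panel.H[:, v]
    mu = panel.mu[v]
    match = h[:, None] == h[None, :]
    if not ancestral_mode:
        return np.where(match, 1.0 - mu, mu)
    if panel.ancestral is None:
        raise ValueError("ancestral_mode requires panel.ancestral")
    derived = h != panel.ancestral[v]
    # mismatch where the recipient is derived: ordinary miscopy penalty mu;
    # mismatch where only the donor is derived: donor's private mutation,
    # copying the ancestral allele through it is not penalised.
    recip_derived = np.broadcast_to(derived[None, :], match.shape)
    out = np.where(match, 1.0 - mu, np.where(recip_derived, mu, 1.0 - mu))
    return out


def _rescale(m: np.ndarray, logscale: np.ndarray) -> None:
    """Rescale each column to unit sum in place, accumulating log factors."""
    s = m.sum(axis=0)
    ok = s > 0
    np.divide(m, np.where(ok, s, 1.0)[None, :], out=m)
    logscale += np.where(ok, np.log(np.where(ok, s, 1.0)), 0.0)


def forward_init(panel: HaplotypePanel, *, ancestral_mode: bool = False) -> ForwardState:
    """Forward state at the first variant: uniform donor prior times emission."""
    N = panel.n_haplotypes
    f = _emission(panel, 0, ancestral_mode) / (N - 1)
    np.fill_diagonal(f, 0.0)
    logscale = np.zeros(N)
    _rescale(f, logscale)
    return ForwardState(0, f, logscale)


def forward_step(
    panel: HaplotypePanel,
    f_prev: ForwardState,
    v: int,
    *,
    ancestral_mode: bool = False,
) -> ForwardState:
    """Advance the forward state from variant ``v - 1`` to ``v``.

    Per column ``j``: mix donor retention and recombination restart over the
    ``N - 1`` donors, then multiply by the emission at ``v``. Column ``j``
    never copies from itself (the diagonal stays 0).
    """
    N = panel.n_haplotypes
    if not (0 < v < panel.n_variants):
        raise ValueError(f"variant index {v} out of range (1..{panel.n_variants - 1})")
    if f_prev.v != v - 1:
        raise ValueError(f"f_prev is at variant {f_prev.v}, expected {v - 1}")
    if f_prev.f.shape != (N, N):
        raise ValueError("forward state dimension mismatch with panel")
    rho = panel.rho[v - 1]
    colsum = f_prev.f.sum(axis=0)
    f = (1.0 - rho) * f_prev.f + (rho / (N - 1)) * colsum[None, :]
    np.fill_diagonal(f, 0.0)
    f *= _emission(panel, v, ancestral_mode)
    logscale = f_prev.logscale.copy()
    _rescale(f, logscale)
    return ForwardState(v, f, logscale)


def forward_to(
    panel: HaplotypePanel,
    v: int,
    start: ForwardState | None = None,
    *,
    ancestral_mode: bool = False,
) -> ForwardState:
    """Propagate the forward recursion to variant ``v`` (from scratch or ``start``)."""
    state = forward_init(panel, ancestral_mode=ancestral_mode) if start is None else start
    while state.v < v:
        state = forward_step(panel, state, state.v + 1, ancestral_mode=ancestral_mode)
    if state.v != v:
        raise ValueError(f"start state at {state.v} is past requested variant {v}")
    return state


def backward_init(panel: HaplotypePanel) -> BackwardState:
    """Backward state at the last variant: all ones off the diagonal."""
    N = panel.n_haplotypes
    b = np.ones((N, N))
    np.fill_diagonal(b, 0.0)
    return BackwardState(panel.n_variants - 1, b, np.zeros(N))


def backward_step(
    panel: HaplotypePanel,
    b_next: BackwardState,
    v: int,
    *,
    ancestral_mode: bool = False,
) -> BackwardState:
    """Retreat the backward state from variant ``v + 1`` to ``v``.

    Mirror of :func:`forward_step`: emission at ``v + 1`` enters first, then
    the transition over the interval ``(v, v + 1)``.
    """
    N = panel.n_haplotypes
    if not (0 <= v < panel.n_variants - 1):
        raise ValueError(f"variant index {v} out of range (0..{panel.n_variants - 2})")
    if b_next.v != v + 1:
        raise ValueError(f"b_next is at variant {b_next.v}, expected {v + 1}")
    if b_next.b.shape != (N, N):
        raise ValueError("backward state dimension mismatch with panel")
    rho = panel.rho[v]
    eb = _emission(panel, v + 1, ancestral_mode) * b_next.b
    np.fill_diagonal(eb, 0.0)
    colsum = eb.sum(axis=0)
    b = (1.0 - rho) * eb + (rho / (N - 1)) * colsum[None, :]
    np.fill_diagonal(b, 0.0)
    logscale = b_next.logscale.copy()
    _rescale(b, logscale)
    return BackwardState(v, b, logscale)


def backward_to(
    panel: HaplotypePanel,
    v: int,
    start: BackwardState | None = None,
    *,
    ancestral_mode: bool = False,
) -> BackwardState:
    """Propagate the backward recursion down to variant ``v``."""
    state = backward_init(panel) if start is None else start
    while state.v > v:
        state = backward_step(panel, state, state.v - 1, ancestral_mode=ancestral_mode)
    if state.v != v:
        raise ValueError(f"start state at {state.v} is before requested variant {v}")
    return state


def distances(f: np.ndarray | ForwardState, b: np.ndarray | BackwardState) -> np.ndarray:
    """Per-locus distance matrix from matched forward/backward matrices.

    ``d[i, j] = -log(max(f[i, j] b[i, j] / sum_k f[k, j] b[k, j], TINY))`` for
    ``i != j``; the self-distance ``d[j, j]`` is 0 by convention (a haplotype
    is at distance zero from itself even though it cannot copy from itself).

    Raises if a column's products are all zero — that signals a decoding
    failure and must never turn into a silent NaN.
    """
    fm = f.f if isinstance(f, ForwardState) else np.asarray(f, dtype=float)
    bm = b.b if isinstance(b, BackwardState) else np.asarray(b, dtype=float)
    if isinstance(f, ForwardState) and isinstance(b, BackwardState) and f.v != b.v:
        raise ValueError(f"forward at variant {f.v} but backward at {b.v}")
    if fm.shape != bm.shape or fm.ndim != 2 or fm.shape[0] != fm.shape[1]:
        raise ValueError("f and b must be square matrices of equal shape")
    prod = fm * bm
    colsum = prod.sum(axis=0)
    if (colsum <= 0).any():
        bad = np.flatnonzero(colsum <= 0)
        raise FloatingPointError(
            f"all-zero forward-backward products for recipient column(s) {bad.tolist()}"
        )
    post = prod / colsum[None, :]
    d = -np.log(np.maximum(post, TINY))
    np.fill_diagonal(d, 0.0)
    return d


def decode_locus(
    panel: HaplotypePanel,
    locus: int,
    *,
    ancestral_mode: bool = False,
) -> LocusDecoding:
    """Decode a single locus from scratch (one forward + one backward pass)."""
    if not (0 <= locus < panel.n_variants):
        raise ValueError(f"locus {locus} out of range")
    fwd = forward_to(panel, locus, ancestral_mode=ancestral_mode)
    bwd = backward_to(panel, locus, ancestral_mode=ancestral_mode)
    return LocusDecoding(locus, fwd.f, bwd.b, distances(fwd, bwd))
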