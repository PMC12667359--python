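"""Optimal checkpointing for sequential reverse-order HMM decoding.

Decoding target loci in descending order needs the forward state at each
target, but the forward recursion only runs left-to-right. With a memory
budget of ``C`` stored forward states ("checkpoint slots", in addition to the
one working state, with the cost-free initial state at the origin always
available), the scheduler below minimises the total number of forward steps
needed to materialise the forward state at targets ``L, L-1, ..., 1``.

Cost model: advancing the forward state across one target interval costs 1;
the single right-to-left backward sweep is not part of the cost (backward
steps are slightly more expensive, so schedules favour re-running the forward
recursion). Target ``l`` (1-based) sits ``l - 1`` intervals from the origin,
so with no checkpoints the total cost is ``sum_{l=1}^{L} (l - 1) = L(L-1)/2``.

The dynamic program assumes evenly spaced targets, which gives the problem a
nested binomial structure: the minimal cost ``M(l, c)`` of serving ``l``
targets above a free base with ``c`` slots satisfies

    M(l, c) = min_{1 <= m <= l}  m + M(l - m, c - 1) + M(m - 1, c)

(advance ``m`` steps, drop a checkpoint there, serve the upper segment with
one slot fewer, then reuse all slots below). ``M(l, 0) = l(l+1)/2``. The row
recursion is solved with a monotone-argmin two-pointer sweep, so ``L = 1e6``
solves in seconds; a quadratic reference DP (full argmin scan) is retained
for testing. Unevenly spaced targets are mapped to their rank order, which is
optimal for even spacing and a documented approximation otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .hmm import (
    BackwardState,
    ForwardState,
    LocusDecoding,
    backward_to,
    distances,
    forward_to,
)
from .panel import HaplotypePanel

__all__ = [
    "CheckpointSchedule",
    "solve_schedule",
    "cost_table",
    "cost_table_reference",
    "iterate_targets",
]


@dataclass
class CheckpointSchedule:
    """Instruction list produced by :func:`solve_schedule`.

    ``actions`` is an ordered list of dicts with an ``op`` key:

    - ``{"op": "load", "slot": k}`` — copy slot ``k`` (or ``"origin"``) into
      the working state;
    - ``{"op": "advance", "to": p}`` — advance the working state to rank
      position ``p`` (cost ``p - current``);
    - ``{"op": "store", "slot": k}`` — store the working state into slot ``k``;
    - ``{"op": "emit", "target": p}`` — the working state is the forward state
      of the target at rank position ``p``.

    Rank positions count target intervals from the origin: the ``l``-th target
    (1-based) is at position ``l - 1`` and the origin state (position 0) is
    permanently available as slot ``"origin"``.
    """

    L: int
    C: int
    actions: list[dict] = field(repr=False)
    total_cost: int

    def validate(self) -> None:
        """Replay the actions; raise if any invariant is broken."""
        slots: dict[object, int] = {"origin": 0}
        pos: int | None = 0
        cost = 0
        emitted: list[int] = []
        for a in self.actions:
            op = a["op"]
            if op == "load":
                if a["slot"] not in slots:
                    raise ValueError(f"load from unwritten slot {a['slot']!r}")
                pos = slots[a["slot"]]
            elif op == "advance":
                if pos is None or a["to"] < pos:
                    raise ValueError("cannot advance backwards")
                cost += a["to"] - pos
                pos = a["to"]
            elif op == "store":
                if a["slot"] == "origin":
                    raise ValueError("origin slot is read-only")
                slots[a["slot"]] = pos
                live = len(slots) - 1
                if live > self.C:
                    raise ValueError(f"{live} live slots exceed budget C={self.C}")
            elif op == "free":
                slots.pop(a["slot"], None)
            elif op == "emit":
                if pos != a["target"]:
                    raise ValueError(f"emit at {pos}, expected {a['target']}")
                emitted.append(a["target"])
            else:
                raise ValueError(f"unknown op {op!r}")
        if emitted != list(range(self.L - 1, -1, -1)):
            raise ValueError("targets not emitted exactly in descending order")
        if cost != self.total_cost:
            raise ValueError(f"replayed cost {cost} != total_cost {self.total_cost}")

    def to_json(self) -> str:
        return json.dumps(
            {"L": self.L, "C": self.C, "total_cost": self.total_cost, "actions": self.actions}
        )

    @classmethod
    def from_json(cls, text: str) -> "CheckpointSchedule":
        obj = json.loads(text)
        return cls(obj["L"], obj["C"], obj["actions"], obj["total_cost"])


def cost_table_reference(l_max: int, c_max: int) -> np.ndarray:
    """Quadratic-time reference DP: full argmin scan. For testing.

    Returns ``M`` with ``M[c, l]`` the minimal cost for ``l`` targets above a
    free base with ``c`` slots.
    """
    M = np.zeros((c_max + 1, l_max + 1), dtype=np.int64)
    ls = np.arange(l_max + 1, dtype=np.int64)
    M[0] = ls * (ls + 1) // 2
    for c in range(1, c_max + 1):
        for l in range(1, l_max + 1):
            m = np.arange(1, l + 1)
            M[c, l] = np.min(m + M[c - 1, l - m] + M[c, m - 1])
    return M


def _rows(l_max: int, c_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Cost and argmin tables via the monotone two-pointer row recursion."""
    M = np.zeros((c_max + 1, l_max + 1), dtype=np.int64)
    A = np.zeros((c_max + 1, l_max + 1), dtype=np.int64)
    ls = np.arange(l_max + 1, dtype=np.int64)
    M[0] = ls * (ls + 1) // 2
    A[0] = ls  # c=0: no checkpoint is stored; argmin unused
    for c in range(1, c_max + 1):
        prev = M[c - 1]
        cur = M[c]
        arg = A[c]
        m_opt = 1
        for l in range(1, l_max + 1):
            # cost(m) = m + prev[l - m] + cur[m - 1]; argmin nondecreasing in l
            m = max(1, min(m_opt, l))
            best = m + prev[l - m] + cur[m - 1]
            # walk the pointer upward while it improves (convex in m),
            # with a 2-step lookahead guarding against flat plateaus
            while m < l:
                c1 = (m + 1) + prev[l - m - 1] + cur[m]
                if c1 < best:
                    m, best = m + 1, c1
                    continue
                if m + 2 <= l:
                    c2 = (m + 2) + prev[l - m - 2] + cur[m + 1]
                    if c2 < best:
                        m, best = m + 2, c2
                        continue
                break
            cur[l] = best
            arg[l] = m
            m_opt = m
    return M, A


def cost_table(l_max: int, c_max: int) -> np.ndarray:
    """Minimal-cost table ``M[c, l]`` (fast row recursion)."""
    return _rows(l_max, c_max)[0]


def solve_schedule(L: int, C: int) -> CheckpointSchedule:
    """Cost-minimal schedule for ``L`` evenly spaced targets and ``C`` slots.

    ``C = 0`` degenerates to restarting from the origin for every target.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if C < 0:
        raise ValueError("C must be >= 0")
    lm = L - 1  # topmost target's rank position
    M, A = _rows(lm, C)
    actions: list[dict] = []
    next_slot = [0]

    def serve(base: object, base_pos: int, l: int, c: int) -> None:
        # serve targets at positions base_pos + l .. base_pos + 1 (descending)
        while l > 0:
            if c == 0:
                for p in range(base_pos + l, base_pos, -1):
                    actions.append({"op": "load", "slot": base})
                    actions.append({"op": "advance", "to": p})
                    actions.append({"op": "emit", "target": p})
                return
            m = int(A[c][l])
            if m == l:
                # storing at the top target buys nothing; emit it directly
                actions.append({"op": "load", "slot": base})
                actions.append({"op": "advance", "to": base_pos + l})
                actions.append({"op": "emit", "target": base_pos + l})
                l -= 1
                continue
            slot = next_slot[0]
            next_slot[0] += 1
            actions.append({"op": "load", "slot": base})
            actions.append({"op": "advance", "to": base_pos + m})
            actions.append({"op": "store", "slot": slot})
            serve(slot, base_pos + m, l - m, c - 1)
            actions.append({"op": "load", "slot": slot})
            actions.append({"op": "emit", "target": base_pos + m})
            actions.append({"op": "free", "slot": slot})
            next_slot[0] -= 1
            l = m - 1

    serve("origin", 0, lm, C)
    actions.append({"op": "load", "slot": "origin"})
    actions.append({"op": "emit", "target": 0})
    sched = CheckpointSchedule(L, C, actions, int(M[C, lm]))
    return sched


def iterate_targets(
    panel: HaplotypePanel,
    targets: list[int],
    C: int,
    decode_callback: Callable[[LocusDecoding], None],
    *,
    ancestral_mode: bool = False,
    schedule: CheckpointSchedule | None = None,
) -> dict:
    """Stream decodings at ``targets`` (descending variant indices, 0-based).

    Runs one backward sweep right-to-left while re-materialising forward
    states per the checkpoint schedule; each produced :class:`LocusDecoding`
    is handed to ``decode_callback`` and then forgotten (nothing N x N is
    persisted here). The decodings are bit-identical to decoding each target
    independently from scratch.

    Returns accounting: realized forward steps in target-rank units (equals
    ``schedule.total_cost``) and in variant units (equal when targets occupy
    consecutive variants starting at 0; otherwise spacing scales them).
    """
    targets = list(targets)
    if targets != sorted(targets, reverse=True):
        raise ValueError("targets must be sorted descending")
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate targets")
    if targets and not (0 <= targets[-1] and targets[0] < panel.n_variants):
        raise ValueError("target out of range")
    asc = targets[::-1]  # rank p -> variant asc[p]
    L = len(asc)
    if L == 0:
        return {"forward_steps_rank": 0, "forward_steps_variants": 0}
    if schedule is None:
        schedule = solve_schedule(L, C)
    elif schedule.L != L:
        raise ValueError("schedule length does not match targets")

    def variant_of(rank: int) -> int:
        return asc[rank]

    # The schedule's free "origin" base is the forward state at the first
    # target (rank position 0); reaching it from the panel's first variant is
    # a fixed overhead counted only in variant units.
    origin = forward_to(panel, asc[0], ancestral_mode=ancestral_mode)
    steps_var = asc[0]
    slots: dict[object, ForwardState] = {}
    slot_rank: dict[object, int] = {}
    work: ForwardState | None = None
    work_rank: int | None = None
    bwd: BackwardState | None = None
    steps_rank = 0

    for a in schedule.actions:
        op = a["op"]
        if op == "load":
            src = origin if a["slot"] == "origin" else slots[a["slot"]]
            work = src.copy()
            work_rank = 0 if a["slot"] == "origin" else slot_rank[a["slot"]]
        elif op == "advance":
            tgt_rank = a["to"]
            tgt_var = variant_of(tgt_rank)
            steps_rank += tgt_rank - work_rank
            steps_var += tgt_var - work.v
            work = forward_to(panel, tgt_var, work, ancestral_mode=ancestral_mode)
            work_rank = tgt_rank
        elif op == "store":
            slots[a["slot"]] = work.copy()
            slot_rank[a["slot"]] = work_rank
        elif op == "free":
            slots.pop(a["slot"], None)
            slot_rank.pop(a["slot"], None)
        elif op == "emit":
            rank = a["target"]
            var = variant_of(rank)
            if work.v != var:
                raise RuntimeError(f"schedule emitted at variant {work.v}, expected {var}")
            bwd = backward_to(panel, var, bwd, ancestral_mode=ancestral_mode)
            dec = LocusDecoding(var, work.f.copy(), bwd.b.copy(), distances(work, bwd))
            try:
                decode_callback(dec)
            except Exception as err:
                raise RuntimeError(
                    f"decode callback failed at target variant {var} "
                    f"(rank {rank} of {L})"
                ) from err
    return {"forward_steps_rank": steps_rank, "forward_steps_variants": steps_var}
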