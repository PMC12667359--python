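"""Cost of decoding many target loci in reverse order under a memory budget.

The forward recursion only runs left-to-right, so serving targets
L, L-1, ..., 1 needs either enormous memory (store every state) or enormous
recomputation (restart from the origin each time). The optimal checkpoint
schedule interpolates: with C stored forward states the total forward
distance drops from ~L^2/2 to a small multiple of L.
"""

import time

from cladescan import solve_schedule
from cladescan.checkpoint import cost_table

L = 100_000
t0 = time.time()
table = cost_table(L - 1, 10)
print(f"L = {L:,} evenly spaced targets (solved in {time.time() - t0:.2f} s)\n")
print(f"{'C':>3} {'total forward steps':>20} {'multiple of L':>14}")
for C in (0, 1, 2, 4, 8, 10):
    cost = int(table[C, L - 1])
    print(f"{C:>3} {cost:>20,} {cost / L:>13.2f}x")

# a small schedule, spelled out
sched = solve_schedule(8, 2)
print(f"\nschedule for L=8, C=2 (total cost {sched.total_cost} forward steps):")
for a in sched.actions:
    print("  ", a)
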