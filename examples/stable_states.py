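"""Find the stable community types reachable from random starts.

Uses a 4-genus community engineered with two mutually exclusive blocks
({a, b} help each other, {c, d} help each other, blocks suppress each
other) and runs a census: 30 sparse random starts are each simulated until
static, and the resulting fixed points are grouped into statuses by Ward
clustering on Bray-Curtis distance.
"""

import numpy as np

from nednsim import ModelParams, census, random_compositions

genera = ("a", "b", "c", "d")
params = ModelParams(
    genera,
    alpha=np.full(4, 0.5),
    beta=np.array(
        [
            [0.0, 0.1, -2.0, -2.0],
            [0.1, 0.0, -2.0, -2.0],
            [-2.0, -2.0, 0.0, 0.1],
            [-2.0, -2.0, 0.1, 0.0],
        ]
    ),
)

starts = random_compositions(30, 4, shape=0.2, seed=30, genera=genera)
result = census(starts, params)

print(f"{result.n_statuses} stable status(es) from {len(starts)} random starts "
      f"({result.n_unresolved} unresolved)\n")
print("status  frequency  dominant  profile")
for row in result.summary_rows():
    profile = "  ".join(f"{row[g]:.4f}" for g in genera)
    print(f"{row['status']:6d}  {row['frequency']:9d}  {row['dominant_genus']:>8s}  {profile}")
print(
    "\nEach status is an attractor: whichever block dominates the sparse\n"
    "Dirichlet start wins, the other block is pinned at the 1e-6 floor, and\n"
    "the frequencies report how many random starts fell into each basin."
)
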