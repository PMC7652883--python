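"""Shift a stable community with a laxative-then-probiotic regimen.

Starting from the block-2 attractor of a two-attractor community, compares
three scenarios built from the same +5% probiotic dose of genus 'a':
dosing alone, purging alone, and purging followed by the dose on the next
day. Only the sequential regimen moves the community into the other
basin — purging to 1% of the standing mass creates the low-density window
in which the same dose, once renormalized, outweighs the incumbents.
"""

import numpy as np

from nednsim import (
    Composition,
    InterventionAction,
    InterventionSchedule,
    ModelParams,
    run_to_stability,
    simulate_scenario,
)

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

# settle into the block-2 attractor (c/d dominant) first
x0 = Composition(genera, np.array([0.05, 0.05, 0.45, 0.45]))
stable, _ = run_to_stability(x0, params)
print("starting attractor:", np.round(stable.values, 6))

scenarios = {
    "single +5% dose of 'a' at day 50":
        InterventionSchedule.single_dose("a", 0.05, day=50),
    "laxative (1% retention) at day 50":
        InterventionSchedule.from_records(
            [{"day": 50, "kind": "laxative", "magnitude": 0.01}]
        ),
    "laxative day 50, then +5% 'a' at day 51":
        InterventionSchedule((
            InterventionAction(50, "laxative", 0.01),
            InterventionAction(51, "probiotic", 0.05, "a"),
        )),
}

print(f"\n{'scenario':42s}  outcome (final stable state)")
for name, sched in scenarios.items():
    result = simulate_scenario(stable, params, sched)
    final = result.stable_state
    dom = final.genera[int(np.argmax(final.values))]
    shifted = "SHIFTED" if dom in ("a", "b") else "returned"
    print(f"{name:42s}  {dom}-dominant ({shifted}), {np.round(final.values, 4)}")

print(
    "\nAgainst the full-density community the +5% dose is a small minority\n"
    "after renormalization and is competed back out, and the purge alone just\n"
    "regrows the old attractor; but dosed into the post-purge community\n"
    "(total mass 1%) the same 0.05 increment dominates the renormalized\n"
    "composition and flips the system into the a/b basin."
)
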