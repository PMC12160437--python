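"""Simulate one paired trajectory for each movement scenario.

Two individuals move by biased correlated random walk in a 100 x 100 arena:
A.a / A.b climb a habitat-quality gradient (side by side / from opposite
sides), B forages in a patchy Perlin landscape, C avoids barriers in a
homogeneous matrix, D is mutual attraction with no landscape effect.
"""

import numpy as np

from dyadmove import ScenarioConfig, simulate_pair

for scenario in ["A.a", "A.b", "B", "C", "D"]:
    cfg = ScenarioConfig(scenario=scenario, seed=1, barrier_proportion=0.3 if scenario == "C" else 0.0)
    sim = simulate_pair(cfg)
    a, b = sim.traj_a, sim.traj_b
    dist = np.hypot(a.x - b.x, a.y - b.y)
    print(
        f"{scenario}: {a.n_fixes} fixes each | mean step {a.step_lengths.mean():.2f} | "
        f"pair distance start {dist[0]:.1f} -> end {dist[-1]:.1f}"
    )

print()
print("Mean step length ~ 0.9 = gamma shape 6 x scale 0.15; the pair distance")
print("shrinks under mutual attraction (D) and when both individuals converge")
print("on the same resource (A.b, B), although no interaction was simulated there.")
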