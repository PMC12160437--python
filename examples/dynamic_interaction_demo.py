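"""Dynamic interaction index on an interacting and a non-interacting pair.

DI multiplies a direction-cohesion term cos(theta1 - theta2) with a
displacement-similarity term 1 - |d1-d2|/(d1+d2), averaged over
simultaneous steps; the p-value comes from circularly time-shifting one
track's step series (which keeps each track's autocorrelation but destroys
simultaneity).
"""

from dyadmove import DIConfig, ScenarioConfig, di_index, simulate_crw_pair, simulate_pair

attracted = simulate_pair(ScenarioConfig(scenario="D", seed=4))
independent = simulate_crw_pair(seed=4)

for name, sim in [("mutual attraction (D)", attracted), ("independent CRWs", independent)]:
    res = di_index(sim.traj_a, sim.traj_b, DIConfig(n_permutations=999))
    print(
        f"{name}: DI = {res.di:+.3f} (direction {res.di_theta:+.3f}, "
        f"displacement {res.di_d:.3f}), permutation p = {res.p_value:.3f}"
    )

print()
print("The attracted pair shows positive movement cohesion with a small p-value;")
print("the independent pair's DI is near zero and non-significant.")
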