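# dyadmove

Movement ecologists increasingly infer *inter-individual interactions* —
attraction, avoidance, cohesive travel — from simultaneous GPS tracks of
two animals.  But two trajectories can correlate for a much more mundane
reason: both animals respond to the same landscape (a resource gradient, a
patchy habitat, barriers that channel movement).  `dyadmove` is a
simulation-and-inference framework for studying exactly this confounding.
It simulates pairs of individuals under scenarios where the truth is known
(landscape-driven correlation vs. genuine mutual attraction), applies the
standard inference methods, and measures how often each method gets the
answer right.

Three inference methods are implemented:

* **DI** — the dynamic interaction index,
  `DI = mean_t[ cos(θ₁ₜ − θ₂ₜ) · (1 − |d₁ₜ − d₂ₜ|/(d₁ₜ + d₂ₜ)) ]`,
  with a circular time-shift permutation test;
* **SSF-OD** — a step-selection function (conditional logistic regression
  of used vs. 20 available steps) with the partner's occurrence
  distribution as covariate;
* **SSF-DIST** — the same SSF with the (negated) distance to the partner,
  so a positive coefficient β means attraction.

For the SSFs three model structures are compared: *Full* (interaction +
landscape covariates), *Individual* (interaction only — the situation with
no environmental data), and *Spatial+* — a correction for spatial
confounding that first regresses the interaction covariate on a penalised
thin-plate spline of the coordinates (100 knots) and then fits the SSF
with the residuals plus a spatial smooth, testing the residual
coefficient.

The simulator is an agent-based biased correlated random walk (von Mises
turning angles, κ = 4; gamma step lengths, shape 6, scale 0.15) in five
scenarios: parallel gradient climbing (A.a), convergence on a central
resource (A.b), foraging in a patchy Perlin landscape (B), barrier
avoidance in a fragmented matrix (C, with a sweep of barrier proportions),
and true mutual attraction (D).  See `docs/methods.md` for the model, all
defaults, and known limitations.

## Worked example

```python
from dyadmove import DIConfig, ScenarioConfig, di_index, simulate_crw_pair, simulate_pair

attracted   = simulate_pair(ScenarioConfig(scenario="D", seed=4))   # mutual attraction
independent = simulate_crw_pair(seed=4)                             # no interaction

for name, sim in [("attracted", attracted), ("independent", independent)]:
    r = di_index(sim.traj_a, sim.traj_b, DIConfig(n_permutations=999))
    print(name, f"DI={r.di:+.3f}", f"p={r.p_value:.3f}")
```

prints

```
attracted   DI=+0.149 p=0.001
independent DI=-0.033 p=0.771
```

the attracted pair shows significant movement cohesion (positive DI, small
permutation p), the independent pair does not.  The confounding problem in
one picture — the same SSF-DIST fit on a truly interacting pair (D) and on
a pair that merely climbs the same gradient (A.a):

```
D:   dist coefficient +2.144 (SE 0.104), p = 1.5e-94   # true attraction
A.a: dist coefficient +3.311 (SE 1.565), p = 0.034     # false positive
```

Both are "significant attraction", but in A.a no interaction was
simulated; applying the Spatial+ correction removes the spurious effect
(see `examples/spatial_plus_demo.py`).  Each script in `examples/` is a
short narrative of one capability: scenario simulation, DI, SSF fitting,
Spatial+, and the evaluation harness.

A thin command line mirrors the library:

```sh
dyadmove simulate --scenario D --steps 1000 --seed 7 --out pair.csv
dyadmove di --traj-a a.csv --traj-b b.csv
dyadmove evaluate --scenario C --seed 1 --out results/
```

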