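"""Step-selection inference of inter-individual interaction.

Builds strata (each observed step plus 20 available steps drawn from the
fitted gamma / von Mises movement kernel), attaches the distance-to-partner
covariate (negated so a positive coefficient means attraction), and fits
the conditional logistic regression for a genuinely interacting pair
(scenario D) and for a pair that merely shares a habitat gradient (A.a).
"""

from dyadmove import ScenarioConfig, simulate_pair
from dyadmove.evaluation import build_strata
from dyadmove.ssf import fit_ssf

for scenario in ["D", "A.a"]:
    sim = simulate_pair(ScenarioConfig(scenario=scenario, seed=2))
    strata, _ = build_strata(sim)
    fit = fit_ssf(strata, ["dist"])
    print(
        f"{scenario}: dist coefficient {fit.coefficients['dist']:+.3f} "
        f"(SE {fit.std_errors['dist']:.3f}), p = {fit.p_values['dist']:.2e}, "
        f"{fit.n_strata} strata"
    )

print()
print("Scenario D shows strong true attraction. In A.a no interaction was")
print("simulated: any significant coefficient is a false positive created by")
print("both individuals following the same resource gradient.")
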