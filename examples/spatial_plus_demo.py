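"""Spatial+ correction of a spatially confounded step-selection estimate.

In scenario B both individuals independently climb the same patchy
landscape, so the distance-to-partner covariate is spatially confounded and
the naive ("Individual") SSF tends to infer spurious attraction.  Spatial+
first regresses the covariate on a penalised thin-plate spline of the
candidate coordinates (100 knots), then fits the SSF with the residuals
plus a spatial smooth; the residual coefficient is the corrected
interaction estimate.
"""

from dyadmove import ScenarioConfig, simulate_pair
from dyadmove.evaluation import build_strata
from dyadmove.spatial_plus import fit_spatial_plus_ssf
from dyadmove.ssf import fit_ssf

sim = simulate_pair(ScenarioConfig(scenario="B", seed=903))
strata, _ = build_strata(sim)

individual = fit_ssf(strata, ["dist"])
corrected = fit_spatial_plus_ssf(strata, "dist")

print(f"Individual model: dist z = {individual.z_values['dist']:+.2f}, p = {individual.p_values['dist']:.2e}")
print(
    f"Spatial+ model:  residual z = {corrected.z_values['dist_residual']:+.2f}, "
    f"p = {corrected.p_values['dist_residual']:.3f}"
)
print()
print("The spurious attraction (large positive z) disappears once the spatial")
print("dependence of the covariate is partialled out; no interaction was simulated.")
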