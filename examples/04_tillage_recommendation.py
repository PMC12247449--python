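"""Environment-specific tillage recommendation and its benefit.

Compares the actual run with no-till (NT) and conventional-till (CT)
counterfactuals, maps where each practice reduces GHGI sensitivity in
>75% of moving windows, and quantifies the sensitivity reduction the
recommended scheme achieves.
"""

import numpy as np

import edhwheat as e
from edhwheat.pipeline import sensitivity_suite

cfg = e.SyntheticConfig(n_lat=8, n_lon=8, seed=11)
cfg.tillage_effect_regions = {
    "NT": e.TillageRegion(5, 8, 0, 8, beta_scale=0.3),  # NT buffers the north
    "CT": e.TillageRegion(0, 3, 0, 8, beta_scale=0.3),  # CT buffers the south
}
_, edh, suite = e.generate_scenario_suite(cfg, scenarios=("S2", "S12", "S13"))
fields = sensitivity_suite(edh, suite)
actual, nt, ct = (fields[(s, "ghgi", "pearson")] for s in ("S2", "S12", "S13"))

rec = e.recommendation_map(actual, nt, ct, variable="GHGI", threshold=0.75)
cons = rec["recommendation_consensus"].values
print("consensus recommendation map (rows south -> north):")
for i in range(cfg.n_lat - 1, -1, -1):
    print("   " + " ".join(f"{c:>4s}" for c in cons[i]))
counts = {lab: int((cons == lab).sum()) for lab in ("NT", "CT", "none")}
print(f"\ncells recommended: {counts}")

optimal = e.apply_recommendation(actual, nt, ct, rec)
red = e.sensitivity_reduction(actual, optimal, cons != "none")
print(f"GHGI dry-heat sensitivity reduction in recommended cells: "
      f"{red['mean']:.1f}% (range {red['range'][0]:.1f}-{red['range'][1]:.1f}% "
      f"across HC/DC/CDHC)")
print("The map recovers the two injected benefit bands; cells outside them")
print("stay unmanaged because their tillage runs equal the actual run.")
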