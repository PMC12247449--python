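"""Moving-window sensitivity of GHG intensity to dry-heat indices.

Computes 20-year moving-window correlations between the annual EDH indices
and GHGI on a small grid, summarizes them regionally, and tests for a
temporal trend in the regional median sensitivity.
"""

import numpy as np

import edhwheat as e

cfg = e.SyntheticConfig(n_lat=6, n_lon=6, seed=3)
_, edh, suite = e.generate_scenario_suite(cfg, scenarios=("S2",))
ghgi = e.ghg_bundle(suite["S2"])["ghgi"].rename("ghgi")

field = e.sensitivity_field(edh, ghgi, window=20, method="pearson")
summary = e.regional_summary(field)

print("20-year moving-window Pearson R between GHGI and each EDH index")
print(f"({field.sizes['window_end_year']} windows ending "
      f"{int(field['window_end_year'][0])}-{int(field['window_end_year'][-1])}):\n")
for key in ("hc", "dc", "cdhc"):
    med = summary[f"r_{key}_median"].values
    pos = summary[f"r_{key}_pos_share"].values
    mk = e.mann_kendall_trend(med)
    print(f"  {key.upper():5s} median R first/last window: "
          f"{med[0]:+.2f} / {med[-1]:+.2f};  area with R>0: {100*pos[-1]:.0f}%;"
          f"  trend p = {mk['p_value']:.3f}")

print("\nPositive R means dry-heat years raise emission intensity: the")
print("injected couplings make GHGI rise (emissions up, yield down) with")
print("every extreme day, which the windowed correlations recover.")
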