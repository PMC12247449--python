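"""Count extreme dry-heat days for one synthetic growing region.

Builds a small daily climate grid, computes the annual heat (HC), dry (DC)
and compound dry-heat (CDHC) day counts over the Mar 1 - Sep 30 window,
and prints the regional means and the drying trend.
"""

import numpy as np

import edhwheat as e

cfg = e.SyntheticConfig(n_lat=6, n_lon=6, seed=42)
climate = e.generate_daily_climate(cfg)
edh = e.compute_edh_field(climate)

print("annual day counts over Mar 1 - Sep 30 (214-day window), 6x6 grid:")
for key, label in [("hc", "heat days  (Tmax > 30 degC)"),
                   ("dc", "dry days   (AI < 0.2)"),
                   ("cdhc", "compound dry-heat days")]:
    vals = edh[key].values
    print(f"  {label}: mean {vals.mean():6.1f}  min {vals.min():3d}  max {vals.max():3d}")

# regional drying: Mann-Kendall on the regional-mean dry-day series
dc_series = edh["dc"].values.reshape(-1, cfg.years.size).mean(axis=0)
mk = e.mann_kendall_trend(dc_series)
print(f"\nregional dry-day trend: {mk['slope']*10:+.2f} days/decade "
      f"(Mann-Kendall p = {mk['p_value']:.2e})")
print("A positive trend means the growing season is drying, so compound")
print("dry-heat exposure rises even where heat days alone are stable.")
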