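# edhwheat

Analysis pipeline for how extreme dry-heat (EDH) climate affects the
greenhouse-gas emission intensity of wheat agroecosystems: annual EDH
day-count indices from daily climate, CO₂-equivalent GHG accounting,
moving-window climate-sensitivity analysis, factorial driver attribution,
and an environment-specific tillage recommendation scheme — exercised
end-to-end on synthetic gridded data whose dry-heat couplings are injected
with known sign and magnitude, so every stage has a ground-truth recovery
test.

It is written for agroecosystem modellers and climate-impact analysts who
have gridded daily climate (Tmax, Tmin, precipitation) and annual
process-model outputs (yield, CO₂/N₂O/CH₄ fluxes per management scenario),
and want the full index → intensity → sensitivity → recommendation chain as
a tested, reusable library.

## The method

**EDH indices** (Mar 1 – Sep 30, N = 214 days in every year):

- HC = Σᵢ 1[Tmaxᵢ > 30 °C] — heat-day count,
- DC = Σᵢ 1[AIᵢ < 0.2] — dry-day count, where AI = P/ETp is the daily
  aridity index, ETp the Hargreaves potential evapotranspiration
  ETp = 0.0023 · 0.408·Ra · (Tmax−Tmin)^0.5 · (T + 17.8),
  and Ra = (S₀/π)(r₀/r)²[H sinφ sinδ + sinH cosφ cosδ] the
  extraterrestrial radiation (S₀ = 118.02 MJ m⁻² d⁻¹, FAO-56 geometry),
- CDHC = count of simultaneously hot *and* dry days (CDHC ≤ min(HC, DC)).

**GHG intensity** with 100-yr global-warming potentials (N₂O = 273,
CH₄ = 27):
ECO₂ = F_CO₂·44/12, EN₂O = F_N₂O·44/28·273, ECH₄ = F_CH₄·16/12·27,
EGHG = ECO₂ + EN₂O + ECH₄, GHGI = EGHG/Y.

**Sensitivity** is the Pearson (optionally Kendall/Spearman) correlation R
between an EDH index and a response (yield, EGHG, GHGI) in 20-year moving
windows after full-period linear detrending; per-grid trends use OLS with a
two-sided t-test, regional trends the Mann–Kendall test; uncertainty across
dataset × method combinations is SE = s/√n.

**Tillage scheme**: per cell and window, D = R_tillage − R_actual is a
positive effect (PE) when it strengthens the yield coupling (D > 0) or
weakens the GHG/GHGI coupling (D < 0). A practice is recommended where its
PE frequency across windows strictly exceeds 75%; applying the recommended
map yields the reduction in regional median sensitivity.

**Attribution**: the contribution of a driver is the all-drivers run minus
the paired run with that driver held constant; land-use change is isolated
by a management-frozen pair.

## Worked example

```bash
python examples/04_tillage_recommendation.py
```

prints (8×8 grid, 59 years, NT benefit injected in the northern band and CT
in the southern band):

```
cells recommended: {'NT': 24, 'CT': 24, 'none': 16}
GHGI dry-heat sensitivity reduction in recommended cells: 33.4% (range 31.6-35.2% across HC/DC/CDHC)
```

All 24 + 24 cells of the two injected benefit bands are recovered and no
cell outside them is recommended; applying the recommended practices cuts
the median GHGI–EDH correlation in those cells by about a third. The other
examples (`01_edh_indices.py`, `02_ghg_accounting.py`, `03_sensitivity.py`)
walk the earlier stages with the same printed-number style.

The full pipeline is also available from the shell:

```bash
edhwheat run-all --config examples/demo_config.yaml --outdir out/
```

which writes every stage (climate, indices, scenarios, sensitivities,
recommendation map, attribution table) as NetCDF/CSV; rerunning with the
same config and seed reproduces the files byte-for-byte.

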