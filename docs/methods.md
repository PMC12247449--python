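# Methods

## Scope and data model

The package implements the analysis layer that sits on top of a
process-based agroecosystem model: it consumes daily gridded climate and
annual scenario outputs and produces extreme dry-heat (EDH) indices,
CO₂-equivalent emission intensities, moving-window sensitivities, driver
attributions, and tillage recommendations. The process model itself is out
of scope; its factorial experiment suite is *emulated* by the synthetic
generator so that every downstream stage can be tested against known
injected truth.

Gridded data live in xarray Datasets (dims `lat, lon, time|year|
window_end_year`), are computed in float64 and stored as float32 NetCDF3
(scipy backend). All files carry the configuration digest and seed; no
timestamps are written, so identical runs are byte-identical.

## EDH indices

HC, DC and CDHC count days in the fixed Mar 1 – Sep 30 window (214 days,
leap-invariant since February is excluded) using strict inequalities:
Tmax > 30 °C for heat, AI < 0.2 for dryness, both for the compound count.
No lag or cascading logic links consecutive days. Missing days in a window
are an error, never imputed.

The aridity index is the daily ratio P/ETp. ETp uses the Hargreaves model
with extraterrestrial radiation from FAO-56 solar geometry
(δ = 0.409 sin(2πJ/365 − 1.39), (r₀/r)² = 1 + 0.033 cos(2πJ/365),
H = arccos(clamp(−tanφ tanδ))); the sunset-hour-angle clamp makes Ra = 0
under polar night. ETp is floored at zero (negative values would require a
mean temperature below −17.8 °C). Days with ETp ≤ 10⁻⁶ mm have an
*undefined* AI and never count as dry: a frozen or dark day without
evaporative demand is not meteorological drought. Though some conventions
quote P and ETp in annual units, the ratio is formed daily from mm/day
quantities; the 0.2 threshold is scale-free either way.

## GHG accounting

The converters are unit-agnostic linear maps with AR6 100-yr GWPs
(N₂O = 273, CH₄ = 27) and molar conversions from elemental mass
(44/12, 44/28, 16/12). Positive F_CO₂ is net carbon release (SOC loss);
sequestration is negative, and a negative GHGI is a meaningful net-sink
intensity. GHGI masks cells with yield ≤ 1 kg/ha (NaN) instead of letting
near-crop-failure years blow up the ratio; masked cell-years propagate as
missing through every window that touches them. Regional totals weight
cells by spherical cell area times an optional wheat-fraction layer
(default 1 on synthetic grids).

Attribution assumes additive, non-interacting drivers, as the
all-drivers-minus-one design implicitly does; interactions would land in
the S2−S1 residual and be reported as such. On the synthetic suite the
closure Σ(S2−Sᵢ) = S2−S1 is exact by construction.

## Sensitivity analysis

Both the index and the response are linearly detrended over the **full**
period once, then correlated in 20-year trailing windows labelled by their
final year (a 59-year record gives 40 windows). Per-window detrending is
available as an option for comparison. Windows with zero variance or any
missing value in either series give a missing R and are excluded from
medians and area shares. The default method is Pearson; Kendall and
Spearman are available for the dataset × method uncertainty design, whose
spread is summarized as SE = s/√n with s the ddof-1 standard deviation.

Grid-cell trends in R use OLS on window end-year with a two-sided t-test at
α = 0.05; a constant series is reported as slope 0 with p = 1. Regional
trends use the Mann–Kendall test: S = Σ_{i<j} sign(xⱼ−xᵢ), tie-corrected
variance (n(n−1)(2n+5) − Σt(t−1)(2t+5))/18, ±1 continuity correction, and a
normal approximation; the reported slope is the Theil–Sen median of
pairwise slopes. No multiple-testing correction is applied across grid
cells — a documented caveat, as the per-cell maps are descriptive.

## Tillage scheme

For each cell, window and EDH index, D = R_tillage − R_actual is classified
PE/NE by the sign rules (yield: D>0 → PE; GHG and GHGI: D>0 → NE). Exact
zeros are *neutral* and excluded from both numerator and denominator of the
positive-effect frequency, since the sign rules define labels only for
strict inequalities. A practice qualifies where its PE frequency strictly
exceeds 0.75; when both qualify, the higher frequency wins with exact ties
broken toward no-till (the lower-disturbance practice; configurable). The
decision variable defaults to GHGI, the mitigation target; yield and GHG
maps are produced as diagnostics. Per-index maps are complemented by a
consensus map (majority across HC/DC/CDHC, `none` when all three disagree),
which is the map the scheme implements.

The sensitivity-reduction statistic is a reconstruction — no canonical
formula exists for it: per window, the spatial median of R over recommended
cells under the actual and the recommended fields; the relative change
100·(med_actual − med_optimal)/|med_actual| is averaged over windows, and
the range is taken across the three indices. Windows whose actual median is
within 10⁻⁶ of zero are undefined and skipped.

## Synthetic generator

The generator emulates six decades (1960–2018) of a mid-latitude wheat
belt on a 20×20 grid:

- **Temperature**: latitude-graded mean (−0.5 °C per degree north around a
  24 °C base Tmax), a 12 °C sinusoidal seasonal cycle peaking in mid-July,
  a 0.3 °C/decade warming trend stepped by calendar year (so annual means
  are exactly linear in year), iid daily Gaussian noise (σ = 2.5 °C), and
  Tmin = Tmax − |N(10, 2²)| so the physical ordering holds by construction.
- **Precipitation**: a mixed Bernoulli/Gamma process; dry-day probability
  0.55 drifting by +0.02/decade (the drying trend), wet-day amounts
  Gamma(0.8, scale chosen to hit a 2.5 mm/day long-run mean) for
  right-skewed daily rainfall.
- **Responses**: each annual response is baseline + active deterministic
  driver ramps + (when the climate driver is active) the injected coupling
  Σₖ βₖ·EDHₖ + Gaussian noise, with yield floored at 0. Scenario S1 holds
  everything at baseline, S2 activates all drivers, S3–S9 deactivate one
  driver each, S10/S11 freeze management and differ only in land cover,
  and S12/S13 rescale the couplings by the region-specific tillage
  multipliers.

Randomness comes from named child streams of one master seed
(`SeedSequence(seed, spawn_key=(crc32(name),))`). Response noise is keyed
per **variable**, not per scenario: the emulated process model is
deterministic, so factorial runs must share their internal variability.
This makes paired differences (attribution, tillage effects) exact, mirrors
how factorial process-model experiments actually behave, and means cells
outside the injected tillage regions have D ≡ 0 — the false-positive rate
of the recommendation map is structurally zero rather than statistically
small.

### Choice of couplings and noise

The default betas (yield: −20/−10.5/−5 kg/ha per HC/DC/CDHC day, of order
0.1–0.3% of yield per extreme day; gas fluxes proportional) were balanced
against the generator's own index variability so each index carries a
comparable share of the response signal: HC and DC are empirically almost
uncorrelated, so their signal correlations trade off directly, while CDHC
correlates with both and is given the small bridging weight. Response
noise (yield 95 kg/ha, F_CO₂ 0.95 g C m⁻² yr⁻¹, F_N₂O 0.005 g N m⁻² yr⁻¹,
F_CH₄ 0.002 g C m⁻² yr⁻¹) is set near the signal's interannual SD. This is
deliberate: correlation is scale-invariant, so at zero noise a tillage
multiplier changes R not at all, and at large noise all correlations
drown — the difference D = R_t − R_a that the recommendation scheme detects
is largest at signal-to-noise ≈ 1. The tillage multipliers (0.3 in the
northern NT band, rows 13–20, and the southern CT band, rows 0–7) were
fixed by a 20-seed Monte-Carlo at these settings *before* the conditions
were frozen: the consensus map recovers ≥99% of injected cells in every
seed with zero false positives; the per-index diagnostic maps average
92–100% with worst-seed minima of 85% (HC in the saturated south) and 89%
(DC in the north).

### What the generator does not emulate

Gaussian residuals stand in for process-model output variability, whose
true structure is unknown here; there is no spatial autocorrelation beyond
the tillage region masks, no geography, no phenology or management
feedback, and the driver ramps are linear. Passing tests therefore
demonstrate the *analysis machinery* — counting, accounting, windowed
correlation, classification, thresholding — recovers known truth under
controlled conditions; they do not validate any claim about real wheat
systems.

## Numerical choices

- Window length 20 years, heat threshold 30 °C, aridity threshold 0.2,
  α = 0.05, recommendation threshold 0.75: the protocol constants, echoed
  into output metadata.
- Full-period detrending before windowing (per-window optional).
- Zero-variance windows, undefined AI days, and GHGI-masked cell-years are
  missing, never silently zero.
- float64 computation, float32 NetCDF payloads (correlation and trend
  stability vs file size); integers stored as int32 for NetCDF3.
- Problem sizes used by the test and acceptance runs: 20×20 × 59 years for
  the headline recovery, 8×8 or smaller for unit-level fixtures, a 10×10
  grid for the nine-way dataset × method uncertainty summary — sizes at
  which every documented property is already exercised.

## Known limitations

- The sensitivity-reduction aggregation is one defensible reconstruction,
  flagged as such above.
- Pearson R as "sensitivity" is linear; Kendall/Spearman are offered but no
  lagged or nonlinear response models are included.
- No field-significance or spatial-autocorrelation-aware inference.
- The tillage scheme considers only the NT/CT pair; no economic costs of
  switching.
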