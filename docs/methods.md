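# Methods

This note documents the model realization, the numerical choices, the
synthetic-data generator, and the design decisions taken where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Soil water

Variably saturated flow in a 1-D column (depth positive downward, surface
at z = 0, all fluxes positive downward) follows Richards' equation,

∂θ/∂t = −∂q/∂z − S_w,  q = K(ψ) (1 − ∂ψ/∂z),

with the van Genuchten–Mualem closure (S_e = (1+(α|ψ|)ⁿ)^(−m), m = 1−1/n,
K = K_s S_e^{1/2} [1−(1−S_e^{1/m})^m]²). Default hydraulics are literature
silt-loam values: θ_r = 0.067, θ_s = 0.45, α = 0.02 cm⁻¹, n = 1.41,
K_s = 10.8 cm day⁻¹.

Numerics: cell-centered finite volumes, Picard-iterated implicit step in
the mass-conservative mixed θ–ψ form (Celia-style), arithmetic-mean
interfacial conductivities, tolerance 0.05 cm on head, recursive step
halving on non-convergence. Three robustness devices, all mass-neutral:

- the surface flux is limited by the infiltration capacity of the top
  half-cell, evaluated at the pre-step head so the boundary does not
  flip-flop inside the Picard loop; the rejected part is runoff;
- once the surface cell is saturated under rain, the step switches to a
  ponded Dirichlet surface (ψ₀ = 0) — with free drainage below this keeps
  a fully saturated column well posed (two flux boundaries would leave the
  pressure undetermined) — and the realized infiltration is recovered from
  the top cell's mass balance;
- a small extra storativity (2·10⁻³) is applied only where ψ > −0.5 cm to
  suppress node-wise chattering across the saturation switch.

After convergence, θ is updated *from the face fluxes*, saturation excess
is pushed to the surface as runoff, and ψ is re-derived from θ. The water
ledger (rain − runoff − drainage − transpiration − evaporation − Δstorage)
therefore closes to round-off; the tests assert < 0.5% of season rainfall.

Evaporation is off by default (`evaporation_mm_d` is a config hook with an
exfiltration-capacity limiter). Transpiration demand is 4 mm day⁻¹ at full
canopy (maize peak), scaled by the logistic crop-development factor and by
a linear water-stress ramp between θ = 0.11 and 0.16, distributed over
depth proportionally to root length density.

## Nitrogen

Nitrate and ammonium move by advection (Darcy fluxes from the water step)
and dispersion (molecular diffusion with Millington–Quirk tortuosity
θ^{7/3}/θ_s², plus dispersivity 5 cm times pore velocity). Ammonium sorbs
linearly (k_d = 1.5 cm³ g⁻¹, ρ_b = 1.3 g cm⁻³, retardation ≈ 7); organic
N is immobile. The implicit upwind finite-volume step is a tridiagonal
M-matrix solve per species, hence positivity-preserving and exactly
conservative across the moving water inventory; bottom-boundary advective
flux accumulates as leached N.

The N cycle is the linear network org → NH₄ (mineralization, 3·10⁻³ d⁻¹),
NH₄ → org (immobilization, 8·10⁻³ d⁻¹), org ⇌ NO₃ (5·10⁻⁴ / 2·10⁻³ d⁻¹)
and nitrification NH₄ → NO₃ (0.2 d⁻¹). Rates are constant (constant
temperature), so one matrix exponential exp(A·Δt) is precomputed per
season and applied cell-wise — exact and mass-conserving, which the
exponential-decay oracle test exploits.

Root uptake per cell is Michaelis–Menten in solution concentration
(v_max = 2·10⁻³ mg N cm⁻¹ root d⁻¹, K_m = 0.01 mg N cm⁻³), multiplied by
root length density and by a water-availability factor
((θ−θ_r)/(θ_s−θ_r))^p with p = 1 (`mobility_exponent`). The factor stands
in for the saturation-dependent advective/diffusive delivery of N to root
surfaces: dry soil immobilizes N. Uptake is explicit with a cap at the
cell's available mass.

Fertilizer lands on a surface granule pool and enters the topsoil with
infiltrating rain (63% washed in per 0.3 cm of infiltration) plus a slow
background dissolution (0.05 d⁻¹). The pool is part of the N inventory, so
the season ledger (initial + applied − uptake − leached − final) closes to
round-off; tests assert < 1% of (initial + applied).

Initial pools are uniform in depth and integrate exactly to 41.6 (NO₃),
6.6 (NH₄) and 191 (organic) kg N ha⁻¹. The initial head is uniform at
−100 cm — late-winter field capacity for a silt loam.

## Calibration of the defaults

The transformation, root and uptake parameters of the source framework are
not published alongside it, so the defaults here were fixed once so that
historic-like forcing (≈1.7 mm day⁻¹) yields seasonal maximum uptakes of
order 200–215 kg N ha⁻¹ with mid-season optima, wetter forcing yields
lower maxima with later optima and substantially more leaching, and drier
forcing yields earlier optima — the qualitative structure the analysis
targets. The column is 60 cm deep (30 nodes of 2 cm, Δt = 0.25 d, sub-step
halving as needed). The depth matters scientifically: leaching must be
able to respond to fertilization timing *within* a season, which requires
the bottom boundary to be reachable by fertilizer-derived N under wet
forcing. Halving dz and Δt changes seasonal uptake by < 2% (tested).

## Timing optimization

The timing grid is t = t_min, t_min+Δ, … ≤ 70 days with Δ = 1.2 d and
t_min = Δ (no day-0 application; 58 points, 1711 admissible pairs with
t₁ ≤ t₂). Every pair is an independent model instance; results are
order-independent. Ties at the maximum break to the lexicographically
earliest pair (deterministic, favors earlier application). Close-to-optimal
= uptake ≥ 0.95·max. Stability uses a Chebyshev box of radius r = 2.4 d
clipped to the admissible triangle; season stability is the mean over the
close-to-optimal set. Medians over even-sized sets use the midpoint
convention.

## Precipitation analytics

- Seasonal mean = arithmetic mean of the 122 daily rates.
- Rolling means: centered, width 11 years, windows truncated symmetrically
  at the series ends so output spans the full year range.
- Heavy-rain threshold: 99th empirical percentile (linear interpolation)
  of all in-season days in a reference window (default 1950–1979 style); a
  heavy day is ≥ the threshold.
- SPI: per calendar month across the fit window (default: full record), a
  gamma distribution is fitted by maximum likelihood to the monthly
  totals; zeros are handled as a point-mass mixture,
  SPI = Φ⁻¹(q + (1−q)·G(x)). Degenerate months (all zero, or fewer than
  two distinct positive totals) report NaN/"missing". Drought classes:
  (0,−1] mild, (−1,−1.5] moderate, (−1.5,−2] severe, ≤−2 extreme;
  boundaries fall in the drier class. The implementation was cross-checked
  against an independent gamma-ML fit in R (frozen in the test suite) and
  calibrates to N(0,1) on i.i.d. gamma totals by construction.
- Decades are calendar decades ("1950s" = 1950–1959); partial decades are
  excluded by default.

## Synthetic weather

Occurrence is a two-state Markov chain (wet/dry persistence); wet-day
amounts are gamma draws with an optional heavy-day mixture (a longer-tailed
gamma chosen with small probability). Seasons are independent across years
— the analysis treats seasons independently — and dated 1 March, so every
season is exactly 122 days (the window contains no leap day). Presets:
historic-like ≈1.7 mm day⁻¹ seasonal mean, wet ≈3.6, dry ≈1.2, with heavy
days rarest in the dry preset. What the generator does *not* emulate:
interannual autocorrelation, trends within the record, temperature, and
any spatial structure — so passing ensemble tests demonstrate the
pipeline's directional behavior under controlled rainfall statistics, not
climatological realism for any particular region.

## Study pipeline

Per season: uptake surface → optimum, close set, medians, stability;
per decade: medians pooled over all close-to-optimal pairs in the decade,
mean close-pair counts, heavy-day percentages; correlations: Pearson r of
seasonal mean daily rate and seasonal mean SPI (mean of the four 1-month
values) against maximum uptake and the median close-to-optimal timings, on
raw yearly values and on 11-year rolling means (reported separately, no
multiple-testing adjustment). A fixed-strategy efficiency helper scores a
single timing pair against every season's own maximum. All outputs are
deterministic given record + config; the report serializes its full
configuration for provenance.

## Problem sizes used in the checks

The acceptance checks run a 7-day timing grid (10 points, 55 pairs per
season) over 20 wet + 20 dry synthetic seasons — about 2300 season
simulations — plus closed-form transport verifications on refined grids
(240 cells, Δt = 0.002 d) and a 100-year SPI calibration. These sizes were
chosen as the smallest at which the ensemble medians are stable.

## Known limitations

- Gaseous N losses (N₂O, N₂, NH₃) are not represented; "losses" means
  leaching only.
- Constant temperature; no growth-stage-dependent N demand; root growth is
  never water- or N-limited, so dry-season uptake may be optimistic.
- First-order, moisture-independent transformation rates.
- The close-to-optimal *count* contrast between wet and dry seasons comes
  out opposite to the source analysis under this realization (dry-season
  surfaces are flatter than wet ones, because leaching is the only
  wet-season loss channel while mid-season dry timing carries no
  comparable penalty); the directional shifts of the optima themselves and
  the uptake ordering reproduce robustly. See the acceptance suite.
- One soil texture and one crop parameterization; no 2-D/3-D effects.
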