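# Methods

## Scope and structure

The package chains four model components: (1) a stochastic range-expansion
simulator producing presence/absence grids of the pine wood nematode at
the coarse resolution of a spread model; (2) a climate layer gating
expression of pine wilt disease by mean July–August temperature; (3) a
regional host-stock inventory in six vulnerability classes (age ≤20 yr or
>20 yr × susceptible/intermediate/resistant); and (4) an economic module
with two parts — partial budgeting for spatially indexed direct losses and
a partial-equilibrium model of the EU round-wood market for welfare
effects. Spatial integration is done at two resolutions throughout, and
the divergence between them is itself a result of interest.

## Direct losses (partial budget)

For polygon *i*, `L_i = p · Σ_jk e_i · m_jk · s_ijk`, with the exposure
`e_i = r_i · d_i` at coarse resolution and the qualifying-cell fraction at
fine resolution. Assumptions:

* Trees expressing the disease are a total loss; symptomless trees retain
  full value. No salvage value, no replanting revenue within the horizon.
* No discounting: the cumulative series is an undiscounted running total
  of lost stock value, recomputed each year from that year's occupancy.
* The standing-stock structure is static over the 23-year horizon (no
  growth, harvest response or replacement).
* Disease expression uses a **strict** inequality (temperature > threshold);
  a region or cell exactly at the threshold expresses no disease, at both
  resolutions.

Mortality presets (fraction killed, by age × susceptibility):

| preset | ≤20 yr S/I/R | >20 yr S/I/R |
| --- | --- | --- |
| default | 1.00 / 0.80 / 0.50 | 0.90 / 0.70 / 0.40 |
| minimum | 0.60 / 0.60 / 0.40 | 0.50 / 0.50 / 0.40 |
| maximum | 1.00 / 1.00 / 0.50 | 0.90 / 0.90 / 0.50 |

Impact per km² is reported per **qualifying** km² (cells that are both
infested and warm enough). Published per-km² figures cannot be
reconstructed from a single stated denominator (qualifying vs total vs
forested area give different values), so the package states its
denominator explicitly and uses it consistently.

## Market model (partial equilibrium)

Constant-elasticity forms are used for all three curves; the cited
literature supplies elasticities but not functional forms, and log-linear
curves are the standard choice that the scale parameters can be calibrated
to exactly:

* demand `D(P) = χP^η`, calibrated χ = D₀/P₀^η;
* domestic supply `S(P) = β·g·P^θ`, β = S₀/P₀^θ, with pest-shock
  multiplier `g = (1−z) + z(1−h)(1−ν)^θ`, which collapses to `1−x`
  (x = z·h) when the cost increase ν = 0. The package parameterizes the
  aggregate `x` and treats (z, h, ν) as optional: the separate components
  are never identified by the available data, and mitigation costs (ν) are
  excluded from scope by design;
* the EU–world price link is additive, `P = WP + µ` with µ = P₀ − WP₀ =
  −4.01 €/m³ — the simplest linear relation consistent with both observed
  prices;
* net imports `M(WP) = υWP^ω` with υ = (D₀−S₀)/WP₀^ω. The EU is a net
  importer at baseline (D₀ > S₀), and the sign of υ carries the trade
  direction through the solution.

The supply shock applies the yearly-flow rule: the reduction in annual
round-wood supply equals the flow fraction (default 1.8%, the average
yearly removal share of standing stock) of the cumulative lost stock
volume, `x = f·(Lₜ/p)/S₀`.

The clearing price solves `S(P) + M(P−µ) = D(P)` by bracketed Brent root
finding on [P₀/2, 4P₀] at relative tolerance 1e-12. Supply and imports
increase and demand decreases in P, so the residual is strictly monotone
and the root unique; the zero-shock case returns the calibrated baseline
exactly rather than re-solving.

Welfare: `ΔCS = −χ(P₁^{1+η} − P₀^{1+η})/(1+η)` (a logarithmic
antiderivative handles η = −1); `ΔPS = S₁P₁/(1+θ) − S₀P₀/(1+θ)`, the
producer-surplus formula for a constant-elasticity curve evaluated on the
shifted curve at the new equilibrium; `ΔW = ΔCS + ΔPS` by construction.
Only surplus *changes* are reported — the absolute consumer-surplus
integral diverges for |η| < 1. In percentage terms the consumer-side
changes are reported against baseline consumer expenditure (D₀·P₀), the
producer side against the baseline producer surplus; absolute changes are
the primary output.

A full-chain caveat: converting the published fine-resolution cumulative
loss to volume at the baseline price and applying the 1.8% rule yields
x ≈ 3.29%, whereas the published equilibrium changes imply an effective
x ≈ 3.0%; the value→volume conversion behind the published table is not
uniquely recoverable. The package therefore exposes `x` directly,
verifies that the 3.29% derivation brackets the published price and
welfare changes, and evaluates the surplus formulas at the published
equilibrium changes when reproducing those numbers exactly.

## Synthetic worlds

The generator emulates the structure of the real input layers, not their
geography:

* **Temperature**: a linear south–north gradient plus i.i.d. Gaussian
  noise per 1 km² cell. Defaults (base 15.8 °C at the mid-row,
  0.12 °C/row, noise SD 0.4 °C on a 100-row grid) put only the southern
  quarter of the domain above the 20 °C expression threshold, mirroring a
  continent where the disease is climatically confined to the south, and
  leave several region means slightly above 20 °C so the coarse/fine
  aggregation discrepancy is expressed.
* **Regions**: contiguous rectangular blocks tiling the grid — sufficient
  for zonal statistics; no real administrative geometry.
* **Stock**: regional totals proportional to area with lognormal (σ=0.3)
  heterogeneity, split across the six vulnerability classes in fixed
  proportions (default mix 10/8/7% young and 30/25/20% old S/I/R,
  reflecting the dominance of mature stands); the grand total hits the
  target (default 2.46×10¹⁰ m³, a continental-scale standing stock)
  exactly up to rounding.
* **Spread**: per-year occupation of cells within a Chebyshev radius
  (default 1) of the occupied set with fixed probability (default 0.3),
  plus Poisson long-distance jumps (default rate 0.05/yr) to uniform
  cells — a generic monotone stochastic expansion with replicate
  variation, standing in for the mechanistic vector-flight/wood-trade
  model whose output the analysis consumes as an exogenous layer. Entry
  defaults to the south-west, 200 replicates, 2008–2030.
* **Percentile selection** among replicates ranks by final-year
  invaded-cell count and takes the nearest rank (⌈q/100·n⌉, ties to the
  lowest replicate index) — reproducible without interpolation.

What the synthetic worlds do **not** capture: realistic host-density
hot-spots (Iberian-scale concentrations), anisotropic spread along trade
corridors, spatially correlated climate noise, and real region shapes.
Passing tests therefore demonstrate correctness of the integration and
economics on structurally faithful inputs, not predictive accuracy for
Europe. Under the default conditions the simulated invasion kills ≈8% of
total stock value by 2030 — a severe-epidemic scenario at the upper end
of, but comparable in order to, assessments on real host data.

## Uncertainty analyses

* Single-parameter sweeps hold the base scenario (median spread, 20 °C,
  default mortality, 50.49 €/m³) and vary one axis: spread percentile
  {5, 50, 95}, threshold {18, 19, 20} °C, mortality preset, price. The
  price sweep defaults to the pair (50.49, 67.7) €/m³ for consistency
  with the published sweep results; the alternative recorded 2003–2009
  pair (50.49, 64.14) is available via configuration.
* Worst case = 95th-percentile spread + 18 °C + maximum mortality +
  highest price; best case is the mirror image. Regional impacts are also
  expressed relative to the regional asset value, valued at that case's
  own price so the ratio isolates exposure × mortality.
* Layer removal recomputes with `d ≡ 1` (no climate constraint) or
  `r ≡ 1` (unknown entry point: climate-only). Both figures are reported
  side by side without asserting which published headline corresponds to
  which mode, since the published description is internally inconsistent
  on that labelling.

## Numerical and engineering choices

* Downscaled cell impacts are forced to sum to the regional value exactly
  (remainder to the first qualifying cell in row-major order); positive
  regional impact with zero qualifying cells is an invariant violation.
* The regional infested proportion is computed as the area fraction
  covered by occupied coarse cells, which equals the occupied-cell count
  fraction whenever regions align with the coarse blocking, and remains
  well defined when they do not.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning (one child per spread replicate);
  identical seeds give byte-identical outputs end to end.
* Grids are exchanged as Esri ASCII rasters, tables as UTF-8 CSV; rounded
  tables are paired with full-precision `*_raw.csv` companions.
* Default problem sizes — 100×100 fine cells, 20×20 coarse cells,
  20 regions, 200 replicates, 23 annual steps — keep a full pipeline run
  in the low seconds while leaving every statistical feature (replicate
  spread, percentile separation, regional heterogeneity) expressed.

## Known limitations

* Coarse cells are square blocks of fine cells with configurable side
  length; the degree-based cell size of the original spread model is
  internally inconsistent with its stated km² coverage, so no fixed
  conversion is imposed.
* The partial-equilibrium model is single-commodity and static: no
  fuel-wood market, no cross-price effects, no dynamics beyond the
  year-by-year sequence of independent equilibria.
* Mitigation/control costs and policy responses are out of scope; the
  assessment is of an uncontrolled invasion.
* Country-level absolute losses on real data require the proprietary
  inventory layer; the package reproduces published totals only where
  they follow from published inputs (additivity, price rescaling, the
  welfare worked examples).
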