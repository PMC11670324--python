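# Methods

## The accounting problem

Anoxic incubations of diluted peat soil (slurry microcosms) are the
standard tool for resolving the anaerobic food chain: a labile substrate is
added, concentrations of substrate, fermentation products and gases are
followed over days, and the question is whether the measured products
account for the measured substrate consumption. `anoxmet` implements this
accounting in two common currencies:

- **carbon**: μM of a compound × its C atoms per molecule → μM-C;
- **reductant**: μM × its degree of reduction γ → μM electron equivalents.

The degree of reduction is the generalized electron content per molecule
relative to the fully oxidized reference states CO2, H2O and NH3:

    γ = 4·nC + 1·nH − 2·nO − 3·nN.

Examples: N-acetylglucosamine (NAG, C8H15NO6) γ = 32, ethanol 12, acetate
(as acetic acid) 8, formate 2, propionate 14, methane 8, CO2 0, H2 2. Two
conventions fix these numbers and are hard-wired deliberately:

1. **Neutral acid forms.** Organic acids are registered as their protonated
   formulas (C2H4O2, CH2O2, C3H6O2). The anionic forms would need a charge
   term in γ; the neutral convention reproduces the standard factor pairs
   and sidesteps charge accounting.
2. **NH3 as the nitrogen reference** (weight −3). This is the only
   reference under which an amino sugar like NAG carries 32 electron
   equivalents; alternative references (NO3⁻, N2) are intentionally not
   supported rather than silently configurable.

Sulfur and phosphorus parse in formulas but are rejected by the γ rule — no
reference state is defined for them here. Negative γ (species more oxidized
than CO2) triggers a warning, never an abort; hard errors are reserved for
malformed input.

## Turnover pipeline

For a time frame [t0, t1] and analyte a:

1. **Frame delta**: Δ = mean concentration over replicates at t1 − mean at
   t0. Replicates are averaged first ("mean-first"), matching how such data
   are reported (means ± SE of triplicates); a per-replicate policy is
   available and gives the same mean but a different SE. If a frame
   boundary was not a sampling day, the value is linearly interpolated per
   replicate between the bracketing samples and a warning is emitted;
   exact-match mode is available. Whether replicates should be averaged
   before or after control subtraction is ambiguous in general — the orders
   agree for means but not for SEs — so the reported uncertainties are the
   package's own quadrature-combined endpoint SEs, not a claim about any
   particular lab's error model.
2. **Control subtraction**: net = Δ(treatment) − Δ(matched control), SEs in
   quadrature. The control must carry the same BES flag as the treatment
   (BES-inhibited arms are compared to BES-inhibited controls); a mismatch
   is a hard error, because subtracting a methanogenically active control
   from an inhibited treatment confounds the budget.
3. **Unit conversion**: net × (nC, γ), giving μM-C and μM-e with signs
   preserved (positive = net production).
4. **Recovery**: 100 × Σ(positive turnovers) / |Σ(negative turnovers)| per
   frame and basis. Values > 100% (more product than substrate measured)
   are reported as-is with a flag — clipping would hide real unmeasured
   sources. No net consumption → an explicit undefined flag, not a number.
   `product_fraction` gives one compound's share of total net production.

CO2 is treated as a single lumped measured pool (no carbonate speciation),
and analytes absent from a treatment's records contribute zero turnover
with a logged notice — this mirrors the common case of a gas (H2) that
cannot be quantified reliably.

## Chamber fluxes and unit conversions

Closed-chamber fluxes use ordinary least squares of mixing ratio (ppmv) on
time (h) over all timepoints; with chamber volume V, footprint A, and
ideal-gas mole content n = PV/RT, flux = slope·PV/(RTA) in μmol m⁻² h⁻¹.
No curvature (saturation) correction is applied — appropriate for short
(≤ 3 h) deployments with few timepoints — and negative slopes are reported
as uptake. Defaults are T = 293.15 K, P = 101.325 kPa, both configurable.
The slope SE (needing ≥ 3 points) converts with the same factor; with
exactly 2 points the slope is the two-point difference quotient and the SE
is NaN.

CO2:CH4 ratios are computed elementwise on key-aligned series; points with
CH4 ≤ 0 are flagged undefined and left NaN without disturbing the rest.

`headspace_to_slurry` converts a headspace volume percentage to mmol per
litre of slurry by the ideal gas law. `umol_per_gdw` divides μM of slurry
by a configured constant (default 10.5, the conventional divisor for a
1:10 peat slurry). Both the printed equivalence 8 vol% ↔ 8.4 mmol L⁻¹
sometimes quoted for such setups and the 10.5 divisor depend on unstated
details of flask geometry and soil water content; they are therefore
honored as configuration defaults, not derived quantities.

## The synthetic microcosm simulator

The simulator exists to make every accounting stage verifiable against a
known truth. Its reaction library is the canonical anaerobic food chain,
every entry element- and electron-balanced by construction:

| reaction | stoichiometry | k (d⁻¹) | lag (d) | BES-sensitive |
|---|---|---|---|---|
| primary NAG fermentation | NAG + 3 H2O → 2 acetate + ethanol + formate + CO2 + H2 + NH3 | 2.0 | 0 | no |
| formate methanogenesis | 4 formate → CH4 + 3 CO2 + 2 H2O | 0.8 | 2 | yes |
| hydrogenotrophic methanogenesis | 4 H2 + CO2 → CH4 + 2 H2O | 1.5 | 2 | yes |
| syntrophic ethanol oxidation | ethanol + H2O → acetate + 2 H2 | 0.6 | 2 | yes |
| hydrogenotrophic acetogenesis | 4 H2 + 2 CO2 → acetate + 2 H2O | 0.1 | 0 | no |
| aceticlastic methanogenesis | acetate → CH4 + CO2 | 0.05 | 4 | yes |

The primary fermentation stoichiometry is the unique small-integer solution
of the element + electron balance for the observed mixed-acid product set
(2 acetate + 1 ethanol + 1 formate + 1 CO2 + 1 H2 + 1 NH3 carry exactly
the 8 C and 32 e of one NAG). Kinetics are first-order in one designated
limiting substrate per reaction (rate = k·[S]); Monod kinetics,
thermodynamic feedback (H2 partial-pressure control of syntrophy) and
population dynamics are out of scope. Rate constants and lags were chosen
once so that the default scenario reproduces the canonical succession —
500 μM NAG consumed to < 1 μM by day 4, transient formate/ethanol maxima
during the primary stage, then a delayed methanogenic stage consuming the
intermediates while CH4 rises monotonically. Dissolved/gaseous partitioning
is ignored: all pools are slurry-equivalent μM, consistent with how the
turnover math treats CO2 and CH4.

**BES.** A BES design zeroes the rate of every BES-sensitive reaction.
Besides the three CH4-forming reactions this includes syntrophic ethanol
oxidation, which produces no CH4 but depends obligately on H2 removal by a
methanogenic partner — blocking the partner stalls the syntrophy. This is
what produces the characteristic BES signature: zero CH4 and larger
transient formate and ethanol pools than in uninhibited arms.

**Unmeasured sink.** A fraction s ∈ [0,1] of each reaction's substrate
carbon and electrons is diverted to explicit unmeasured pools (μM-C, μM-e,
tracked in the truth output); products are scaled by (1−s). This emulates
assimilation into biomass and undetected products. On a scenario with only
the primary fermentation active, frame recovery equals 100·(1−s) exactly on
both bases (`nag_primary_only_model`). With the full cascade, downstream
reactions divert a share of re-consumed intermediates too, so frame
recoveries fall below that line — which is why the attribution property is
stated and tested on the single-stage scenario.

**Endogenous background.** Controls produce CO2 from peat organic matter;
this is modelled as a zeroth-order external source (default 200 μM d⁻¹)
applied to treatments and controls alike, so matched-control subtraction
cancels it. Because its ultimate organic source and electron acceptors are
not part of the network, it is bookkept as a cumulative external input
column in the truth table; the conservation invariant is total carbon minus
cumulative endogenous input = constant, and total electron equivalents =
constant (the source is CO2, which carries no electrons).

**Integration and noise.** Deterministic fixed-step RK4 (0.01 d, 10-day
horizon, sampling at days 0,1,2,3,4,6,8,10 to mimic 1–2-day intervals).
Because the RHS conserves C and e pointwise, RK4 conserves them to
round-off (observed drift ~1e-15 relative). A pool excursion below
−10⁻⁶ × the concentration scale aborts with an error rather than being
clipped; sub-tolerance negatives from round-off are zeroed. Measurement
noise is additive Gaussian (default SD 10 μM), truncated at zero, applied
independently per triplicate replicate to measured analytes only — means ±
SE are the only moments claimed, so no heteroscedastic model is attempted.
Default measured analytes are NAG, acetate, formate, ethanol, propionate,
CO2 and CH4 (H2 deliberately unmeasured). The default scenario
(`nag_microcosm_model`) uses sink fraction 0.5, the regime in which roughly
half of consumed carbon/reductant is recovered in detected products. All
randomness flows from a single integer seed (arm-level streams derived via
`SeedSequence`); identical seeds give byte-identical serialized output. No
propionate-forming reaction is included by default — its source is
endogenous fermentation with no identified stoichiometry — so simulated
propionate stays at zero while remaining a measured analyte.

**What the simulator does not emulate**, and hence what passing tests do
not show about real incubations: carbonate equilibria and headspace
partitioning, substrate-threshold and thermodynamic inhibition effects,
growth-coupled (autocatalytic) kinetics, temperature dependence, and any
propionate dynamics. Closure tests certify the accounting arithmetic, not
the realism of peat kinetics.

## Numerical and design choices

- Stoichiometric coefficients are exact rationals (`fractions.Fraction`);
  balance reports carry exact residuals, so "balanced" involves no
  tolerance. Atom counts are integers only.
- Frame-boundary matching tolerance is 1e-9 days; sampling days must fall
  on the RK4 grid or the simulator refuses.
- The flux estimator and its Monte-Carlo check are deliberately kept as
  two routes: `simulate_chamber` (forward model) and `chamber_flux`
  (scipy OLS inverse), exact on noiseless input to round-off.
- Recovery ratios use exact sign splits of the turnover column; ties at
  exactly zero contribute to neither side.
- Problem sizes throughout (10-day horizon, 8 sampling days, triplicates,
  1000-seed Monte Carlo for estimator bias) were chosen as the smallest
  that exercise every code path with comfortable statistical resolution.

## Known limitations

- Charged species, S/P compounds and isotopes are out of scope for γ.
- SEs from mean-first differencing understate replicate covariance; the
  per-replicate policy exists for that reason but no inferential testing
  is provided (means ± SE only).
- The interface validates and rejects; it never repairs. Malformed rows are
  reported with line numbers, and pipeline failures name their stage.
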