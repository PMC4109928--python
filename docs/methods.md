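# Methods

## Scope and assumptions

The model describes a parcel of shallow groundwater discharged into a
small, shaded, nutrient-poor headwater stream on silicate bedrock. Under
those conditions the DIC budget is dominated by two processes — delivery
of respiration-derived CO₂ by groundwater and evasion to the atmosphere —
and the model deliberately contains nothing else: no carbonate-mineral
dissolution (silicate terrain), no in-stream metabolism (low relative to
gas exchange), no organic-alkalinity dynamics (treated as constant and
folded into the carbonate-alkalinity baseline), no diel temperature
cycles, no confluences. Water travel times of minutes to hours justify a
fixed temperature per run. Activity coefficients are set to 1 throughout
(conductivities of tens of µS/cm); there is no ionic-strength correction
anywhere.

Units are fixed package-wide: µmol/L for concentrations, µeq/L for
alkalinity, °C, ‰ VPDB, days. Converters live only at the I/O boundary.

## Carbonate system

Equilibrium constants are freshwater, zero-salinity fits evaluated at the
run temperature (valid −2…40 °C, enforced):

| constant | fit | 4 °C | 25 °C |
|---|---|---|---|
| pK₁ (CO₂*–HCO₃⁻) | Harned & Davis (1943): 3404.71/T + 0.032786 T − 14.8435 | 6.528 | 6.352 |
| pK₂ (HCO₃⁻–CO₃²⁻) | Harned & Scholes (1941): 2902.39/T + 0.02379 T − 6.4980 | 10.568 | 10.329 |
| pK_w | Harned & Owen (1958): 4470.99/T + 0.017060 T − 6.0875 | 14.773 | 13.995 |
| K_H (mol/L/atm) | Weiss (1974), S = 0 | 0.0665 | 0.0339 |

(T in kelvin inside the fits.) These reproduce the worked parcel
(DIC 1200 µmol/L, pH 5.5, 4 °C): CO₂* = 1097 µmol/L, HCO₃⁻ = 103 µmol/L,
and CO₂eq(380 ppmv) = 25.3 µmol/L.

Two alkalinity-like quantities are kept deliberately distinct:

* **carbonate alkalinity** CA = [HCO₃⁻] + 2[CO₃²⁻] — the quantity
  conventionally reported for these waters (103 µeq/L for the worked
  parcel);
* **total (charge-balance) alkalinity** CA + [OH⁻] − [H⁺] — the acid
  neutralizing capacity of the carbonate–water system. Only this form is
  exactly invariant under CO₂ gain or loss, so it is what the simulator
  holds constant. It is 99.7 µeq/L for the worked parcel and goes
  negative below pH ≈ 5 where free acidity exceeds the carbonate charge.
  Holding CA constant instead would be wrong at low pH: an acid stream at
  pH 4 keeps its pH while pure CO₂ evades, which only the charge-balance
  form reproduces.

CA therefore drifts by a few µeq/L over a simulation as [H⁺] falls; that
is chemistry, not solver error. The trajectory CSV's `alk_ueq_L` column
carries the conserved (total) form.

`ph_from_dic_alk` inverts either form by a bracketed root find on
pH ∈ [2, 12] (both are strictly increasing in pH at fixed DIC, so the
root is unique); the residual is converged to ~1e−10 µeq/L. Inside the
simulation loop the same equation is solved on [H⁺] by a warm-started
Newton iteration (2–3 iterations per step) with the bracketed solver as
fallback.

## Isotopes

All fractionations are additive ε offsets in ‰ (first-order delta
arithmetic), with the convention ε(A–B) = δA − δB at equilibrium. At the
δ values of these systems the error against full ratio algebra is far
below 0.01 ‰. Fits, with values at 4 °C:

* ε(CO₂aq–HCO₃⁻) = −9866/T + 24.12 (Mook et al. 1974) = **−11.48 ‰**
* ε(HCO₃⁻–CO₃²⁻) = −0.0621 t + 3.56 (difference of the HCO₃-gas and
  CO₃-gas fits of Zhang, Quay & Wilbur 1995) = **+3.31 ‰**
* ε(CO₂aq–CO₂g) = −373/T + 0.19 (Mook et al. 1974) = **−1.16 ‰**
* ε_k (kinetic, gas transfer) = linear through the Zhang et al. (1995)
  measurements (−0.95 ‰ at 5 °C, −0.81 ‰ at 21 °C) = **−0.96 ‰**

Bulk δ¹³C-DIC is partitioned among species by solving the linear system
{fraction-weighted mass balance; two equilibrium offsets} exactly. The
simulator's conservation bookkeeping uses the linearized heavy pool
h = C·(1 + δ/1000); in that variable, mixing and flux removal are exactly
linear, and removal at offset ε reproduces the Rayleigh law
δ = δ₀ + ε·ln f exactly in the continuum limit.

## Forward model

Each Euler step of length dt:

1. gross evasion k·CO₂·dt leaves with δ¹³C-CO₂(aq) + ε_k; gross invasion
   k·CO₂eq·dt enters with δ¹³C_atm + ε_k + ε_aq-g (net flux
   k·(CO₂ − CO₂eq)·dt);
2. pH is re-solved to hold total alkalinity constant; species and species
   deltas are re-partitioned;
3. with inflow, a volume fraction gw_inflow·dt of groundwater is mixed in
   conservatively (DIC, alkalinity, heavy pool), and pH re-solved again.

Steps are sub-divided automatically so that k·dt_sub ≤ 0.05: per-sub-step
CO₂ turnover below 5% bounds the first-order discretization error and
makes overshoot below atmospheric equilibrium impossible. Halving dt
moves the end state by < 0.1%.

The gross-flux isotope labelling makes the atmospheric asymptote emerge
rather than being imposed: the net ¹³C flux vanishes exactly when
δ¹³C-CO₂(aq) = δ¹³C_atm + ε_aq-g. Two consequences worth knowing:

* at CO₂ = CO₂eq the concentrations are steady but the isotopes keep
  exchanging — a parcel at chemical equilibrium still relaxes
  isotopically toward the atmosphere at rate ≈ k·CO₂eq/DIC;
* therefore isotopic equilibration lags concentration equilibration. A
  run stopped at CO₂ ≤ 1.001·CO₂eq (t ≈ 0.7 d for the typical parcel at
  k = 15/d) still carries a ~2.6 ‰ δ¹³C-CO₂ disequilibrium; by t ≈ 2–3 d
  the gap is < 0.05 ‰. The asymptote test runs to t = 3 d for this
  reason.

Defaults: k = 15/d (mid-range of the 7–25/d measured in comparable
streams), dt = 0.002 d, pCO₂_atm = 380 ppmv, δ¹³C_atm = −8 ‰ (standard
late-20th-century troposphere; not printed in the source data, so
configurable), stop at CO₂ ≤ 1.01·CO₂eq or 10 d.

Bookkeeping: `cum_evaded` and `cum_gw_added` are net concentration
equivalents defined so DIC(t) = DIC(0) − cum_evaded + cum_gw_added holds
exactly, also under dilution by inflow; the same balance holds for the
heavy pool. `fraction_CO2_lost` uses amount (volume-tracked) bookkeeping:
net CO₂ evaded divided by CO₂ delivered (initial plug CO₂ plus the CO₂
carried by any groundwater added), on the CO₂-species basis.

## Inverse fit

Unknowns: groundwater DIC and pH, and the matched degassing time t*.
Groundwater δ¹³C-DIC is fixed (C3-constrained; an optional ±box can open
it as a fourth variable). The objective is the σ-weighted SSE over
(DIC, pH, δ¹³C-DIC); default σ = (50 µmol/L, 0.05, 0.3 ‰) are typical
measurement precisions and are user-overridable.

The optimizer is Nelder–Mead over (log gw_DIC, gw_pH) — log because DIC
is a scale parameter and the DIC/t* trade-off is the flat direction — with
t* profiled out exactly: each candidate end-member is simulated once and
the SSE minimum along the trajectory (with local time interpolation) is
taken. This has the same optimum as a three-variable simplex but needs
one simulation per candidate instead of one per (candidate, time) pair.
Five restarts are jittered (seeded, hence deterministic) around initial
guesses built from the observation itself: without inflow the trajectory
conserves total alkalinity, so for any guessed gw_DIC the matching gw_pH
is solved directly from the observed alkalinity — which is why the
simplex almost always starts within sight of the optimum. Bounds are
enforced by large finite penalties (gw_pH ∈ [3, 6.8], gw_DIC ∈ [obs DIC,
5·10⁴ µmol/L]); equal-SSE ties resolve to the smallest gw_DIC, the most
conservative loss estimate. A fit whose SSE exceeds a χ²-scale threshold
(default 25) is returned with `converged = False` rather than silently
accepted. Endpoint matching via t* is used throughout (matching to the
nearest trajectory point is the same thing once t* is profiled).

Identifiability at desk scale: noise-free observations across
gw_DIC ∈ {1200, 1500, 1800} µmol/L × loss ∈ {0.3, 0.5, 0.7, 0.9} are
recovered to ≪ 1% in gw_DIC and ≪ 0.01 in fraction; with default noise,
100 synthetic sites give a median |fraction error| ≈ 0.03. The end-member
DIC itself is softer under noise (hundreds of µmol/L) because DIC and t*
trade off along the trajectory — the lost *fraction* is the robust
quantity, which is exactly what the method is for.

With continuous inflow the same observation implies *more* cumulative
evasion (groundwater kept topping the stream up), so ignoring a known
inflow underestimates the upstream loss; the forward effect of inflow is
to pull the stream state back toward groundwater values (higher DIC,
lower pH, lower δ¹³C-DIC at a given time). Both behaviours are asserted
in the tests. The inflow rate can be given directly (parcel volumes per
day) or derived from discharge growth along a reach,
f = ln(Q_down/Q_up)/τ with τ = length/velocity.

## Flux scaling

flux_daily [mgC/m²/d] = co2_lost·12.011·Q·86400/(A·10⁶)/1000 with
co2_lost in µmolC/L, Q in L/s, A in km². Annual values are
discharge-weighted means of daily fluxes × 365.25/1000 (gC/m²/yr), with
the unweighted median reported alongside. Upstream distance uses
L = (v/k)·ln(1/(1−completeness)), completeness defaulting to 0.95
(ln 20 ≈ 3 decay lengths); velocity may be given directly or as
discharge/cross-section. All inputs are exposed rather than hard-coding
any particular v–k–Q–A combination.

## Synthetic data

`generate_survey` simulates the forward model from a single truth
end-member (defaults: DIC 1500 µmol/L, pH 5.0, δ¹³C −25 ‰, 4 °C — the
centre of the landscape family DIC 1200–1800 µmol/L, pH 4.0–5.5),
samples each site at a target lost fraction (given, or uniform on
[0.3, 0.9], covering the 60–80% losses typical of real headwater
samples), and adds independent Gaussian noise per variable. A truth
sidecar records the end-member, per-site fractions and times, sigmas and
seed. Same seed ⇒ identical survey.

What passing recovery tests on these fixtures shows — and what it does
not: they demonstrate that the inverse machinery is unbiased and
well-conditioned when the forward model is the data-generating process
and the noise is independent Gaussian. Real streams add model error
(inflow patterns, metabolism, temperature drift, correlated errors),
which these fixtures deliberately exclude; field application leans on the
model-adequacy assumptions listed at the top.

## Numerical choices and problem sizes

* pH solves: Newton on [H⁺] warm-started from the previous step,
  residual < 1e−10 µeq/L, bracketed fallback; brentq xtol 1e−12 for the
  public solver.
* Euler sub-division cap: 5% CO₂ turnover per sub-step.
* Rayleigh-limit verification: pH 3.0, pCO₂_atm = 0, dt = 2·10⁻⁴ d, down
  to f = 0.01 — agreement with δ₀ + ε_k ln f to 0.02 ‰. At higher pH or
  deeper f the residual bicarbonate pool makes the closed form itself
  inapplicable, not the integrator.
* Recovery studies: 12 noise-free grid fits and 100 noisy single-sample
  fits (3 restarts, ≤ 100 simplex iterations each) — about half a minute
  total on one CPU.

## Known limitations

* Fixed temperature per run; no seasonal or diel forcing.
* First-order delta arithmetic (exact for the model's own bookkeeping;
  differs from full ratio algebra by ≪ 0.01 ‰ at natural abundances).
* The end-member DIC/t* trade-off leaves gw_DIC weakly constrained from
  a single noisy sample; only the lost fraction is reported with
  confidence.
* No formal uncertainty on fitted parameters (multi-start SSE only);
  Monte-Carlo over inputs is the intended route and is cheap.
* The inflow model assumes a constant fractional rate along the reach.
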