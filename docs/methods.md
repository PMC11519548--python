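# Methods

This note documents the models implemented by `airmob`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real measurements.

## Headspace mass accounting

A trace gas at mixing ratio *x* (p.p.m.v.) in a closed headspace of volume
*V* (L) at pressure *P* (bar) and temperature *T* (K) amounts to
*n* = *x*·10⁻⁶·*PV*/(*RT*) mol (ideal gas; *R* = 0.083145 L bar mol⁻¹ K⁻¹).
The default bottle is a 250 mL vessel with 50 mL of medium (0.2 L
headspace) at 1.05 bar and 293.15 K, the geometry of the incubation
experiments the package targets.

Each gas-chromatograph measurement withdraws a syringe volume *v*ₛ
(default 2 mL) at bottle pressure. Withdrawal is modeled as instantaneous,
isothermal, and well-mixed at fixed headspace volume, so each sampling
multiplies the pressure by (1 − *v*ₛ/*V*); observation *i* is taken after
*i* prior withdrawals. The correction is discrete (per sampling event),
matching the discrete protocol, and conserves the molar budget of a
non-consumed tracer exactly: withdrawn + remaining = initial.

Dissolved gas re-equilibration between headspace and medium during an
incubation interval is ignored in the budget; the dissolved pool enters
only as the substrate axis of the kinetics analysis. No fugacity or
humidity corrections are applied.

### Henry's-law calibration

The CH₄ solubility constant is anchored so that 250 nM dissolved
corresponds exactly to 159.3 p.p.m.v. at 20 °C and 1.013 bar, giving
*k*H = 1.5492 × 10⁻³ mol L⁻¹ bar⁻¹; this reproduces the full conversion
table (2.98/50/100/250 nM ↔ 1.9/31.9/63.7/159.3 p.p.m.v.) to printed
rounding. Anchoring to the published conversion, rather than adopting any
particular handbook value, makes the conversion table itself the ground
truth. Other temperatures are reached with a van 't Hoff coefficient of
1900 K for CH₄; the H₂, CO, O₂, CO₂, and N₂ constants are standard
compilation values. All of these live in `src/airmob/data/gases.yaml` and
can be overridden by a user registry file.

## First-order kinetics

Consumption of a trace gas by a filter culture is pseudo-first-order.
The rate constant is estimated by ordinary least squares on the integrated
rate law, ln *C*ₜ = ln *C*₀ − *k t* — a deterministic, closed-form fit that
is exact on noiseless exponential data and reduces to
*k* = ln(*C*₁/*C*₂)/(*t*₂ − *t*₁) for two points.

The fit uses **mixing ratios**, not sampling-corrected molar amounts:
a syringe withdrawal removes all gases in proportion, so the mixing ratio
is invariant under sampling and carries the pure consumption signal,
whereas corrected molar amounts contain step drops at each sampling that
would be mis-attributed to consumption. The pressure correction enters
where it belongs — in converting fitted kinetics to molar rates
(mol h⁻¹) and budgets. R² is computed in log space; a constant series has
*k* = 0 and R² defined as 1 (the model fits perfectly). A negative fitted
*k* (net production) is reported with a warning, never clamped, because it
is diagnostic of contamination or desorption.

Rates at atmospheric concentrations are *k* × *n*(*x*atm) with the
registry's atmospheric mixing ratios (CH₄ 1.87, H₂ 0.5, CO 0.2 p.p.m.v.),
and per-cell rates divide by the bead-estimated cell count.

## Michaelis–Menten kinetics and specific affinity

Whole-cell oxidation kinetics *v* = *V*max·*S*/(*K*m + *S*) are fit by
unweighted Levenberg–Marquardt nonlinear least squares (via lmfit), with
start values defaulting to (median *S*, max *v*). The substrate axis is
the dissolved concentration (nM) obtained from the headspace mixing ratio
by Henry's law. Parameters are unconstrained; negative estimates are
flagged rather than bounded away, since they indicate a defective design
rather than a fixable fit. Standard errors come from the estimated
covariance at the optimum. A design spanning less than a 5-fold substrate
range triggers a warning: *K*m and *V*max become collinear there. When all
*S* ≫ *K*m the fit still pins *V*max but reports a large *K*m standard
error — the test suite exercises exactly this failure mode.

The specific affinity *a*⁰A = *V*max(app)/*K*m(app) has units
L cell⁻¹ h⁻¹ directly when *V*max is in nmol cell⁻¹ h⁻¹ and *K*m in nM,
and is invariant under joint rescaling of both parameters. It, not *K*m
alone, is the appropriate single-number measure of performance at trace
concentrations, because in the *S* ≪ *K*m limit the curve reduces to
*v* = *a*⁰A·*S*.

The fit accepts either pooled multi-interval observations or per-interval
rates; rates derived from depletion over an interval should use the
interval-mean concentration as *S* (the simplest consistent estimator).

## Reaction energetics

In-situ Gibbs energy changes use Δr*G* = Δr*G*° + *RT* ln *Q*r
(*R* = 8.3145 × 10⁻³ kJ mol⁻¹ K⁻¹) for

- CH₄ + 2 O₂ → CO₂ + 2 H₂O(l)
- 2 H₂ + O₂ → 2 H₂O(l)
- 2 CO + O₂ → 2 CO₂

Gas activities are partial pressures in bar against a 1 bar standard
state; liquid water has activity 1. All quantities are normalized per mole
of the trace gas, so the Eq. identity holds on the stored fields of every
`ReactionEnergetics` (the reaction quotient is stored with the same
normalization). Element balance (C, H, O) is validated on construction of
every `Reaction`.

Formation energies default to CRC-table values — CH₄(g) −50.5, CO₂(g)
−394.4, H₂O(l) −237.1, CO(g) −137.2, H₂/O₂ 0 kJ mol⁻¹ — and the
temperature dependence of Δr*G*° itself is neglected across 293–298 K.
With these defaults, CH₄ oxidation at 20 °C, 1.013 bar, and atmospheric
composition gives −797.45 kJ mol⁻¹. The analogous computed values are
≈ −199.9 kJ per mol H₂ and ≈ −236.8 kJ per mol CO. Published per-gas
figures of −236.8 (H₂) and −199.9 (CO) kJ mol⁻¹ circulate with the
assignments the other way around; the thermodynamics here supports the
swapped attribution (H₂ oxidation to liquid water has Δr*G*° = −237.1 and
loses ~37 kJ to dilution; CO oxidation has Δr*G*° = −257.2 and loses
~20 kJ), so the package always reports its computed values and does not
hard-code either printed number. Whether two-electron gases are normalized
per mole of gas or per reaction-as-written matters by a factor of two;
per mole of gas is used, which reproduces the magnitudes above.

These energies are catabolic potentials only: no accounting for the
activation cost of CH₄ by the methane monooxygenase, enzyme synthesis, or
proton-motive-force efficiency.

### Energy yields and maintenance

Per-cell yield is rate × |Δr*G*| × 10³ J cell⁻¹ h⁻¹, summed over gases;
an endergonic Δr*G* is refused outright. Per carbon-mole,
*y* = total × 10⁻³ / (*m*dry·*f*C/12.011) kJ C-mol⁻¹ h⁻¹ with dry mass in
fg. The carbon fraction is a required user input in quantitative work;
the convenience default of 0.48 g g⁻¹ is a typical bacterial composition,
not a measurement, and warns loudly when used.

Maintenance benchmarks (default 2.8 kJ C-mol⁻¹ h⁻¹ at 20 °C) are moved
across temperature with an Arrhenius factor,
*m*(*T*) = *m*(*T*ref)·exp(−(*E*ₐ/*R*)(1/*T* − 1/*T*ref)), with
*E*ₐ = 69.4 kJ mol⁻¹ — the constant that makes 4.5 kJ C-mol⁻¹ h⁻¹ at
25 °C correspond to 2.8 at 20 °C. The conversion round-trips to 10⁻¹⁰
relative. `fold_below_maintenance` reports the min/max of
maintenance/yield over a set of strains.

## Cell counting and dry mass

The bead estimator *x*filter = (*b*abs/*b*c)·*x*c is unbiased because
beads and cells are acquired at the same fraction; it is invariant under
subsampling both counts by a common factor. Records with more beads
counted than added are rejected as inconsistent.

Dry mass uses the two-fluid buoyant-mass identity
*m*dry = (ρD₂O·*m*b,H₂O − ρH₂O·*m*b,D₂O)/(ρD₂O − ρH₂O), with default
fluid densities 1.0043 and 1.1033 g cm⁻³ (H₂O- and D₂O-based PBS at
20 °C). The population statistic is the **median** of each single-cell
buoyant-mass distribution, taken before the identity — the instrument
measures two separate aliquots, so cells cannot be paired individually.
A negative dry mass is flagged, not clipped: it indicates mis-specified
densities or swapped aliquots.

## Isotope enrichment

at% ¹⁵N = 100·¹²C¹⁵N⁻/(¹²C¹⁵N⁻ + ¹²C¹⁴N⁻) per region of interest, with
counts summed over acquisition cycles before the ratio (ratio of sums is
the lower-variance estimator for counts). Inputs are assumed dead-time-
and QSA-corrected upstream; instrument corrections are out of scope. A
cell is "labeled" when strictly above baseline mean + 3 SD (default
baseline 0.369 ± 0.043 at%); 3 SD is the conventional detection limit.
`headspace_label_fraction` predicts the headspace at% after adding labeled
N₂ to an air headspace by volume-proportional mixing (200 mL air headspace
holds ≈ 156 mL N₂; adding 50 mL of 98 at% label gives ≈ 24 at%, a value
that can drop toward 23 at% with pressure adjustment or incomplete
flushing — both exposed as parameters, neither forced).

## Synthetic data

The generators emulate the statistical structure the estimators assume:

- **Incubations**: *C*(*t*) = *C*₀·e^(−*kt*) on a 6-point, 120 h schedule
  with ~5 p.p.m.v. spikes, perturbed by multiplicative log-normal noise
  (default sd 2%). Multiplicative noise reflects roughly proportional GC
  error and keeps log-space fitting well-specified — on real data a
  detector noise floor at very low mixing ratios would violate this.
- **Kinetics tables**: Michaelis–Menten rates on the incubation
  concentration grid (1.9–175 p.p.m.v. → ≈ 3–275 nM dissolved), 5% noise.
- **Buoyant masses**: log-normal single-cell dry masses (median = true
  value, CV 30%), converted per fluid via
  *m*b = *m*dry(1 − ρfluid/ρdry) with dry density 1.4 g cm⁻³, plus 1%
  measurement noise; two independent aliquots.
- **Bead mixtures**: independent binomial subsampling of beads and cells
  at a common acquisition fraction (10% default).

Each scenario draws from a single `numpy.random.Generator` seeded in its
config, so identical seeds reproduce datasets bit-for-bit. Monte-Carlo
checks in the test suite use 50–500 seeded replicates per estimator —
sizes at which the sampling error of the checked mean/median is several
times smaller than the asserted tolerance. What passing shows: the
estimators are unbiased/accurate under the assumed noise models at
realistic noise levels. What it does not show: robustness to drifting GC
baselines, correlated residuals, bimodal cell populations, inactive-cell
fractions, or cytometry gating errors — none of which the generators
simulate.

## Numerical choices and edge cases

- Log-linear fitting refuses non-positive mixing ratios with guidance to
  truncate the series at depletion (the alternative — dropping points
  silently — hides information loss).
- Zero reactant partial pressure makes ln *Q*r diverge and raises a
  dedicated error instead of returning ±inf.
- Bottle pressures outside (0.5, 2.0) bar are rejected as physically
  implausible for crimp-sealed incubations.
- Fluid densities outside (0.9, 1.3) g cm⁻³ are rejected; the D₂O-based
  fluid must be the denser one.
- Table readers are strict by default (malformed rows raise with line
  numbers); `--no-strict` drops them with a logged warning instead.

## Known limitations

- The first-order model assumes a constant active population; declining
  activity during long incubations biases *k* downward.
- Interval-mean substrate concentrations slightly bias Michaelis–Menten
  fits when depletion within an interval is large.
- Energy yields assume every counted cell contributes to the observed
  oxidation; inactive cells inflate the apparent per-cell economy.
- The dissolved-phase pool is not tracked dynamically; for the bottle
  geometries used (headspace ≫ dissolved inventory for CH₄/H₂/CO) the
  error is negligible, but it would matter for highly soluble gases.
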