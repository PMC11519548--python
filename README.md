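# airmob

Quantitative analysis of trace-gas oxidation by atmospheric methane-oxidizing
bacteria (atmMOB) — methanotrophs that grow with air as their sole energy,
carbon, and nitrogen source. The package takes the measurements such studies
produce (closed-bottle headspace gas time series, bead-spiked flow-cytometry
counts, paired buoyant masses, whole-cell kinetics tables, secondary-ion
isotope counts) and turns them into the physiological quantities of interest:
oxidation rate constants, per-cell rates, in-situ Gibbs free energies, energy
yields per cell and per carbon-mole of biomass, Michaelis–Menten specific
affinities, and ¹⁵N enrichment calls. A synthetic-data module generates
inputs with the same statistical structure, so the whole chain is testable
without instrument data.

## The analysis chain

**Headspace budget.** A closed bottle (headspace volume *V*, pressure *P*,
temperature *T*) holds *n* = *x*·10⁻⁶·*PV*/(*RT*) mol of a trace gas at
mixing ratio *x* p.p.m.v. Each syringe withdrawal of volume *v*ₛ multiplies
the pressure by (1 − *v*ₛ/*V*); molar budgets use the corrected pressure at
each time point. Dissolved concentrations follow Henry's law,
*C* = *k*H(*T*)·*p*gas, with the CH₄ constant calibrated so 250 nM dissolved
corresponds to 159.3 p.p.m.v. at 20 °C and 1.013 bar.

**Kinetics.** Consumption is pseudo-first-order: ln *C*ₜ = ln *C*₀ − *k t*,
fit by ordinary least squares in log space. The bottle-level rate at any
mixing ratio is *k*·*n*(*x*); dividing by the cell count (from the bead
estimator *x*filter = (*b*abs/*b*c)·*x*c) gives per-cell rates. Whole-cell
Michaelis–Menten kinetics *v* = *V*max·*S*/(*K*m + *S*) are fit by
Levenberg–Marquardt, and the specific affinity — the oligotrophy metric —
is *a*⁰A = *V*max(app)/*K*m(app) (L cell⁻¹ h⁻¹).

**Energetics.** In-situ reaction energies come from
Δr*G* = Δr*G*° + *RT* ln *Q*r with gas activities taken as partial pressures
in bar and liquid-water activity 1, normalized per mole of trace gas.
Per-cell energy yield is rate × |Δr*G*|; dividing by carbon-moles per cell
(*m*dry·*f*C/12.011, with dry mass from two-fluid buoyant masses,
*m*dry = (ρD₂O·*m*b,H₂O − ρH₂O·*m*b,D₂O)/(ρD₂O − ρH₂O)) expresses it in
kJ C-mol⁻¹ h⁻¹, comparable against maintenance-energy benchmarks scaled
across temperature by an Arrhenius relation (*E*ₐ = 69.4 kJ mol⁻¹).

**Isotopes.** ¹⁵N enrichment per cell is
at% ¹⁵N = 100·¹²C¹⁵N⁻/(¹²C¹⁵N⁻ + ¹²C¹⁴N⁻), classified against an unlabeled
baseline (0.369 ± 0.043 at%) at mean + 3 SD.

## Worked example

Simulate a trace-gas incubation (true rate constants 0.03, 0.05, and
0.04 h⁻¹ for CH₄, H₂, CO; 2% gas-chromatograph noise) and fit it:

```sh
airmob --seed 7 --out demo simulate
airmob --seed 7 --out demo rates --input demo/timeseries.csv
```

```
bottle_id gas  k_per_h  c0_ppmv  r_squared  n_obs  rate_mol_per_h_at_atm
    sim-7 CH4 0.030187 5.017521   0.999983      6           4.863538e-10
    sim-7  H2 0.050028 5.027523   0.999959      6           2.155174e-10
    sim-7  CO 0.040079 4.991126   0.999936      6           6.906303e-11
```

The fitted `k_per_h` recover the configured constants within the noise, and
`rate_mol_per_h_at_atm` is the consumption each bottle would sustain at the
atmospheric mixing ratio of the gas (1.87, 0.5, and 0.2 p.p.m.v.).

```sh
airmob --out demo energy
```

```
gas  delta_g0_kj_per_mol  reaction_quotient  delta_g_kj_per_mol  temperature_k
CH4               -818.1       4.772071e+03         -797.454046         293.15
 H2               -237.1       4.290844e+06         -199.876275         293.15
 CO               -257.2       4.346625e+03         -236.781651         293.15
```

At atmospheric composition and 20 °C, oxidizing one mole of CH₄ conserves
797.5 kJ — the dilution of the trace gases costs 20–37 kJ mol⁻¹ relative to
standard state (the positive *RT* ln *Q*r term).

```sh
airmob --seed 7 --out demo affinity --input demo/mm_observations.csv
```

```
strain  km_app_nM  vmax_app_nmol_per_cell_h  specific_affinity_L_per_cell_h ...
   sim  48.857739              4.898453e-08                    1.002595e-09
```

The fit recovers the configured kinetics (*K*m 48.54 nM, *V*max
4.91 × 10⁻⁸ nmol cell⁻¹ h⁻¹) and reports the specific affinity
≈ 1.0 × 10⁻⁹ L cell⁻¹ h⁻¹: each cell clears about a nanoliter of medium of
CH₄ per hour.

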