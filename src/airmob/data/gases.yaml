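# Default physical registry for the trace-gas analysis.
#
# formation_energies: standard Gibbs free energies of formation (kJ mol-1,
#   298.15 K, 1 bar; liquid water as "H2O(l)").  CRC Handbook values.
# gases: Henry's-law solubility constant (mol L-1 bar-1 at t_ref K) with a
#   van 't Hoff temperature coefficient (K), and the default atmospheric
#   mixing ratio (p.p.m.v.).  The CH4 constant is calibrated so that
#   250 nM dissolved corresponds to 159.3 p.p.m.v. at 20 C and 1.013 bar;
#   the remaining constants follow the Sander compilation.
formation_energies:
  CH4: -50.5
  O2: 0.0
  H2: 0.0
  CO: -137.2
  CO2: -394.4
  "H2O(l)": -237.1
gases:
  CH4:
    henry_constant: 1.5492e-3
    henry_t_ref: 293.15
    henry_van_t_hoff: 1900.0
    atm_mixing_ratio: 1.87
  H2:
    henry_constant: 7.7e-4
    henry_t_ref: 298.15
    henry_van_t_hoff: 500.0
    atm_mixing_ratio: 0.5
  CO:
    henry_constant: 9.7e-4
    henry_t_ref: 298.15
    henry_van_t_hoff: 1300.0
    atm_mixing_ratio: 0.2
  O2:
    henry_constant: 1.3e-3
    henry_t_ref: 298.15
    henry_van_t_hoff: 1500.0
    atm_mixing_ratio: 209000.0
  CO2:
    henry_constant: 3.3e-2
    henry_t_ref: 298.15
    henry_van_t_hoff: 2400.0
    atm_mixing_ratio: 400.0
  N2:
    henry_constant: 6.4e-4
    henry_t_ref: 298.15
    henry_van_t_hoff: 1300.0
    atm_mixing_ratio: 780900.0
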