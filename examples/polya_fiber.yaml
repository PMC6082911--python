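# Nucleated fiber co-assembly: trimeric nucleus, published 25 °C constants
# (k_n+ = k_e+ = 7e4 /M/min, nucleus K_D = 100 uM, elongation K_D = 1 uM).
# Usable with:  thmap fluxes --config examples/polya_fiber.yaml --out fluxes.csv
#          or:  thmap simulate/synth with the acquisition fields below.
mechanism:
  kind: goldstein_stryer
  s: 3
  N_max: 100
  tie_forward_rates: true
  nucleation:
    forward: {k_ref: 7.0e4, T_ref_C: 25.0}
    reverse: {k_ref: 7.0,   T_ref_C: 25.0, dH_act: 2.0e5}
  elongation:
    forward: {k_ref: 7.0e4, T_ref_C: 25.0}
    reverse: {k_ref: 0.07,  T_ref_C: 25.0, dH_act: 2.0e5}
C_T: 5.0e-5
temperature_C: 25.0
scan_rates: [0.2, 0.5, 1.0, 2.0, 3.0, 4.0]
T_range: [2.0, 65.0]
hold: 5.0
directions: [anneal]
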