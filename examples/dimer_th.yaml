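# Strongly hysteretic reversible dimerisation at 1 mM strands.
# Usable with:  thmap simulate --config examples/dimer_th.yaml --out out/
#          or:  thmap synth    --config examples/dimer_th.yaml --out out/
mechanism:
  kind: one_step
  N: 2
  steps:
    - forward: {k_ref: 0.005, T_ref_C: 50.0, dH_act: -2.0e5}
      reverse: {k_ref: 0.005, T_ref_C: 50.0, dH_act: 3.0e5}
C_T: 1.0e-3
scan_rates: [0.5, 1.0, 2.0]
T_range: [0.0, 85.0]
hold: 10.0
noise_sd: 0.002
seed: 1
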