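# thmap — mapping supramolecular assembly energy landscapes by thermal hysteresis

Supramolecular assemblies — tetramolecular G-quadruplexes, nucleic-acid
fibers, amyloids, capsids — form through transient, weakly populated
intermediates that are hard to observe directly. When melting and annealing
curves are scanned faster than the system can relax, the two branches
separate (*thermal hysteresis*), and the size of the lag encodes the
assembly and disassembly kinetics. `thmap` implements the multi-scan-rate
thermal-hysteresis (TH) analysis of that lag:

1. **Preprocess** raw temperature–signal traces into fraction-unfolded
   curves θ_U(T) by linear-baseline correction, with Savitzky–Golay
   smoothed derivatives.
2. **Model-free analysis.** Each curve gives instantaneous rates
   d[M]/dt = C_T·(dθ_U/dT)·(dT/dt); pooling scan rates builds a 3-D
   temperature–concentration–rate surface. Under strong hysteresis the
   annealing branch obeys d[M]/dt ≈ −k_on[M]^n, so an isothermal ln–ln
   slice has slope *n* (the effective assembly order) and intercept
   ln k_on; the melting branch gives the disassembly order *m* from
   ln(d[M]/dt) vs ln(C_T−[M]). Orders are resolved every 0.5 °C across
   the whole transition.
3. **Forward simulation** of explicit mechanisms under arbitrary
   temperature programs: one-step N-mer, step-wise monomer addition,
   dimer-of-dimers, and open-ended nucleated polymerisation
   (Goldstein–Stryer type: nucleation constants k_n± below the critical
   nucleus size *s*, elongation constants k_e± above it, explicit
   oligomers to N_max with a two-moment closure for longer fibers). Rate
   constants follow ln k(T) = ln k_ref − (ΔH‡/R)(1/T − 1/T_ref) +
   (ΔCp‡/R)(T_ref/T − 1 + ln(T/T_ref)).
4. **Global fitting** (`THKineticModel.fit()` → `THKineticResults`, in the
   statsmodels mould) of mechanisms to all traces simultaneously in θ_U
   space, with asymptotic standard errors, AIC model comparison
   (AIC = n·ln(RSS/n) + 2p, relative likelihood e^{(AICmin−AIC)/2}) and a
   nucleus-size scan.
5. **Flux analysis.** For polymerisation, monomer consumption decomposes
   into per-oligomer fluxes Φ_N = k⁺c₁c_N − k⁻c_{N+1} with
   R = Σ Φ_N = −dc₁/dt, and the effective order is the flux-weighted
   average n = Σ (Φ_N/R)·∂lnΦ_N/∂ln c₁ — linking measured orders to the
   critical nucleus size (canonical scaling laws (s+3)/2 isothermal,
   (s+1)/2 in TH).

It is aimed at biophysical chemists running melting experiments on a
temperature-controlled spectrophotometer who want kinetic mechanism
information without stopped-flow or NMR time series.

## Worked example

```python
import numpy as np
from thmap import (simulate_th_dataset, preprocess_dataset,
                   build_rate_surface, order_profile, effective_order)
from thmap.synth import polya_like_mechanism

# nucleated fiber assembly from published constants: s=3,
# k_n+ = k_e+ = 7e4 /M/min, nucleus K_D = 100 uM, elongation K_D = 1 uM
mech = polya_like_mechanism()

# six-scan-rate annealing design at 50 uM strands, 2-65 °C
ds = simulate_th_dataset(mech, (0.2, 0.5, 1, 2, 3, 4), (2.0, 65.0),
                         C_T=5e-5, holds=5.0, directions=("anneal",))
curves = preprocess_dataset(ds, signal_is_theta=True)
profile = order_profile(build_rate_surface(ds, curves), "anneal")
mid = (profile.temperature >= 24) & (profile.temperature <= 28)
print("model-free n near 25-27 °C:", np.round(profile.order[mid].mean(), 2))

# flux-weighted effective order at 50% monomer consumption, 25 °C
dec = effective_order(mech, C_T=5e-5, temperature_C=25.0)
print("flux-weighted n_eff:", round(dec.n_eff, 2))
print("dominant fluxes N:", dec.sizes[np.argsort(-np.abs(dec.weights))[:5]])
```

prints

```
model-free n near 25-27 °C: 2.19
flux-weighted n_eff: 2.54
dominant fluxes N: [3 1 4 2 5]
```

i.e. mid-transition annealing of this fiber model shows an effective
order between 2 and 3, and the consumption flux runs mainly through
dimers up to ~10-mers — the signature of a trimeric critical nucleus
feeding fiber elongation.

A command-line interface wraps the same library:
`thmap simulate|synth|modelfree|fit|fluxes|survey --config … --out …`.

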