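# Methods

## The measurement and the model-free analysis

A multi-scan-rate thermal-hysteresis (TH) experiment records a
spectroscopic signal while the sample is heated and cooled at several
programmed rates. When the scan outpaces relaxation, melting and
annealing branches separate, and the populations lag behind temperature.
After linear-baseline correction the fraction of subunits that are free
monomers is

θ_U(T) = (signal − folded(T)) / (unfolded(T) − folded(T)),

and the instantaneous monomer release/consumption rate follows from the
chain rule, d[M]/dt = C_T·(dθ_U/dT)·(dT/dt), with dT/dt signed (negative
on cooling). Pooling the curves from all scan rates gives, at every grid
temperature, several ([M], d[M]/dt) pairs — a temperature–concentration–
rate surface.

With assembly order *n* and disassembly order *m* the phenomenological
rate law is d[M]/dt = −k_on[M]ⁿ + k_off·N·((C_T−[M])/N)ᵐ. When
hysteresis is large the assembly term dominates the cooling branch and
the disassembly term the heating branch, so ordinary least squares on
ln(−d[M]/dt) vs ln[M] (anneal) gives *n* and ln k_on, and on
ln(d[M]/dt) vs ln(C_T−[M]) (melt) gives *m* and (1−m)·ln N + ln k_off.
Natural logarithms are used internally; slopes are base-invariant.

**Adequacy heuristics.** The approximations are accepted when the
apparent-Tm separation between matching melt/anneal scans is ≥ 1 °C and
the ratio of |dθ_U/dT| of the slowest annealing scan to the slowest
melting scan, evaluated at the anneal mid-transition temperature, is
≥ 3. We read the published slope heuristic as this anneal-to-melt ratio:
at the anneal mid-transition an equilibrated system would show comparable
slopes on both branches (ratio ≈ 1), while a strongly lagged system shows
a steep anneal branch against an essentially flat melt branch there, so a
large ratio indicates that the single-term approximations are safe.

**Usable-point window.** Slices use points with 0.10 ≤ θ_U ≤ 0.90
(anneal; the mirror window on 1−θ_U for melts), rates above a noise
floor of 10⁻⁴·C_T min⁻¹, and at least two distinct scan rates. The
window and floor are this package's choices; both are configurable.

## Kinetic mechanisms

Four mechanisms are simulated with stiff-capable adaptive integration
(`scipy.integrate.solve_ivp`, BDF; analytic Jacobian sparsity for the
polymerisation model), sampled every 0.5 °C of the program. Default
tolerances are rtol = 10⁻⁸ and atol = 10⁻¹²·C_T; mass (monomer
equivalents) is conserved to better than 10⁻⁸ relative on every
trajectory at these settings.

* **one_step** — N·M ⇌ A_N in a single step. Its constants follow the
  phenomenological convention d[M]/dt = −k_on[M]^N + N·k_off·[A], i.e.
  k_on and k_off absorb stoichiometric factors, so the equilibrium
  constant is [A]/[M]^N = k_on/(N·k_off). This keeps the one-step model
  aligned with the two-term rate law above.
* **stepwise** — sequential monomer addition M ⇌ D ⇌ … ⇌ A_N with
  per-step event fluxes φᵢ = kᵢ⁺c₁cᵢ − kᵢ⁻cᵢ₊₁; the monomer balance
  loses two per dimerisation event.
* **dimer_of_dimers** — M ⇌ D followed by 2D ⇌ A₄.
* **goldstein_stryer** — open-ended nucleated polymerisation. Oligomer
  growth is by monomer addition only. Steps forming species of size ≤ s
  use the nucleation constants k_n±; the nucleus itself adds the next
  monomer at k_e+ and sheds one at k_n−; larger species use k_e±.
  Species are explicit up to N_max (default 100).

**Tail closure.** Fibers beyond N_max are lumped into two moments:
number P and monomer-equivalent mass Q. Tail fibers elongate at k_e+·c₁
and shrink at k_e−; a fiber shrinking at the boundary re-enters the
explicit ladder. The boundary re-entry concentration is estimated as
c_edge = P / max(1, Q/P − N_max), the fraction of tail fibers at minimal
length under a geometric excess-length assumption. This closure is exact
at detailed balance (a geometric equilibrium tail is a fixed point) and
its adequacy is verified by the N_max-doubling test: in sub-saturating
conditions, θ_U(t) with N_max = 100 and 200 agree within 10⁻³.

**Temperature dependence.** Every rate constant follows

ln k(T) = ln k_ref − (ΔH‡/R)(1/T − 1/T_ref) + (ΔCp‡/R)(T_ref/T − 1 + ln(T/T_ref)),

an integrated transition-state-style law whose apparent activation
enthalpy is ΔH‡ + ΔCp‡(T − T_ref). Equilibrium constants derive from
forward/reverse pairs, so van't Hoff behaviour (with ΔCp ≠ 0 when
desired) is automatic. Units: M and minutes; file-facing temperatures in
°C, Kelvin internally.

**Scan programs.** A TH cycle is hold(T_max) → anneal → hold(T_min) →
melt, so each melt starts from its annealed end state exactly as in the
acquisition protocol. Hold defaults are 10 min (millimolar quadruplex
design) and 5 min (50 µM fiber design).

## Global fitting

`THKineticModel` fits a mechanism to all traces of a θ_U dataset
simultaneously with trust-region least squares. Rate constants are
optimised as log₁₀ values, enthalpies linearly, inside generous physical
boxes (±8 log units, ±500 kJ mol⁻¹) that keep the trust region finite.
Standard errors come from the asymptotic covariance
(JᵀJ)⁻¹·RSS/(n−p) at the solution. Model comparison uses the
Gaussian-RSS Akaike criterion AIC = n·ln(RSS/n) + 2p (AICc available)
and relative likelihoods exp((AIC_min − AIC)/2). The nucleus-size scan
refits the nucleated model for each candidate s with shared settings and
ranks by RSS/AIC. Fitting is in θ_U space; the hysteresis diagnostics
warn (but do not block) when the dataset looks near-equilibrium, because
then the parameters are weakly identified.

The integrator tolerance inside the fit objective defaults to 10⁻⁶.
Meaningfully looser tolerances leave a solver-error floor in the
residuals that parameters can absorb: at rtol = 10⁻⁵ a zero-noise
synthetic fit recovers constants only to tens of per cent, at 10⁻⁶ to
0.1 %. For noisy data (σ_θ ≈ 0.01) the noise dominates and 10⁻⁵ is safe;
the test suite uses exactly these settings.

## Flux decomposition and effective orders

For monomer-addition polymerisation the net rate at which the N-mer
grows is Φ_N = k⁺(N)c₁c_N − k⁻(N+1)c_{N+1}. The decomposition reports
monomer-consumption fluxes: the dimerisation event flux is doubled (two
monomers per event; the dimer-pairing step of the dimer-of-dimers model
consumes none), so the total R = ΣΦ_N equals −dc₁/dt exactly — the same
quantity the rate surface measures, which keeps the model-free and
flux-based orders commensurable.

Per-flux orders ∂lnΦ_N/∂ln c₁ are evaluated numerically from paired
trajectories whose total concentration differs by ±Δ/2 (default Δ = 2 %),
compared at matched temperature and matched extent of reaction —
the same variation a multi-scan-rate experiment samples at fixed
temperature. Differences are taken as ratio differences
(ΔΦ_N/Φ̄_N)/(Δc₁/c̄₁); because R is the flux sum for both members of the
pair, the weighted-average identity n_eff = Σ(Φ_N/R)·order_N =
ΔR/R̄/(Δln c₁) holds to round-off by construction. The default
evaluation point is 50 % monomer consumption ("mid-reaction"). Matching
extent rather than elapsed time excludes the initial pre-nucleus
equilibration burst, and in the canonical nucleated regime reproduces
the classical rate ∝ c₀^{(s+3)/2} scaling (half-time argument:
t½ ∝ c₀^{−(s+1)/2} and R ∝ c₀/t½).

**Scaling experiments.** "Canonical nucleated" is operationalised as
k_n+ = k_e+ with the nucleation dissociation constant ≥ 10³-fold weaker
than elongation. Isothermal mode regresses the log mid-reaction rate on
log initial concentration over a 4-fold range (prediction (s+3)/2).
TH mode simulates annealing at 0.2/0.5/1/2 °C min⁻¹, builds the rate
surface, and takes the median log–log slope over slices in which *every*
scan rate lies inside the 0.25–0.75 transition window (prediction
(s+1)/2). Restricting to such fully-populated slices matters: slices
near the annealing onset are dominated by the nucleation burst of the
fastest scan and their apparent slopes diverge; in the developed,
elongation-dominated part of the transition the empirical law holds
within ±0.1 at s = 3.

## Synthetic data

The generator maps simulated θ_U back to signal space through linear
baselines (defaults folded 0.50 + 0.0010·T, unfolded 0.80 + 0.0008·T —
arbitrary but spectroscopically plausible) and adds seeded i.i.d.
Gaussian noise (default σ = 0.002 signal units). Two acquisition designs
are built in: a tetramolecular-quadruplex-like design (1 mM strands,
scan rates 0.2–2 °C min⁻¹, 0–85 °C, 10 min holds, 295 nm) and a
fiber-like design (50 µM strands, 0.2–4 °C min⁻¹, 2–65 °C, 5 min holds,
252 nm, annealing only). Ground truth (noiseless θ_U and the generating
constants) is written alongside the traces. The noise model is i.i.d.
only: no drift, photobleaching or evaporation; passing tests therefore
demonstrate correctness of the analysis chain under ideal instrument
behaviour, not robustness to correlated artefacts. The published
constants are only available at one temperature for the fiber system, so
the built-in designs use this package's own activation enthalpies
(forward barriers ≈ 0, dissociation enthalpies 2×10⁵ J mol⁻¹); analyses
that depend only on 25 °C values (the mid-reaction flux decomposition)
are insensitive to that choice, temperature-resolved order profiles are
not.

**Reference one-step template.** The strongly hysteretic all-or-none
N-mer used for order-recovery tests pins the dissociation constant at
k_off(Tm) = 0.005 min⁻¹ with ΔH‡_off = 3×10⁵ J mol⁻¹ and
ΔH‡_on = −2×10⁵ J mol⁻¹ (negative assembly activation enthalpies are
typical of multimolecular nucleic-acid association). Both branches then
run far from equilibrium at 0.5–2 °C min⁻¹, the regime the single-term
approximations require; with near-equilibrium melts the extracted m is
biased upward by the residual assembly term (we observe m ≈ 1.2–2 there,
which is why the adequacy diagnostics exist).

**Kinetic applicability survey.** The apparent relaxation rate of a
dimerisation at its melting temperature is k_off + 4k⁺[M]_eq (event-rate
k⁺), equal to (3/2)·k_on·C_T in the phenomenological convention; the
survey pins k_on from the requested k_app and a DNA-like dissociation
enthalpy of 2.5×10⁵ J mol⁻¹, then measures the melt-minus-anneal
apparent-Tm shift at 2 °C min⁻¹. The shift is monotone decreasing in
k_app, < 0.05 °C at 10³ min⁻¹, and ≈ 4 °C at 1 min⁻¹ — comfortably above
the ≥ 1 °C usefulness threshold, so 1 min⁻¹ is an order-of-magnitude
upper kinetic limit for the technique.

## Numerical choices and degenerate inputs

* θ_U resampled to a uniform 0.5 °C grid (snapped to multiples of the
  step so all traces share it) before Savitzky–Golay differentiation
  (window 2.5 °C, polyorder 2, polynomial end handling). Polynomials of
  degree ≤ polyorder are differentiated exactly.
* θ_U outside [0, 1] is retained for rate computation (clipping would
  bias derivatives) but excluded from log–log fits; excursions beyond a
  configurable tolerance (default 0.25) raise a data error.
* Baselines intersecting inside the window raise a degenerate-denominator
  error; apparent Tm uses the first 0.5-crossing with a warning when the
  curve crosses more than once; curves that never cross raise.
* Integration failures raise with the segment and solver message;
  concentrations below −10⁻⁶·C_T abort, smaller negative excursions are
  clipped to zero.
* The per-scan-rate temperature-lag correction T_sample = T_block −
  λ·(dT/dt) is available with default λ = 0 (no correction).

## Problem sizes used in the shipped tests

The suite exercises reduced but structurally faithful problems chosen as
routine desk-scale experiments: two to three scan rates instead of six,
N_max = 30–50 for fitted polymerisation models (100 for flux analysis),
a nucleus scan over s ∈ {2, 3, 4}, and isothermal scaling over
s = 1…5. These sizes reproduce every qualitative and quantitative claim
tested while keeping a full run to a few minutes.

## Known limitations

* No fragmentation, coagulation, secondary nucleation or pathway
  competition; monomer-addition topology only.
* The per-flux order pairing is a documented stand-in for a derivative
  whose published derivation is not printed; it is validated by the
  exact weighted-average identity and the canonical scaling laws, but
  other pairings (e.g. matched time) give systematically different
  per-flux orders for polymerisation.
* Baseline correction is linear; strongly curved baselines or
  multi-wavelength unfolding are out of scope.
* Fits assume a shared C_T across traces and i.i.d. Gaussian residuals
  in θ_U; absorbance-space fitting with co-estimated baselines is
  available but not the default.
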