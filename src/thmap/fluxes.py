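"""Per-oligomer flux decomposition and flux-weighted effective orders.

For monomer-addition polymerisation the net rate at which an N-mer binds a
monomer is Φ_N = k⁺(N)·c₁·c_N − k⁻(N+1)·c_{N+1}. The total monomer-
consumption rate is the flux sum R = Σ_N Φ_N, and the effective reaction
order decomposes exactly as a flux-weighted average:

    n_eff = ∂lnR/∂ln c₁ = Σ_N (Φ_N/R)·(∂lnΦ_N/∂ln c₁)

Per-flux orders are evaluated numerically from paired trajectories whose
total concentration differs by a small relative perturbation, compared at
matched temperature and matched extent of reaction (the same variation the
multi-scan-rate experiment samples). Differences are taken as ratio
differences (ΔΦ/Φ̄)/(Δc₁/c̄₁), which makes the weighted-average identity
exact to round-off because R is the flux sum for both members of the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import THConfigurationError, UndefinedOrderError
from .kinetics import (
    C2K,
    MechanismSpec,
    RateLaw,
    SpeciesState,
    StepRates,
    TemperatureProgram,
    rate_constant,
    simulate,
)

__all__ = [
    "FluxDecomposition",
    "compute_fluxes",
    "effective_order",
    "scaling_experiment",
    "canonical_nucleated_mechanism",
]


@dataclass(frozen=True)
class FluxDecomposition:
    """Fluxes Φ_N, total rate R and (optionally) per-flux orders.

    ``sizes[i]`` is the N of flux Φ_N (the oligomer binding the monomer);
    for the nucleated mechanism the last entry is the tail-boundary flux.
    ``weights`` are Φ_N/R; ``orders`` are ∂lnΦ_N/∂ln c₁ and ``n_eff`` their
    flux-weighted average (equal to ∂lnR/∂ln c₁ by construction).
    """

    sizes: np.ndarray
    fluxes: np.ndarray
    total_rate: float
    orders: np.ndarray | None = None
    n_eff: float | None = None

    @property
    def weights(self) -> np.ndarray:
        return self.fluxes / self.total_rate

    def to_frame(self) -> pd.DataFrame:
        data = {"N": self.sizes, "flux": self.fluxes, "weight": self.weights}
        if self.orders is not None:
            data["order"] = self.orders
        return pd.DataFrame(data)


def _flux_vector(mech: MechanismSpec, state: SpeciesState, T_K: float) -> tuple[np.ndarray, np.ndarray]:
    """Monomer-consumption fluxes Ψ_N per step (plus tail terms for the
    nucleated mechanism), so that Σ Ψ_N = −dc₁/dt exactly.

    Each step's event flux Φ_N is scaled by the number of monomers the
    event consumes: 2 for dimerisation, 1 for every other monomer
    addition, 0 for the dimer-pairing step of the dimer-of-dimers
    mechanism (reported but not monomer-consuming). The one-step mechanism
    is already phenomenological (its k_on absorbs stoichiometry).
    """
    c = state.c
    if mech.kind == "goldstein_stryer":
        from .kinetics import _gs_constants, _gs_edge_conc  # shared with the RHS

        M = mech.N_max
        kn_f, kn_r, ke_f, ke_r = _gs_constants(mech, T_K)
        sizes_plus = np.arange(2, M + 1)
        kf = np.where(sizes_plus <= mech.s, kn_f, ke_f)
        kr = np.where(sizes_plus <= mech.s, kn_r, ke_r)
        flux = kf * c[0] * c[: M - 1] - kr * c[1:M]
        flux[0] *= 2.0  # dimerisation consumes two monomers per event
        c_edge = _gs_edge_conc(state.tail_number, state.tail_mass, M)
        boundary = ke_f * c[0] * c[M - 1] - ke_r * c_edge
        # net monomer exchange with tail interiors (edge shrink events belong
        # to the boundary flux); vanishes at detailed balance
        tail_flux = ke_f * c[0] * state.tail_number - ke_r * (state.tail_number - c_edge)
        sizes = np.concatenate([np.arange(1, M), [M, M + 1]])
        return sizes, np.concatenate([flux, [boundary, tail_flux]])
    if mech.kind == "one_step":
        kf = rate_constant(mech.steps[0].forward, T_K)
        kr = rate_constant(mech.steps[0].reverse, T_K)
        return np.array([1]), np.array([kf * c[0] ** mech.N - mech.N * kr * c[1]])
    if mech.kind == "stepwise":
        flux = np.empty(mech.N - 1)
        for i, step in enumerate(mech.steps):
            kf = rate_constant(step.forward, T_K)
            kr = rate_constant(step.reverse, T_K)
            flux[i] = kf * c[0] * c[i] - kr * c[i + 1]
        flux[0] *= 2.0
        return np.arange(1, mech.N), flux
    # dimer_of_dimers: the pairing step consumes no monomers
    k1f = rate_constant(mech.steps[0].forward, T_K)
    k1r = rate_constant(mech.steps[0].reverse, T_K)
    return np.array([1]), np.array([2.0 * (k1f * c[0] ** 2 - k1r * c[1])])


def compute_fluxes(state: SpeciesState, mechanism: MechanismSpec, T: float) -> FluxDecomposition:
    """Per-oligomer monomer-consumption fluxes and the total rate R = −dc₁/dt.

    ``T`` in Kelvin. ``total_rate`` equals the flux sum exactly, which in
    turn equals the instantaneous monomer consumption rate of the
    mechanism's ODEs.
    """
    sizes, flux = _flux_vector(mechanism, state, T)
    return FluxDecomposition(sizes=sizes, fluxes=flux, total_rate=float(flux.sum()))


# ---------------------------------------------------------------------------
# effective order by paired perturbed trajectories


def _state_at_extent(
    mech: MechanismSpec,
    C_T: float,
    T_C: float,
    extent: float,
    rtol: float,
    max_time: float,
) -> SpeciesState:
    """Integrate an isothermal annealing reaction until c₁/C_T = 1 − extent."""
    target = (1.0 - extent) * C_T

    def hit(t, y):
        return y[0] - target

    hit.terminal = True
    hit.direction = -1
    duration = max_time
    for _ in range(6):
        program = TemperatureProgram.isothermal(T_C, duration)
        traj = simulate(mech, program, C_T, initial="monomer", rtol=rtol, events=[hit])
        if traj.y[0, -1] <= target * (1.0 + 1e-6):
            return traj.state_at(traj.y.shape[1] - 1)
        duration *= 4.0
    raise UndefinedOrderError(
        f"reaction did not reach extent {extent} within {duration/4:.3g} min at {T_C} °C"
    )


def effective_order(
    mechanism: MechanismSpec,
    C_T: float,
    temperature_C: float,
    extent: float = 0.5,
    delta: float = 0.02,
    rtol: float = 1e-8,
    max_time: float = 1e3,
) -> FluxDecomposition:
    """Flux-weighted effective order of monomer consumption at mid-reaction.

    Two isothermal annealing trajectories with total concentrations
    C_T·(1 ± δ/2) are integrated from all-monomer initial conditions to the
    same extent of reaction (default 50 % monomer consumption); fluxes are
    compared between the paired states. Raises
    :class:`~thmap.exceptions.UndefinedOrderError` when the total rate
    vanishes at the evaluation point.
    """
    T_K = temperature_C + C2K
    states, fluxes = [], []
    for f in (1.0 + delta / 2.0, 1.0 - delta / 2.0):
        st = _state_at_extent(mechanism, C_T * f, temperature_C, extent, rtol, max_time)
        states.append(st)
        fluxes.append(_flux_vector(mechanism, st, T_K)[1])
    sizes = _flux_vector(mechanism, states[0], T_K)[0]
    phi_hi, phi_lo = fluxes
    phi_bar = 0.5 * (phi_hi + phi_lo)
    R_bar = float(phi_bar.sum())
    if not np.isfinite(R_bar) or abs(R_bar) < 1e-300:
        raise UndefinedOrderError("total rate is zero at the evaluation point")
    c1_hi, c1_lo = states[0].c[0], states[1].c[0]
    dlnc1 = (c1_hi - c1_lo) / (0.5 * (c1_hi + c1_lo))
    with np.errstate(divide="ignore", invalid="ignore"):
        orders = (phi_hi - phi_lo) / phi_bar / dlnc1
    # flux-weighted average == direct total-rate order, exactly:
    n_eff = float((phi_hi - phi_lo).sum() / R_bar / dlnc1)
    return FluxDecomposition(
        sizes=sizes, fluxes=phi_bar, total_rate=R_bar, orders=orders, n_eff=n_eff
    )


# ---------------------------------------------------------------------------
# scaling-law experiments


def canonical_nucleated_mechanism(
    s: int,
    KD_elong: float = 1e-6,
    KD_ratio: float = 1e3,
    k_plus: float = 7e4,
    N_max: int = 60,
    T_ref_C: float = 25.0,
    dH_forward: float = 0.0,
    dH_vant_hoff: float = 3.0e5,
) -> MechanismSpec:
    """Canonical nucleated assembly template: k_n+ = k_e+ and a nucleation
    dissociation constant ``KD_ratio``-fold weaker than elongation.

    ``dH_vant_hoff`` (J mol⁻¹, dissociation enthalpy) sets how steeply the
    elongation equilibrium shifts with temperature, giving a melting
    transition inside the experimental window for TH-mode experiments.
    """
    if KD_ratio < 1e3:
        raise THConfigurationError("canonical nucleated regime requires KD_ratio >= 1e3")
    T_ref = T_ref_C + C2K
    fwd = RateLaw(k_ref=k_plus, T_ref=T_ref, dH_act=dH_forward)
    rev_n = RateLaw(k_ref=k_plus * KD_elong * KD_ratio, T_ref=T_ref, dH_act=dH_forward + dH_vant_hoff)
    rev_e = RateLaw(k_ref=k_plus * KD_elong, T_ref=T_ref, dH_act=dH_forward + dH_vant_hoff)
    return MechanismSpec(
        kind="goldstein_stryer",
        s=s,
        N_max=N_max,
        nucleation=StepRates(forward=fwd, reverse=rev_n),
        elongation=StepRates(forward=fwd, reverse=rev_e),
        tie_forward_rates=True,
    )


def _isothermal_midreaction_rate(
    mech: MechanismSpec, c0: float, T_C: float, rtol: float, extent: float = 0.5
) -> float:
    """Total polymerisation rate at fixed extent of an isothermal annealing run.

    Measuring at matched extent (rather than matched time) removes the
    initial pre-nucleus equilibration burst from the comparison, leaving
    the growth-phase rate that carries the canonical concentration
    scaling.
    """
    st = _state_at_extent(mech, c0, T_C, extent, rtol, max_time=1e3)
    return compute_fluxes(st, mech, T_C + C2K).total_rate


def scaling_experiment(
    s_values: Sequence[int],
    mode: str = "isothermal",
    C_T: float = 5e-5,
    temperature_C: float = 25.0,
    conc_span: float = 4.0,
    n_conc: int = 5,
    scan_rates: Sequence[float] = (0.2, 0.5, 1.0, 2.0),
    T_range: tuple[float, float] = (2.0, 65.0),
    rtol: float = 1e-8,
    mechanism_factory=canonical_nucleated_mechanism,
) -> pd.DataFrame:
    """Fit apparent reaction orders versus nucleus size for nucleated assembly.

    ``isothermal`` mode regresses the log mid-reaction polymerisation rate
    on the log initial monomer concentration across a ``conc_span``-fold
    concentration range (canonical prediction: slope (s+3)/2).
    ``th`` mode simulates multi-scan-rate annealing, builds the rate
    surface and pools the log–log slope of instantaneous rate versus
    instantaneous monomer concentration over mid-transition temperatures
    (empirical prediction: slope (s+1)/2). Returns one row per s with the
    fitted exponent and the deviation from the predicted law.
    """
    rows = []
    for s in s_values:
        mech = mechanism_factory(int(s))
        if mode == "isothermal":
            c_grid = C_T * np.geomspace(1.0 / math.sqrt(conc_span), math.sqrt(conc_span), n_conc)
            lnr = [
                math.log(_isothermal_midreaction_rate(mech, c0, temperature_C, rtol))
                for c0 in c_grid
            ]
            exponent = float(np.polyfit(np.log(c_grid), lnr, 1)[0])
            predicted = (s + 3) / 2.0
        elif mode == "th":
            exponent = _th_mode_exponent(mech, C_T, scan_rates, T_range, rtol)
            predicted = (s + 1) / 2.0
        else:
            raise THConfigurationError("mode must be 'isothermal' or 'th'")
        rows.append(
            {"s": int(s), "mode": mode, "exponent": exponent, "predicted": predicted,
             "deviation": exponent - predicted}
        )
    return pd.DataFrame(rows)


def _th_mode_exponent(mech, C_T, scan_rates, T_range, rtol) -> float:
    from .kinetics import simulate_th_dataset
    from .modelfree import build_rate_surface, order_profile
    from .preprocess import preprocess_dataset

    dataset = simulate_th_dataset(
        mech, scan_rates, T_range, C_T, holds=5.0, directions=("anneal",), rtol=rtol
    )
    curves = preprocess_dataset(dataset, signal_is_theta=True)
    surface = build_rate_surface(dataset, curves)
    profile = order_profile(surface, "anneal", theta_window=(0.25, 0.75))
    if len(profile) == 0:
        raise UndefinedOrderError("no usable mid-transition slices in TH-mode scaling run")
    # mid-transition temperatures proper: every scan rate inside the window,
    # so the slice is not dominated by the nucleation burst of the fastest scan
    full = profile.points_used == len(scan_rates)
    orders = profile.order[full] if full.any() else profile.order
    return float(np.median(orders))
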