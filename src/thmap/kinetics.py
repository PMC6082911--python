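"""Forward simulation of supramolecular assembly under temperature ramps.

Implements four kinetic mechanisms for homomeric assembly:

``one_step``
    N monomers associate in a single step, ``N·M <-> A_N``.
``stepwise``
    Sequential monomer addition up to a finite N-mer,
    ``M <-> D <-> T <-> ... <-> A_N``.
``dimer_of_dimers``
    ``M <-> D`` followed by dimer pairing ``2 D <-> A_4``.
``goldstein_stryer``
    Open-ended nucleated polymerisation: monomer addition with nucleation
    rate constants (k_n±) below the critical nucleus size ``s`` and
    elongation constants (k_e±) above it. Oligomers are tracked explicitly
    up to ``N_max``; longer fibers are lumped into a two-moment tail
    (number and mass) that elongates and shrinks at the elongation rates.

Rate constants follow a transition-state-style integrated law with an
activation enthalpy and an activation heat capacity, so equilibrium
constants (reverse/forward ratios) obey van't Hoff behaviour with
ΔCp ≠ 0 when desired.

Units: concentrations molar (monomer equivalents for totals), time minutes,
file-facing temperatures °C, rate-law temperatures Kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .datasets import THDataset, THTrace
from .exceptions import IntegrationError, THConfigurationError

__all__ = [
    "R_GAS",
    "C2K",
    "RateLaw",
    "StepRates",
    "MechanismSpec",
    "TemperatureProgram",
    "SpeciesState",
    "Trajectory",
    "rate_constant",
    "goldstein_stryer_rhs",
    "simulate",
    "simulate_th_dataset",
    "equilibrium_state",
    "mechanism_from_dict",
]

R_GAS = 8.314  # J mol^-1 K^-1
C2K = 273.15


# ---------------------------------------------------------------------------
# rate laws


@dataclass(frozen=True)
class RateLaw:
    """Temperature-dependent rate constant.

    ln k(T) = ln k_ref − (ΔH‡/R)(1/T − 1/T_ref)
              + (ΔCp‡/R)(T_ref/T − 1 + ln(T/T_ref))

    which reduces to an Arrhenius law for ΔCp‡ = 0 and lets the apparent
    activation enthalpy vary linearly with temperature otherwise:
    ΔH‡(T) = ΔH‡ + ΔCp‡·(T − T_ref).

    Parameters
    ----------
    k_ref : float
        Rate constant at ``T_ref`` (M⁻¹ min⁻¹ for bimolecular steps,
        min⁻¹ for unimolecular ones; M^(1−N) min⁻¹ for an N-molecular
        one-step association).
    T_ref : float
        Reference temperature in Kelvin.
    dH_act : float
        Activation enthalpy at ``T_ref`` in J mol⁻¹.
    dCp_act : float
        Activation heat capacity in J mol⁻¹ K⁻¹.
    """

    k_ref: float
    T_ref: float = 298.15
    dH_act: float = 0.0
    dCp_act: float = 0.0

    def __post_init__(self):
        if not (self.k_ref > 0 and np.isfinite(self.k_ref)):
            raise THConfigurationError("k_ref must be positive and finite")
        if not (self.T_ref > 0):
            raise THConfigurationError("T_ref must be positive (Kelvin)")

    def __call__(self, T: float | np.ndarray) -> float | np.ndarray:
        return rate_constant(self, T)


def rate_constant(law: RateLaw, T: float | np.ndarray) -> float | np.ndarray:
    """Evaluate a :class:`RateLaw` at temperature ``T`` (Kelvin)."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 150.0) or np.any(T > 500.0):
        raise THConfigurationError("temperature outside sanity window (Kelvin expected)")
    lnk = (
        math.log(law.k_ref)
        - (law.dH_act / R_GAS) * (1.0 / T - 1.0 / law.T_ref)
        + (law.dCp_act / R_GAS) * (law.T_ref / T - 1.0 + np.log(T / law.T_ref))
    )
    out = np.exp(lnk)
    if not np.all(np.isfinite(out)):
        raise THConfigurationError("rate constant evaluated to a non-finite value")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StepRates:
    """Forward/reverse rate-law pair for one assembly step."""

    forward: RateLaw
    reverse: RateLaw

    def K_assoc(self, T: float) -> float:
        """Association equilibrium constant k⁺/k⁻ at ``T`` (Kelvin)."""
        return rate_constant(self.forward, T) / rate_constant(self.reverse, T)


# ---------------------------------------------------------------------------
# mechanisms


_KINDS = ("one_step", "stepwise", "dimer_of_dimers", "goldstein_stryer")


@dataclass(frozen=True)
class MechanismSpec:
    """Declarative kinetic mechanism.

    For the finite kinds, ``steps`` holds one :class:`StepRates` per
    assembly step (a single step for ``one_step``; N−1 steps for
    ``stepwise``; two steps — dimerisation then dimer pairing — for
    ``dimer_of_dimers``). For ``goldstein_stryer``, ``nucleation`` and
    ``elongation`` hold the k_n± / k_e± pairs; the critical nucleus of size
    ``s`` binds the next monomer at k_e+ and sheds one at k_n−. With
    ``tie_forward_rates`` the elongation forward law mirrors nucleation
    (k_n+ = k_e+).
    """

    kind: str
    N: int | None = None
    s: int | None = None
    N_max: int = 100
    steps: tuple[StepRates, ...] = ()
    nucleation: StepRates | None = None
    elongation: StepRates | None = None
    tie_forward_rates: bool = False

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise THConfigurationError(f"unknown mechanism kind {self.kind!r}")
        if self.kind == "goldstein_stryer":
            if self.s is None or not (1 <= self.s <= self.N_max):
                raise THConfigurationError("goldstein_stryer needs 1 <= s <= N_max")
            if self.N_max < self.s + 1:
                raise THConfigurationError("N_max must be >= s + 1")
            if self.nucleation is None or self.elongation is None:
                raise THConfigurationError("goldstein_stryer needs nucleation and elongation rates")
            if self.tie_forward_rates:
                object.__setattr__(
                    self, "elongation", replace(self.elongation, forward=self.nucleation.forward)
                )
        else:
            if self.N is None or self.N < 2:
                raise THConfigurationError(f"{self.kind} needs N >= 2")
            expected = {"one_step": 1, "dimer_of_dimers": 2, "stepwise": self.N - 1}[self.kind]
            if len(self.steps) != expected:
                raise THConfigurationError(
                    f"{self.kind} with N={self.N} needs {expected} step(s), got {len(self.steps)}"
                )
            if self.kind == "dimer_of_dimers" and self.N != 4:
                raise THConfigurationError("dimer_of_dimers is a tetramer mechanism (N = 4)")

    # -- species bookkeeping ------------------------------------------------

    def species_sizes(self) -> np.ndarray:
        """Monomer count of each explicitly tracked species (tail excluded)."""
        if self.kind == "one_step":
            return np.array([1, self.N])
        if self.kind == "stepwise":
            return np.arange(1, self.N + 1)
        if self.kind == "dimer_of_dimers":
            return np.array([1, 2, 4])
        return np.arange(1, self.N_max + 1)

    @property
    def n_state(self) -> int:
        """Length of the ODE state vector (explicit species + tail moments)."""
        n = len(self.species_sizes())
        return n + 2 if self.kind == "goldstein_stryer" else n

    @property
    def has_tail(self) -> bool:
        return self.kind == "goldstein_stryer"

    # -- rate-law access ----------------------------------------------------

    def rate_laws(self) -> dict[str, RateLaw]:
        """Named rate laws (``k1+``, ``k1-``, ... or ``kn±``/``ke±``)."""
        if self.kind == "goldstein_stryer":
            return {
                "kn+": self.nucleation.forward,
                "kn-": self.nucleation.reverse,
                "ke+": self.elongation.forward,
                "ke-": self.elongation.reverse,
            }
        laws = {}
        for i, step in enumerate(self.steps, start=1):
            laws[f"k{i}+"] = step.forward
            laws[f"k{i}-"] = step.reverse
        return laws

    def with_rate_laws(self, updates: dict[str, RateLaw]) -> "MechanismSpec":
        """Return a copy with the named rate laws replaced."""
        if self.kind == "goldstein_stryer":
            nuc = StepRates(
                forward=updates.get("kn+", self.nucleation.forward),
                reverse=updates.get("kn-", self.nucleation.reverse),
            )
            elo = StepRates(
                forward=updates.get("ke+", self.elongation.forward),
                reverse=updates.get("ke-", self.elongation.reverse),
            )
            return replace(self, nucleation=nuc, elongation=elo)
        steps = []
        for i, step in enumerate(self.steps, start=1):
            steps.append(
                StepRates(
                    forward=updates.get(f"k{i}+", step.forward),
                    reverse=updates.get(f"k{i}-", step.reverse),
                )
            )
        return replace(self, steps=tuple(steps))


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations of explicit oligomers plus the lumped fiber tail.

    ``c[i]`` is the number concentration (M) of the species whose size is
    ``mechanism.species_sizes()[i]``; ``tail_number``/``tail_mass`` are the
    number (M) and monomer-equivalent mass (M) of fibers beyond ``N_max``.
    """

    c: np.ndarray
    tail_number: float = 0.0
    tail_mass: float = 0.0

    def mass(self, mechanism: MechanismSpec) -> float:
        return float(np.dot(mechanism.species_sizes(), self.c) + self.tail_mass)

    def to_vector(self, mechanism: MechanismSpec) -> np.ndarray:
        if mechanism.has_tail:
            return np.concatenate([self.c, [self.tail_number, self.tail_mass]])
        return np.asarray(self.c, dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray, mechanism: MechanismSpec) -> "SpeciesState":
        y = np.asarray(y, dtype=float)
        if mechanism.has_tail:
            return cls(c=y[:-2].copy(), tail_number=float(y[-2]), tail_mass=float(y[-1]))
        return cls(c=y.copy())


# ---------------------------------------------------------------------------
# right-hand sides


def _gs_constants(mech: MechanismSpec, T: float):
    kn_f = rate_constant(mech.nucleation.forward, T)
    kn_r = rate_constant(mech.nucleation.reverse, T)
    ke_f = rate_constant(mech.elongation.forward, T)
    ke_r = rate_constant(mech.elongation.reverse, T)
    return kn_f, kn_r, ke_f, ke_r


def _gs_edge_conc(P: float, Q: float, N_max: int) -> float:
    # geometric excess-length assumption: fraction of tail fibers sitting at
    # the boundary length N_max+1 is ~ 1/mean-excess, capped at 1
    if P <= 0.0:
        return 0.0
    mu = Q / P - N_max
    return P / max(1.0, mu)


def goldstein_stryer_rhs(
    state: np.ndarray | SpeciesState, T: float, mechanism: MechanismSpec
) -> np.ndarray:
    """Time derivatives of the nucleated-polymerisation state at ``T`` (K).

    Monomer-addition topology only (no fragmentation or coagulation):
    Φ_N = k⁺(N)·c₁·c_N − k⁻(N+1)·c_{N+1}, where k⁺(N) = k_n+ while the
    product (N+1)-mer is at or below the nucleus size s and k_e+ above it
    (so the nucleus itself associates at k_e+), and k⁻(N+1) = k_n− for
    oligomers of size ≤ s (the nucleus dissociates at k_n−), k_e− for
    larger ones. The tail beyond N_max is closed with number (P) and mass
    (Q) balances fed by the boundary flux and per-fiber
    elongation/shrinkage at k_e±.
    """
    y = state.to_vector(mechanism) if isinstance(state, SpeciesState) else np.asarray(state, float)
    M = mechanism.N_max
    s = mechanism.s
    c = y[:M]
    P, Q = max(y[M], 0.0), max(y[M + 1], 0.0)
    kn_f, kn_r, ke_f, ke_r = _gs_constants(mechanism, T)
    c1 = c[0]

    sizes_plus = np.arange(2, M + 1)  # size of the product of step N -> N+1
    kf = np.where(sizes_plus <= s, kn_f, ke_f)
    kr = np.where(sizes_plus <= s, kn_r, ke_r)
    flux = kf * c1 * c[:-1] - kr * c[1:]  # Φ_N for N = 1..M-1

    dy = np.zeros_like(y)
    dy[1:M] += flux
    dy[: M - 1] -= flux
    dy[0] -= flux.sum()  # second monomer consumed by each step

    # tail boundary and moments
    J_in = ke_f * c1 * c[M - 1]
    c_edge = _gs_edge_conc(P, Q, M)
    J_out = ke_r * c_edge
    dy[0] += -J_in - ke_f * c1 * P + ke_r * P
    dy[M - 1] += -J_in + J_out
    dy[M] = J_in - J_out
    dy[M + 1] = (M + 1) * J_in + ke_f * c1 * P - ke_r * P - M * J_out
    return dy


def _finite_rhs(y: np.ndarray, T: float, mech: MechanismSpec) -> np.ndarray:
    c = y
    dy = np.zeros_like(y)
    if mech.kind == "one_step":
        # phenomenological convention: k_on/k_off are the constants of
        # d[M]/dt = -k_on[M]^N + N*k_off*[A], absorbing stoichiometric factors
        N = mech.N
        kf = rate_constant(mech.steps[0].forward, T)
        kr = rate_constant(mech.steps[0].reverse, T)
        rate_M = -kf * c[0] ** N + N * kr * c[1]
        dy[0] = rate_M
        dy[1] = -rate_M / N
    elif mech.kind == "stepwise":
        flux = np.empty(mech.N - 1)
        for i, step in enumerate(mech.steps):
            kf = rate_constant(step.forward, T)
            kr = rate_constant(step.reverse, T)
            flux[i] = kf * c[0] * c[i] - kr * c[i + 1]
        dy[1:] += flux
        dy[:-1] -= flux
        dy[0] -= flux.sum()
    else:  # dimer_of_dimers
        k1f = rate_constant(mech.steps[0].forward, T)
        k1r = rate_constant(mech.steps[0].reverse, T)
        k2f = rate_constant(mech.steps[1].forward, T)
        k2r = rate_constant(mech.steps[1].reverse, T)
        phi1 = k1f * c[0] ** 2 - k1r * c[1]
        phi2 = k2f * c[1] ** 2 - k2r * c[2]
        dy[0] = -2.0 * phi1
        dy[1] = phi1 - 2.0 * phi2
        dy[2] = phi2
    return dy


def mechanism_rhs(y: np.ndarray, T: float, mech: MechanismSpec) -> np.ndarray:
    """Dispatch to the mechanism's right-hand side at temperature ``T`` (K)."""
    if mech.kind == "goldstein_stryer":
        return goldstein_stryer_rhs(y, T, mech)
    return _finite_rhs(y, T, mech)


def _jac_sparsity(mech: MechanismSpec) -> sparse.spmatrix | None:
    if mech.kind != "goldstein_stryer":
        return None
    n = mech.n_state
    M = mech.N_max
    S = sparse.lil_matrix((n, n))
    S[0, :] = 1.0
    S[:, 0] = 1.0
    idx = np.arange(M)
    S[idx, idx] = 1.0
    S[idx[:-1], idx[:-1] + 1] = 1.0
    S[idx[1:], idx[1:] - 1] = 1.0
    for i in (M - 1, M, M + 1):
        for j in (0, M - 1, M, M + 1):
            S[i, j] = 1.0
    return S.tocsr()


# ---------------------------------------------------------------------------
# temperature programs


@dataclass(frozen=True)
class Segment:
    """One program segment: linear ramp (or hold) over ``duration`` minutes."""

    duration: float
    T_start: float  # °C
    T_end: float  # °C

    @property
    def rate(self) -> float:
        """Signed dT/dt in °C min⁻¹ (0 for holds)."""
        return (self.T_end - self.T_start) / self.duration

    def temperature(self, t: float | np.ndarray) -> float | np.ndarray:
        """Temperature (°C) at time ``t`` minutes into the segment."""
        return self.T_start + (self.T_end - self.T_start) * (np.asarray(t) / self.duration)


@dataclass(frozen=True)
class TemperatureProgram:
    """Piecewise-linear temperature protocol (continuous in T)."""

    segments: tuple[Segment, ...]

    def __post_init__(self):
        if not self.segments:
            raise THConfigurationError("program needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.T_end - b.T_start) > 1e-9:
                raise THConfigurationError("temperature program is discontinuous")
        if any(seg.duration <= 0 for seg in self.segments):
            raise THConfigurationError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    @classmethod
    def th_cycle(
        cls,
        T_min: float,
        T_max: float,
        scan_rate: float,
        hold: float = 10.0,
        start: str = "anneal",
        lead_hold: bool = True,
    ) -> "TemperatureProgram":
        """Standard hysteresis cycle: hold, ramp down, hold, ramp up (or melt-first)."""
        ramp = abs(T_max - T_min) / scan_rate
        if start == "anneal":
            segs = []
            if lead_hold:
                segs.append(Segment(hold, T_max, T_max))
            segs += [Segment(ramp, T_max, T_min), Segment(hold, T_min, T_min), Segment(ramp, T_min, T_max)]
        elif start == "melt":
            segs = []
            if lead_hold:
                segs.append(Segment(hold, T_min, T_min))
            segs += [Segment(ramp, T_min, T_max), Segment(hold, T_max, T_max), Segment(ramp, T_max, T_min)]
        else:
            raise THConfigurationError("start must be 'anneal' or 'melt'")
        return cls(tuple(segs))

    @classmethod
    def isothermal(cls, T: float, duration: float) -> "TemperatureProgram":
        return cls((Segment(duration, T, T),))


# ---------------------------------------------------------------------------
# equilibrium initial states


def _gs_equilibrium_mass(c1: float, mech: MechanismSpec, T: float) -> tuple[float, SpeciesState]:
    s = mech.s
    M = mech.N_max
    KDn = rate_constant(mech.nucleation.reverse, T) / rate_constant(mech.nucleation.forward, T)
    KDe = rate_constant(mech.elongation.reverse, T) / rate_constant(mech.elongation.forward, T)
    sizes = np.arange(1, M + 1)
    lnc = np.empty(M)
    lnc[0] = math.log(c1)
    for N in range(2, M + 1):
        KD = KDn if N <= s else KDe
        lnc[N - 1] = lnc[N - 2] + math.log(c1 / KD)
    c = np.exp(lnc)
    r = c1 / KDe
    if r < 1.0:
        # geometric tail sums: sum_{N>M} c_N and sum N c_N
        cM1 = c[-1] * r
        P = cM1 / (1.0 - r)
        Q = cM1 * ((M + 1) - M * r) / (1.0 - r) ** 2
    else:
        P = Q = math.inf
    mass = float(np.dot(sizes, c)) + Q
    return mass, SpeciesState(c=c, tail_number=P, tail_mass=Q)


def equilibrium_state(mech: MechanismSpec, T_kelvin: float, C_T: float) -> SpeciesState:
    """Equilibrium species distribution at temperature ``T_kelvin``.

    Solves the mass balance Σ N·c_N(c₁) = C_T for the free monomer
    concentration by bisection; oligomer concentrations follow from the
    step equilibrium constants (detailed balance).
    """

    def mass_at(c1: float) -> float:
        if mech.kind == "goldstein_stryer":
            return _gs_equilibrium_mass(c1, mech, T_kelvin)[0]
        Ks = [step.K_assoc(T_kelvin) for step in mech.steps]
        if mech.kind == "one_step":
            return c1 + Ks[0] * c1**mech.N  # K = [A]/[M]^N = k_on/(N*k_off)
        if mech.kind == "stepwise":
            total, prod = c1, 1.0
            for i, K in enumerate(Ks, start=2):
                prod *= K
                total += i * prod * c1**i
            return total
        c2 = Ks[0] * c1**2
        c4 = Ks[1] * c2**2
        return c1 + 2 * c2 + 4 * c4

    f = lambda c1: mass_at(c1) - C_T
    hi = C_T
    if f(hi) < 0:  # all-monomer already short of C_T cannot happen; guard anyway
        c1 = C_T
    else:
        lo = C_T * 1e-16
        while f(lo) > 0:
            lo *= 1e-2
            if lo < 1e-300:
                raise THConfigurationError("equilibrium solve failed: no bracket")
        c1 = brentq(f, lo, hi, xtol=1e-300, rtol=1e-14)
    if mech.kind == "goldstein_stryer":
        return _gs_equilibrium_mass(c1, mech, T_kelvin)[1]
    Ks = [step.K_assoc(T_kelvin) for step in mech.steps]
    if mech.kind == "one_step":
        # [A] = (k_on/(N*k_off))*c1^N in the phenomenological convention
        return SpeciesState(c=np.array([c1, Ks[0] / mech.N * c1**mech.N]))
    if mech.kind == "stepwise":
        c = [c1]
        prod = 1.0
        for i, K in enumerate(Ks, start=2):
            prod *= K
            c.append(prod * c1**i)
        return SpeciesState(c=np.array(c))
    c2 = Ks[0] * c1**2
    return SpeciesState(c=np.array([c1, c2, Ks[1] * c2**2]))


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Dense-sampled solution of a temperature-programmed simulation."""

    t: np.ndarray  # minutes
    temperature: np.ndarray  # °C
    y: np.ndarray  # (n_state, n_t)
    segment_index: np.ndarray  # which program segment each sample belongs to
    mechanism: MechanismSpec
    program: TemperatureProgram
    C_T: float

    @property
    def theta_U(self) -> np.ndarray:
        """Fraction of subunits in the free monomeric state, c₁/C_T."""
        return self.y[0] / self.C_T

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_vector(self.y[:, i], self.mechanism)

    def mass_error(self) -> np.ndarray:
        """Relative mass-conservation error at every sample."""
        sizes = self.mechanism.species_sizes()
        n = len(sizes)
        mass = sizes @ self.y[:n]
        if self.mechanism.has_tail:
            mass = mass + self.y[n + 1]
        return np.abs(mass - self.C_T) / self.C_T

    def segment_curve(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """(temperature, θ_U) samples belonging to program segment ``index``."""
        m = self.segment_index == index
        return self.temperature[m], self.theta_U[m]

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.temperature, self.theta_U, ".-")
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel(r"$\theta_U$")
        return ax


def _initial_vector(mech: MechanismSpec, initial, T0_K: float, C_T: float) -> np.ndarray:
    if isinstance(initial, SpeciesState):
        return initial.to_vector(mech)
    if initial == "monomer":
        y0 = np.zeros(mech.n_state)
        y0[0] = C_T
        return y0
    if initial == "equilibrium":
        return equilibrium_state(mech, T0_K, C_T).to_vector(mech)
    raise THConfigurationError(f"unknown initial condition {initial!r}")


def simulate(
    mechanism: MechanismSpec,
    program: TemperatureProgram,
    C_T: float,
    initial: str | SpeciesState = "equilibrium",
    rtol: float = 1e-8,
    atol_factor: float = 1e-12,
    grid_step: float = 0.5,
    method: str = "BDF",
    events: Sequence[Callable] | None = None,
) -> Trajectory:
    """Integrate a mechanism through a temperature program.

    Sampling is every ``grid_step`` °C on ramps (plus a modest time grid on
    holds). ``atol`` is ``atol_factor · C_T``. Raises
    :class:`~thmap.exceptions.IntegrationError` on solver failure or if
    concentrations go negative beyond tolerance.
    """
    jac_sparsity = _jac_sparsity(mechanism)
    T0_K = program.segments[0].T_start + C2K
    y0 = _initial_vector(mechanism, initial, T0_K, C_T)
    atol = atol_factor * C_T

    ts, Ts, ys, seg_ids = [], [], [], []
    t_offset = 0.0
    for si, seg in enumerate(program.segments):
        if abs(seg.T_end - seg.T_start) > 1e-12:
            n = max(2, int(round(abs(seg.T_end - seg.T_start) / grid_step)) + 1)
        else:
            n = max(2, int(round(seg.duration / 0.5)) + 1)
        t_eval = np.linspace(0.0, seg.duration, n)

        def rhs(t, y, seg=seg):
            return mechanism_rhs(y, seg.temperature(t) + C2K, mechanism)

        sol = solve_ivp(
            rhs,
            (0.0, seg.duration),
            y0,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            jac_sparsity=jac_sparsity,
            events=events,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed in segment {si} ({seg.T_start}→{seg.T_end} °C): "
                f"{sol.message}; t={sol.t[-1] if sol.t.size else 0:.3f} min, "
                f"min(y)={y0.min():.3e}"
            )
        t_seg, y_seg = sol.t, sol.y
        hit_event = events is not None and any(len(te) for te in sol.t_events)
        if hit_event:
            # append the event state so the trajectory ends exactly there
            te = min(te[0] for te in sol.t_events if len(te))
            ye = next(ye[0] for te_, ye in zip(sol.t_events, sol.y_events) if len(te_))
            keep = t_seg < te
            t_seg = np.append(t_seg[keep], te)
            y_seg = np.column_stack([y_seg[:, keep], ye])
        ts.append(t_seg + t_offset)
        Ts.append(np.asarray(seg.temperature(t_seg), dtype=float))
        ys.append(y_seg)
        seg_ids.append(np.full(t_seg.size, si))
        y0 = y_seg[:, -1]
        t_offset += seg.duration
        if hit_event:
            break

    y = np.concatenate(ys, axis=1)
    if y.min() < -1e-6 * C_T:
        raise IntegrationError(f"negative concentration beyond tolerance: min={y.min():.3e} M")
    np.clip(y, 0.0, None, out=y)
    return Trajectory(
        t=np.concatenate(ts),
        temperature=np.concatenate(Ts),
        y=y,
        segment_index=np.concatenate(seg_ids),
        mechanism=mechanism,
        program=program,
        C_T=C_T,
    )


def simulate_th_dataset(
    mechanism: MechanismSpec,
    scan_rates: Sequence[float],
    T_range: tuple[float, float],
    C_T: float,
    holds: float = 10.0,
    directions: Sequence[str] = ("anneal", "melt"),
    rtol: float = 1e-8,
    grid_step: float = 0.5,
    label: str = "simulated",
) -> THDataset:
    """Simulate a multi-scan-rate TH dataset of fraction-unfolded curves.

    Each scan rate is run as one chained cycle — equilibrate at the top
    temperature, anneal down, hold, melt up — so the melt starts from the
    annealed end state exactly as in the experimental protocol. Trace
    ``signal`` is θ_U itself.
    """
    T_min, T_max = min(T_range), max(T_range)
    traces = []
    for rate in scan_rates:
        program = TemperatureProgram.th_cycle(T_min, T_max, rate, hold=holds, start="anneal")
        traj = simulate(mechanism, program, C_T, initial="equilibrium", rtol=rtol, grid_step=grid_step)
        # segments: 0 lead hold, 1 anneal ramp, 2 bottom hold, 3 melt ramp
        seg_of = {"anneal": 1, "melt": 3}
        for direction in directions:
            T, theta = traj.segment_curve(seg_of[direction])
            traces.append(
                THTrace(
                    temperature=T,
                    signal=theta,
                    scan_rate=rate,
                    direction=direction,
                )
            )
    return THDataset(traces=traces, C_T=C_T, N=mechanism.N, label=label)


# ---------------------------------------------------------------------------
# config plumbing


def _law_from_dict(d: dict) -> RateLaw:
    T_ref = d.get("T_ref", d["T_ref_C"] + C2K if "T_ref_C" in d else 298.15)
    return RateLaw(
        k_ref=float(d["k_ref"]),
        T_ref=float(T_ref),
        dH_act=float(d.get("dH_act", 0.0)),
        dCp_act=float(d.get("dCp_act", 0.0)),
    )


def mechanism_from_dict(cfg: dict) -> MechanismSpec:
    """Build a :class:`MechanismSpec` from a config mapping (YAML/JSON).

    Finite kinds list their steps under ``steps`` as
    ``[{forward: {...}, reverse: {...}}, ...]``; the nucleated model uses
    ``nucleation``/``elongation`` blocks. Rate-law blocks accept ``k_ref``,
    ``T_ref`` (K) or ``T_ref_C`` (°C), ``dH_act``, ``dCp_act``.
    """
    kind = cfg["kind"]
    if kind == "goldstein_stryer":
        return MechanismSpec(
            kind=kind,
            s=int(cfg["s"]),
            N_max=int(cfg.get("N_max", 100)),
            nucleation=StepRates(
                forward=_law_from_dict(cfg["nucleation"]["forward"]),
                reverse=_law_from_dict(cfg["nucleation"]["reverse"]),
            ),
            elongation=StepRates(
                forward=_law_from_dict(cfg["elongation"]["forward"]),
                reverse=_law_from_dict(cfg["elongation"]["reverse"]),
            ),
            tie_forward_rates=bool(cfg.get("tie_forward_rates", False)),
        )
    steps = tuple(
        StepRates(forward=_law_from_dict(s["forward"]), reverse=_law_from_dict(s["reverse"]))
        for s in cfg["steps"]
    )
    return MechanismSpec(kind=kind, N=int(cfg["N"]), steps=steps)
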