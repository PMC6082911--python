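"""Forward simulation: rate laws, mechanisms, equilibria and the fiber tail."""

import math

import numpy as np
import pytest

from thmap import (
    MechanismSpec,
    RateLaw,
    SpeciesState,
    StepRates,
    THConfigurationError,
    equilibrium_state,
    goldstein_stryer_rhs,
    mechanism_from_dict,
    rate_constant,
    simulate,
    simulate_th_dataset,
)
from thmap.kinetics import C2K, TemperatureProgram
from thmap.preprocess import FractionCurve, apparent_tm
from thmap.synth import polya_like_mechanism


class TestRateConstant:
    def test_reference_temperature_returns_k_ref(self):
        law = RateLaw(k_ref=123.0, T_ref=310.0, dH_act=5e4, dCp_act=-2e3)
        assert rate_constant(law, 310.0) == pytest.approx(123.0, rel=1e-14)

    def test_arrhenius_ratio(self):
        # dH = 100 kJ/mol over a 10 K interval around 298.15 K
        law = RateLaw(k_ref=1.0, T_ref=298.15, dH_act=1e5)
        expected = math.exp((1e5 / 8.314) * (1 / 298.15 - 1 / 308.15))
        assert rate_constant(law, 308.15) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.705, abs=5e-3)

    def test_athermal_law_is_flat(self):
        law = RateLaw(k_ref=7.0)
        T = np.linspace(260.0, 380.0, 20)
        np.testing.assert_allclose(rate_constant(law, T), 7.0, rtol=1e-14)

    def test_heat_capacity_changes_apparent_enthalpy(self):
        # with dCp != 0 the local slope of ln k vs 1/T drifts with temperature
        law = RateLaw(k_ref=1.0, T_ref=300.0, dH_act=1e5, dCp_act=-3e3)
        dT = 0.01

        def local_dH(T):
            lnk1 = math.log(rate_constant(law, T - dT))
            lnk2 = math.log(rate_constant(law, T + dT))
            return -8.314 * (lnk2 - lnk1) / (1 / (T + dT) - 1 / (T - dT))

        assert local_dH(300.0) == pytest.approx(1e5, rel=1e-5)
        assert local_dH(320.0) == pytest.approx(1e5 - 3e3 * 20.0, rel=1e-4)

    def test_kelvin_sanity_window(self):
        with pytest.raises(THConfigurationError):
            rate_constant(RateLaw(k_ref=1.0), 25.0)  # °C passed by mistake


def _irreversible_dimer():
    return MechanismSpec(
        kind="one_step",
        N=2,
        steps=(StepRates(RateLaw(k_ref=1.0), RateLaw(k_ref=1e-12)),),
    )


class TestSimulate:
    def test_dimer_closed_form(self):
        """d[M]/dt = -k[M]^2 integrates to c0/(1 + k c0 t)."""
        traj = simulate(
            _irreversible_dimer(), TemperatureProgram.isothermal(25.0, 1.0), 1.0, initial="monomer"
        )
        assert traj.y[0, -1] == pytest.approx(0.5, rel=1e-6)

    @pytest.mark.parametrize("kind", ["one_step", "stepwise", "dimer_of_dimers", "goldstein_stryer"])
    def test_mass_conservation_all_mechanisms(self, kind, stepwise_mechanism, tetramer_mechanism):
        mech = {
            "one_step": tetramer_mechanism,
            "stepwise": stepwise_mechanism,
            "dimer_of_dimers": _dod_mechanism(),
            "goldstein_stryer": polya_like_mechanism(N_max=30),
        }[kind]
        C_T = 1e-3 if kind != "goldstein_stryer" else 5e-5
        T_range = (0.0, 85.0) if kind != "goldstein_stryer" else (2.0, 65.0)
        prog = TemperatureProgram.th_cycle(*T_range, scan_rate=1.0, hold=5.0)
        traj = simulate(mech, prog, C_T, rtol=1e-8)
        assert traj.mass_error().max() < 1e-8

    def test_one_step_tetramer_long_hold_reaches_equilibrium(self, tetramer_mechanism):
        C_T = 1e-3
        traj = simulate(
            tetramer_mechanism,
            TemperatureProgram.isothermal(50.0, 1e4),
            C_T,
            initial="monomer",
            rtol=1e-10,
        )
        eq = equilibrium_state(tetramer_mechanism, 50.0 + C2K, C_T)
        assert traj.theta_U[-1] == pytest.approx(eq.c[0] / C_T, rel=1e-6)
        # and the distribution obeys K = c4/c1^4 = k_on/(N k_off)
        K = tetramer_mechanism.steps[0].K_assoc(50.0 + C2K) / 4
        assert traj.y[1, -1] == pytest.approx(K * traj.y[0, -1] ** 4, rel=1e-5)

    def test_detailed_balance_stepwise_long_hold(self, stepwise_mechanism):
        """Each step's concentration ratio equals k+/k- after a long hold."""
        T_C = 45.0
        traj = simulate(
            stepwise_mechanism,
            TemperatureProgram.isothermal(T_C, 5e4),
            1e-3,
            initial="monomer",
            rtol=1e-10,
        )
        c = traj.y[:, -1]
        for i, step in enumerate(stepwise_mechanism.steps):
            K = step.K_assoc(T_C + C2K)
            assert c[i + 1] / (c[0] * c[i]) == pytest.approx(K, rel=1e-6)

    def test_negative_duration_rejected(self):
        with pytest.raises(THConfigurationError):
            TemperatureProgram(
                (type(TemperatureProgram.isothermal(25, 1).segments[0])(-1.0, 25.0, 25.0),)
            )


def _dod_mechanism():
    T_ref = 45.0 + C2K
    return MechanismSpec(
        kind="dimer_of_dimers",
        N=4,
        steps=(
            StepRates(RateLaw(k_ref=300.0, T_ref=T_ref, dH_act=-4e4), RateLaw(k_ref=5e3, T_ref=T_ref, dH_act=1.6e5)),
            StepRates(RateLaw(k_ref=2e5, T_ref=T_ref, dH_act=-4e4), RateLaw(k_ref=0.02, T_ref=T_ref, dH_act=2.4e5)),
        ),
    )


class TestGoldsteinStryer:
    def test_isodesmic_equilibrium_is_geometric(self):
        """s = 1 with one set of constants: c_N = c_1 (c_1/K_D)^(N-1)."""
        k, KD = 1e5, 1e-5
        law_f = RateLaw(k_ref=k)
        law_r = RateLaw(k_ref=k * KD)
        mech = MechanismSpec(
            kind="goldstein_stryer",
            s=1,
            N_max=50,
            nucleation=StepRates(law_f, law_r),
            elongation=StepRates(law_f, law_r),
        )
        C_T = 5e-6  # sub-saturating: c1 < K_D
        traj = simulate(
            mech, TemperatureProgram.isothermal(25.0, 1e5), C_T, initial="monomer", rtol=1e-10
        )
        c = traj.y[:-2, -1]
        c1 = c[0]
        expected = c1 * (c1 / KD) ** np.arange(50)
        # the topmost explicit species feels the tail boundary; exempt it
        np.testing.assert_allclose(c[:-1], expected[:-1], rtol=1e-5)
        np.testing.assert_allclose(c, expected, rtol=1e-4)
        # cross-check against the algebraic equilibrium solver
        eq = equilibrium_state(mech, 25.0 + C2K, C_T)
        np.testing.assert_allclose(c[:-1], eq.c[:-1], rtol=1e-5)

    def test_oligomer_number_monotone_without_dissociation(self):
        k = 7e4
        law_f = RateLaw(k_ref=k)
        law_r = RateLaw(k_ref=k * 1e-30)  # effectively irreversible
        mech = MechanismSpec(
            kind="goldstein_stryer",
            s=3,
            N_max=25,
            nucleation=StepRates(law_f, law_r),
            elongation=StepRates(law_f, law_r),
        )
        traj = simulate(
            mech, TemperatureProgram.isothermal(25.0, 50.0), 5e-5, initial="monomer", rtol=1e-9
        )
        total_oligomers = traj.y[1:25, :].sum(axis=0) + traj.y[25, :]
        assert np.all(np.diff(total_oligomers) > -1e-12)

    def test_polya_trimer_never_exceeds_monomer(self):
        """The unstable trimeric nucleus stays below the monomer population."""
        mech = polya_like_mechanism(N_max=40)
        traj = simulate(
            mech, TemperatureProgram.isothermal(25.0, 200.0), 5e-5, initial="monomer", rtol=1e-9
        )
        assert np.all(traj.y[2] <= traj.y[0] + 1e-18)

    def test_tail_closure_insensitive_to_cutoff(self):
        """Doubling N_max leaves theta_U(t) unchanged within 1e-3 (sub-saturating)."""
        def mech(n):
            k, KDn, KDe = 1e5, 1e-4, 2e-5
            return MechanismSpec(
                kind="goldstein_stryer",
                s=2,
                N_max=n,
                nucleation=StepRates(RateLaw(k_ref=k), RateLaw(k_ref=k * KDn)),
                elongation=StepRates(RateLaw(k_ref=k), RateLaw(k_ref=k * KDe)),
            )

        prog = TemperatureProgram.isothermal(25.0, 100.0)
        t1 = simulate(mech(100), prog, 1e-5, initial="monomer", rtol=1e-9)
        t2 = simulate(mech(200), prog, 1e-5, initial="monomer", rtol=1e-9)
        assert np.max(np.abs(t1.theta_U - t2.theta_U)) < 1e-3

    def test_rhs_is_pure_and_mass_free(self):
        mech = polya_like_mechanism(N_max=20)
        state = SpeciesState(
            c=np.full(20, 1e-6), tail_number=1e-8, tail_mass=25 * 1e-8 * 20
        )
        dy = goldstein_stryer_rhs(state, 298.15, mech)
        sizes = np.arange(1, 21)
        mass_rate = sizes @ dy[:20] + dy[21]
        assert abs(mass_rate) < 1e-18  # conservation of monomer equivalents


class TestTHDatasetSimulation:
    def test_scan_rate_ordering_of_apparent_tm(self, tetramer_dataset):
        """Faster scans push melts up and anneals down, monotonically."""
        tms = {}
        for trace in tetramer_dataset.traces:
            curve = FractionCurve.from_trace(trace, trace.signal)
            tms[(trace.direction, trace.scan_rate)] = apparent_tm(curve)
        rates = sorted({r for d, r in tms})
        melt = [tms[("melt", r)] for r in rates]
        anneal = [tms[("anneal", r)] for r in rates]
        assert np.all(np.diff(melt) > 0)
        assert np.all(np.diff(anneal) < 0)
        assert all(m > a for m, a in zip(melt, anneal))

    def test_equilibrium_limit_melt_anneal_coincide(self):
        """As the scan rate vanishes the hysteresis loop closes."""
        mech = _fast_dimer()
        ds = simulate_th_dataset(mech, [0.001], (30.0, 70.0), 1e-3, holds=1.0, grid_step=2.0)
        th = {t.direction: t for t in ds.traces}
        grid = th["melt"].temperature
        anneal_on_grid = np.interp(grid, th["anneal"].temperature, th["anneal"].signal)
        assert np.max(np.abs(th["melt"].signal - anneal_on_grid)) < 0.01

    def test_six_rate_design_yields_nested_anneal_curves(self):
        mech = _fast_dimer(k_scale=1e-3)
        rates = (0.2, 0.3, 0.5, 1.0, 1.5, 2.0)
        ds = simulate_th_dataset(mech, rates, (30.0, 70.0), 1e-3, holds=10.0, directions=("anneal",))
        assert len(ds) == 6
        tms = [apparent_tm(FractionCurve.from_trace(t, t.signal)) for t in ds.traces]
        assert np.all(np.diff(tms) < 0)  # traces ordered by increasing rate


def _fast_dimer(k_scale=1.0):
    T_ref = 50.0 + C2K
    C_T = 1e-3
    k_off = 50.0 * k_scale
    k_on = k_off / (C_T / 2)  # K_D(Tm) = C_T/2 for the phenomenological dimer
    return MechanismSpec(
        kind="one_step",
        N=2,
        steps=(
            StepRates(
                RateLaw(k_ref=k_on, T_ref=T_ref),
                RateLaw(k_ref=k_off, T_ref=T_ref, dH_act=2.5e5),
            ),
        ),
    )


class TestMechanismConfig:
    def test_roundtrip_from_dict(self):
        cfg = {
            "kind": "goldstein_stryer",
            "s": 3,
            "N_max": 40,
            "tie_forward_rates": True,
            "nucleation": {
                "forward": {"k_ref": 7e4, "T_ref_C": 25.0},
                "reverse": {"k_ref": 7.0, "T_ref_C": 25.0, "dH_act": 2e5},
            },
            "elongation": {
                "forward": {"k_ref": 1.0, "T_ref_C": 25.0},
                "reverse": {"k_ref": 0.07, "T_ref_C": 25.0, "dH_act": 2e5},
            },
        }
        mech = mechanism_from_dict(cfg)
        assert mech.s == 3 and mech.N_max == 40
        # forward tie overrides the elongation forward constant
        assert mech.rate_laws()["ke+"].k_ref == 7e4

    def test_invalid_nucleus_rejected(self):
        law = StepRates(RateLaw(k_ref=1.0), RateLaw(k_ref=1.0))
        with pytest.raises(THConfigurationError):
            MechanismSpec(kind="goldstein_stryer", s=0, N_max=10, nucleation=law, elongation=law)
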