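"""Shared fixtures: small simulated datasets reused across test modules.

Simulations are the expensive part of this suite, so heavily reused
datasets are session-scoped. All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from thmap import (
    MechanismSpec,
    RateLaw,
    StepRates,
    THDataset,
    THTrace,
    build_rate_surface,
    preprocess_dataset,
    simulate_th_dataset,
)
from thmap.synth import one_step_reference_mechanism, polya_like_mechanism, tg4t_like_mechanism

_hyp_settings.register_profile("repeatable", derandomize=True, deadline=None)
_hyp_settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def tetramer_mechanism():
    """Strongly hysteretic all-or-none tetramer at millimolar concentration."""
    return one_step_reference_mechanism(4, 1e-3)


@pytest.fixture(scope="session")
def tetramer_dataset(tetramer_mechanism):
    return simulate_th_dataset(
        tetramer_mechanism, (0.5, 1.0, 2.0), (0.0, 85.0), 1e-3, holds=10.0, rtol=1e-8
    )


@pytest.fixture(scope="session")
def tetramer_surface(tetramer_dataset):
    curves = preprocess_dataset(tetramer_dataset, signal_is_theta=True)
    return build_rate_surface(tetramer_dataset, curves)


@pytest.fixture(scope="session")
def stepwise_mechanism():
    return tg4t_like_mechanism()


@pytest.fixture(scope="session")
def stepwise_dataset(stepwise_mechanism):
    """Two-rate noiseless step-wise tetramer dataset (θ_U signal)."""
    return simulate_th_dataset(
        stepwise_mechanism, (0.5, 2.0), (0.0, 85.0), 1e-3, holds=10.0, rtol=1e-8
    )


@pytest.fixture(scope="session")
def polya_mechanism_small():
    """Nucleated poly(A)-fiber mechanism with a reduced explicit cutoff."""
    return polya_like_mechanism(N_max=30)


@pytest.fixture(scope="session")
def zero_noise_stepwise_fit(stepwise_dataset, stepwise_mechanism):
    """Global fit of the generating step-wise model to its own noiseless data.

    The start point is drawn within ~6x of the true rate constants.
    """
    import warnings

    from thmap import THKineticModel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = THKineticModel(stepwise_dataset, stepwise_mechanism, rtol=1e-6, check_hysteresis=False)
        truth = model.start_params()
        rng = np.random.default_rng(0)
        start = truth + rng.uniform(-0.8, 0.8, truth.size)
        result = model.fit(start_params=start)
    return {"model": model, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def noisy_stepwise_dataset(stepwise_dataset):
    """Triplicate noisy θ_U dataset (σ_θ = 0.01) from the step-wise model."""
    rng = np.random.default_rng(2024)
    traces = []
    for rep in range(3):
        for t in stepwise_dataset.traces:
            traces.append(
                THTrace(
                    temperature=t.temperature,
                    signal=t.signal + rng.normal(0.0, 0.01, t.signal.shape),
                    scan_rate=t.scan_rate,
                    direction=t.direction,
                    replicate_id=f"r{rep + 1}",
                )
            )
    return THDataset(traces=traces, C_T=stepwise_dataset.C_T, N=4, label="noisy")


@pytest.fixture(scope="session")
def aic_selection_fits(noisy_stepwise_dataset, stepwise_mechanism):
    """Generating (step-wise) and wrong (dimer-of-dimers) fits to the same data."""
    import warnings

    from thmap import THKineticModel
    from thmap.kinetics import C2K

    T_ref = 45.0 + C2K
    dod = MechanismSpec(
        kind="dimer_of_dimers",
        N=4,
        steps=(
            StepRates(
                RateLaw(k_ref=300.0, T_ref=T_ref, dH_act=-4e4),
                RateLaw(k_ref=5e3, T_ref=T_ref, dH_act=1.2e5),
            ),
            StepRates(
                RateLaw(k_ref=2e5, T_ref=T_ref, dH_act=-4e4),
                RateLaw(k_ref=0.02, T_ref=T_ref, dH_act=2.8e5),
            ),
        ),
    )
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mech in (stepwise_mechanism, dod):
            model = THKineticModel(noisy_stepwise_dataset, mech, rtol=1e-6, check_hysteresis=False)
            fits.append(model.fit())
    return fits


@pytest.fixture(scope="session")
def polya_noisy_dataset(polya_mechanism_small):
    """Noisy (σ_θ = 0.01) two-rate annealing dataset generated with s = 3."""
    from thmap.synth import SynthConfig, generate_dataset

    cfg = SynthConfig(
        mechanism=polya_mechanism_small,
        C_T=5e-5,
        scan_rates=(0.5, 2.0),
        T_range=(2.0, 50.0),
        hold=5.0,
        noise_sd=0.01,
        seed=7,
        directions=("anneal",),
        folded_intercept=0.0,
        folded_slope=0.0,
        unfolded_intercept=1.0,
        unfolded_slope=0.0,
        grid_step=1.0,
    )
    return generate_dataset(cfg)


_GS_FREE_PARAMS = ["kn+.log10_k_ref", "kn-.log10_k_ref", "ke-.log10_k_ref"]


@pytest.fixture(scope="session")
def gs_noisy_fit(polya_noisy_dataset, polya_mechanism_small):
    """Direct s = 3 nucleated-model fit to the noisy dataset (2 SE recovery)."""
    import warnings

    from thmap import THKineticModel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = THKineticModel(
            polya_noisy_dataset,
            polya_mechanism_small,
            free_params=_GS_FREE_PARAMS,
            rtol=1e-5,
            hold=5.0,
            grid_step=1.0,
            check_hysteresis=False,
        )
        truth = model.start_params()
        rng = np.random.default_rng(9)
        result = model.fit(start_params=truth + rng.uniform(-0.3, 0.3, truth.size))
    return {"model": model, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def nucleus_scan_table(polya_noisy_dataset, polya_mechanism_small):
    """Nucleus-size scan on noisy data generated with s = 3."""
    import warnings

    from thmap import nucleus_scan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = nucleus_scan(
            polya_noisy_dataset,
            polya_mechanism_small,
            s_values=(2, 3, 4),
            free_params=_GS_FREE_PARAMS,
            rtol=1e-5,
            hold=5.0,
            grid_step=1.0,
            check_hysteresis=False,
        )
    return table


@pytest.fixture(scope="session")
def isothermal_scaling_table():
    """Canonical nucleated scaling exponents for s = 1..5 (isothermal mode)."""
    from thmap import scaling_experiment

    return scaling_experiment([1, 2, 3, 4, 5], mode="isothermal")


@pytest.fixture(scope="session")
def one_step_order_recovery():
    """Model-free (n, m) medians for simulated one-step N-mers, N = 2..4."""
    import numpy as np

    from thmap import order_profile, preprocess_dataset
    from thmap.modelfree import build_rate_surface as _brs

    out = {}
    for N in (2, 3, 4):
        C_T = 1e-3
        mech = one_step_reference_mechanism(N, C_T)
        ds = simulate_th_dataset(mech, (0.5, 1.0, 2.0), (0.0, 85.0), C_T, holds=10.0, rtol=1e-8)
        curves = preprocess_dataset(ds, signal_is_theta=True)
        surface = _brs(ds, curves)
        pa = order_profile(surface, "anneal", theta_window=(0.2, 0.8))
        pm = order_profile(surface, "melt", theta_window=(0.2, 0.8))
        out[N] = (
            float(np.median(pa.order[pa.points_used == 3])),
            float(np.median(pm.order[pm.points_used == 3])),
        )
    return out


def make_theta_trace(theta_fn, direction="melt", scan_rate=1.0, lo=20.0, hi=80.0, n=121):
    """Trace whose signal is a prescribed θ_U(T)."""
    T = np.linspace(lo, hi, n)
    return THTrace(temperature=T, signal=theta_fn(T), scan_rate=scan_rate, direction=direction)


def sigmoid_theta(tm=50.0, width=5.0):
    return lambda T: 1.0 / (1.0 + np.exp(-(T - tm) / width))
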