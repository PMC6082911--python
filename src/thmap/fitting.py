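"""Global mechanistic fitting of TH datasets with AIC model comparison.

The central object is :class:`THKineticModel`, built from a
fraction-unfolded :class:`~thmap.datasets.THDataset` and a
:class:`~thmap.kinetics.MechanismSpec`. ``fit()`` minimises the summed
squared θ_U residuals over every trace and grid point simultaneously
(trust-region least squares; rate constants optimised as log₁₀ values,
enthalpies linearly) and returns :class:`THKineticResults` with parameter
estimates, asymptotic standard errors, RSS, AIC and a ``summary()`` table.

Model selection uses the Gaussian-RSS form of the Akaike information
criterion, AIC = n·ln(RSS/n) + 2p, and relative likelihoods
exp((AIC_min − AIC)/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datasets import THDataset
from .exceptions import IntegrationError, THConfigurationError
from .kinetics import (
    MechanismSpec,
    RateLaw,
    TemperatureProgram,
    simulate,
)

__all__ = [
    "THKineticModel",
    "THKineticResults",
    "aic_compare",
    "nucleus_scan",
    "akaike_information_criterion",
]

_LAW_FIELDS = ("log10_k_ref", "dH_act", "dCp_act")


def akaike_information_criterion(rss: float, n_points: int, n_params: int, corrected: bool = False) -> float:
    """AIC (optionally AICc) under the Gaussian residual model."""
    aic = n_points * math.log(rss / n_points) + 2 * n_params
    if corrected:
        denom = n_points - n_params - 1
        if denom > 0:
            aic += 2 * n_params * (n_params + 1) / denom
    return aic


def _get_field(law: RateLaw, field: str) -> float:
    if field == "log10_k_ref":
        return math.log10(law.k_ref)
    return getattr(law, field)


def _set_field(law: RateLaw, field: str, value: float) -> RateLaw:
    if field == "log10_k_ref":
        # clamp to avoid float overflow when the optimizer probes far corners
        return replace(law, k_ref=10.0 ** min(max(value, -150.0), 150.0))
    return replace(law, **{field: value})


class THKineticModel:
    """Kinetic mechanism to be fitted globally to a multi-scan-rate dataset.

    Parameters
    ----------
    dataset : THDataset
        Traces whose signal is the fraction unfolded θ_U (use
        :func:`thmap.preprocess.preprocess_dataset` first for raw signals).
    mechanism : MechanismSpec
        Starting mechanism; its rate-law values double as the default
        initial guess.
    free_params : sequence of str, optional
        Parameters to optimise, named ``"<law>.<field>"`` with law keys
        from ``mechanism.rate_laws()`` (``k1+``, ``kn-``, ...) and fields
        ``log10_k_ref``, ``dH_act`` or ``dCp_act``. Default: every law's
        ``log10_k_ref``. With ``tie_forward_rates`` the ``ke+`` entries
        are dropped automatically (they mirror ``kn+``).
    hold : float
        Hold time (min) at the temperature extremes of the reconstructed
        scan programs.
    rtol : float
        Integrator relative tolerance used inside the objective. The
        default is looser than for production simulation; tighten for
        final parameter estimates if needed.
    """

    def __init__(
        self,
        dataset: THDataset,
        mechanism: MechanismSpec,
        free_params: Sequence[str] | None = None,
        hold: float = 10.0,
        rtol: float = 1e-6,
        grid_step: float = 0.5,
        check_hysteresis: bool = True,
        observable: str = "theta",
    ):
        self.dataset = dataset
        self.mechanism = mechanism
        self.hold = hold
        self.rtol = rtol
        self.grid_step = grid_step
        self.observable = observable
        if free_params is None:
            free_params = [f"{k}.log10_k_ref" for k in mechanism.rate_laws()]
        if mechanism.kind == "goldstein_stryer" and mechanism.tie_forward_rates:
            free_params = [p for p in free_params if not p.startswith("ke+.")]
        self.free_params = list(free_params)
        for name in self.free_params:
            law, _, field = name.partition(".")
            if law not in mechanism.rate_laws() or field not in _LAW_FIELDS:
                raise THConfigurationError(f"unknown parameter {name!r}")
        self._n_mech_params = len(self.free_params)
        if observable == "signal":
            # absorbance-space fitting: the four shared linear-baseline
            # coefficients are co-estimated with the kinetic parameters
            from .preprocess import fit_baselines

            ref = min(dataset.traces, key=lambda t: (t.direction != "melt", t.scan_rate))
            bl = fit_baselines(ref)
            self._baseline_start = [
                bl.folded_intercept,
                bl.folded_slope,
                bl.unfolded_intercept,
                bl.unfolded_slope,
            ]
            self.free_params += [
                "baseline.folded_intercept",
                "baseline.folded_slope",
                "baseline.unfolded_intercept",
                "baseline.unfolded_slope",
            ]
        elif observable != "theta":
            raise THConfigurationError("observable must be 'theta' or 'signal'")
        if check_hysteresis and observable == "theta":
            self._warn_if_inadequate()
        # one chained program per scan rate covers both directions; rates
        # without melt traces stop after the annealing ramp
        self._programs = {}
        T_lo = min(t.t_span[0] for t in dataset.traces)
        T_hi = max(t.t_span[1] for t in dataset.traces)
        for rate in dataset.scan_rates():
            full = TemperatureProgram.th_cycle(T_lo, T_hi, rate, hold=self.hold, start="anneal")
            has_melt = any(
                t.direction == "melt" and np.isclose(t.scan_rate, rate) for t in dataset.traces
            )
            program = full if has_melt else TemperatureProgram(full.segments[:2])
            self._programs[rate] = (program, {"anneal": 1, "melt": 3})

    # ------------------------------------------------------------------

    def _warn_if_inadequate(self):
        from .preprocess import FractionCurve, hysteresis_diagnostics, smooth_derivative

        try:
            curves = [
                smooth_derivative(FractionCurve.from_trace(t, t.signal), grid_step=self.grid_step)
                for t in self.dataset.traces
            ]
            report = hysteresis_diagnostics(curves)
            if not report.adequate:
                warnings.warn(
                    f"hysteresis may be inadequate for a well-conditioned global fit "
                    f"(Tm shift {report.tm_shift:.2f} °C, slope ratio {report.slope_ratio:.2f})",
                    stacklevel=3,
                )
        except Exception:
            pass  # diagnostics are advisory only

    def start_params(self) -> np.ndarray:
        laws = self.mechanism.rate_laws()
        mech = [
            _get_field(laws[n.partition(".")[0]], n.partition(".")[2])
            for n in self.free_params[: self._n_mech_params]
        ]
        if self.observable == "signal":
            mech = mech + self._baseline_start
        return np.array(mech)

    def mechanism_at(self, params: np.ndarray) -> MechanismSpec:
        """Mechanism with the free (kinetic) parameters set to ``params``."""
        laws = dict(self.mechanism.rate_laws())
        for name, value in zip(self.free_params[: self._n_mech_params], params):
            key, _, field = name.partition(".")
            laws[key] = _set_field(laws[key], field, float(value))
        return self.mechanism.with_rate_laws(laws)

    def _to_observable(self, trace, theta: np.ndarray, params: np.ndarray) -> np.ndarray:
        if self.observable == "theta":
            return theta
        f0, f1, u0, u1 = params[self._n_mech_params :]
        T = trace.temperature
        folded = f0 + f1 * T
        return folded + ((u0 + u1 * T) - folded) * theta

    def predict(self, params: np.ndarray | None = None) -> list[np.ndarray]:
        """Model θ_U evaluated at each trace's temperatures."""
        mech = self.mechanism_at(params if params is not None else self.start_params())
        out_by_trace = [None] * len(self.dataset.traces)
        for rate, (program, seg_of) in self._programs.items():
            idx = [i for i, t in enumerate(self.dataset.traces) if np.isclose(t.scan_rate, rate)]
            if not idx:
                continue
            traj = simulate(
                mech,
                program,
                self.dataset.C_T,
                initial="equilibrium",
                rtol=self.rtol,
                atol_factor=1e-10,
                grid_step=self.grid_step,
            )
            for i in idx:
                trace = self.dataset.traces[i]
                T, theta = traj.segment_curve(seg_of[trace.direction])
                srt = np.argsort(T)
                out_by_trace[i] = np.interp(trace.temperature, T[srt], theta[srt])
        return out_by_trace

    def residuals(self, params: np.ndarray) -> np.ndarray:
        try:
            preds = self.predict(params)
        except (IntegrationError, THConfigurationError, OverflowError):
            # trust-region step into a pathological corner: return large residuals
            n = sum(t.temperature.size for t in self.dataset.traces)
            return np.full(n, 1e3)
        return np.concatenate(
            [
                t.signal - self._to_observable(t, p, np.asarray(params, float))
                for t, p in zip(self.dataset.traces, preds)
            ]
        )

    # ------------------------------------------------------------------

    def fit(
        self,
        start_params: np.ndarray | None = None,
        bounds: tuple | None = None,
        **least_squares_kwargs,
    ) -> "THKineticResults":
        """Globally fit the mechanism; returns a results object.

        ``bounds`` follows :func:`scipy.optimize.least_squares` (pair of
        arrays in the internal parameter scale). Non-convergence does not
        raise: the best-so-far parameters are returned with
        ``converged=False``.
        """
        x0 = np.asarray(start_params if start_params is not None else self.start_params(), float)
        if bounds is None:
            # unbounded by default: the rate-constant setter clamps overflow,
            # and pathological corners return large finite residuals
            bounds = (-np.inf, np.inf)
        # max_nfev caps runaway trust-region searches; typical converged
        # fits here use ~15 iterations
        kwargs = dict(method="trf", x_scale="jac", max_nfev=100)
        kwargs.update(least_squares_kwargs)
        sol = least_squares(self.residuals, x0, bounds=bounds, **kwargs)
        rss = float(sol.fun @ sol.fun)
        n_points = sol.fun.size
        p = x0.size
        # asymptotic covariance from the Jacobian at the solution
        bse = np.full(p, np.nan)
        try:
            JTJ = sol.jac.T @ sol.jac
            dof = max(n_points - p, 1)
            cov = np.linalg.inv(JTJ) * (rss / dof)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
        at_bound = np.zeros(p, bool)
        lo, hi = np.broadcast_to(np.asarray(bounds[0], float), (p,)), np.broadcast_to(
            np.asarray(bounds[1], float), (p,)
        )
        with np.errstate(invalid="ignore"):
            at_bound = (np.abs(sol.x - lo) < 1e-8) | (np.abs(sol.x - hi) < 1e-8)
        if at_bound.any():
            warnings.warn(
                f"parameters at bounds: {[self.free_params[i] for i in np.nonzero(at_bound)[0]]}",
                stacklevel=2,
            )
        resid = sol.fun
        per_trace, k = [], 0
        for t in self.dataset.traces:
            per_trace.append(resid[k : k + t.temperature.size])
            k += t.temperature.size
        return THKineticResults(
            model=self,
            params=pd.Series(sol.x, index=self.free_params),
            bse=pd.Series(bse, index=self.free_params),
            rss=rss,
            nobs=n_points,
            df_model=p,
            converged=bool(sol.status > 0),
            optimizer_status=sol.status,
            per_trace_residuals=per_trace,
        )


@dataclass
class THKineticResults:
    """Fitted global kinetic model.

    ``params``/``bse`` are in the optimisation scale: log₁₀ for rate
    constants, J mol⁻¹ for enthalpies. ``aic`` uses the Gaussian-RSS form.
    """

    model: THKineticModel
    params: pd.Series
    bse: pd.Series
    rss: float
    nobs: int
    df_model: int
    converged: bool
    optimizer_status: int
    per_trace_residuals: list[np.ndarray]

    @property
    def aic(self) -> float:
        return akaike_information_criterion(self.rss, self.nobs, self.df_model)

    @property
    def aicc(self) -> float:
        return akaike_information_criterion(self.rss, self.nobs, self.df_model, corrected=True)

    @property
    def mechanism(self) -> MechanismSpec:
        """Mechanism with fitted parameter values."""
        return self.model.mechanism_at(self.params.to_numpy())

    def predict(self) -> list[np.ndarray]:
        return self.model.predict(self.params.to_numpy())

    def summary(self) -> str:
        lines = [
            "Global TH kinetic fit",
            "=" * 58,
            f"mechanism:       {self.model.mechanism.kind}"
            + (f" (s={self.model.mechanism.s})" if self.model.mechanism.kind == "goldstein_stryer" else f" (N={self.model.mechanism.N})"),
            f"observations:    {self.nobs}",
            f"free parameters: {self.df_model}",
            f"RSS:             {self.rss:.6g}",
            f"AIC:             {self.aic:.4f}",
            f"converged:       {self.converged}",
            "-" * 58,
            f"{'parameter':<22}{'estimate':>14}{'std err':>14}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<22}{self.params[name]:>14.6g}{self.bse[name]:>14.3g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_report(self) -> dict:
        return {
            "mechanism": self.model.mechanism.kind,
            "free_params": list(self.params.index),
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "rss": self.rss,
            "n_points": self.nobs,
            "n_params": self.df_model,
            "aic": self.aic,
            "converged": self.converged,
        }

    def bootstrap_se(self, n_boot: int = 200, seed: int = 0, **fit_kwargs) -> pd.Series:
        """Seeded residual-bootstrap standard errors.

        Residuals are pooled across traces, resampled with replacement onto
        the fitted observable, and the model is refitted from the point
        estimate for each of ``n_boot`` replicas. Each replica costs a full
        global fit, so large ``n_boot`` is expensive; the asymptotic ``bse``
        is the cheap default.
        """
        from dataclasses import replace as _replace

        rng = np.random.default_rng(seed)
        traces = self.model.dataset.traces
        fitted_obs = [t.signal - r for t, r in zip(traces, self.per_trace_residuals)]
        pooled = np.concatenate(self.per_trace_residuals)
        draws = []
        for _ in range(n_boot):
            new_traces = [
                _replace(t, signal=obs + rng.choice(pooled, size=obs.size, replace=True))
                for t, obs in zip(traces, fitted_obs)
            ]
            ds = THDataset(
                traces=new_traces,
                C_T=self.model.dataset.C_T,
                N=self.model.dataset.N,
                label=self.model.dataset.label,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                replica = THKineticModel(
                    ds,
                    self.model.mechanism,
                    free_params=self.model.free_params[: self.model._n_mech_params],
                    hold=self.model.hold,
                    rtol=self.model.rtol,
                    grid_step=self.model.grid_step,
                    check_hysteresis=False,
                    observable=self.model.observable,
                )
                res = replica.fit(start_params=self.params.to_numpy(), **fit_kwargs)
            draws.append(res.params.to_numpy())
        se = np.std(np.asarray(draws), axis=0, ddof=1)
        return pd.Series(se, index=self.params.index, name="bootstrap_se")

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        preds = self.predict()
        params = self.params.to_numpy()
        for trace, pred in zip(self.model.dataset.traces, preds):
            ax.plot(trace.temperature, trace.signal, ".", ms=3)
            ax.plot(
                trace.temperature,
                self.model._to_observable(trace, pred, params),
                "-", lw=1, color="k", alpha=0.7,
            )
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel(r"$\theta_U$" if self.model.observable == "theta" else "signal")
        return ax


def aic_compare(fits: Sequence[THKineticResults]) -> pd.DataFrame:
    """Rank fitted mechanisms by AIC.

    All fits must score the same observations. The relative likelihood of
    each candidate versus the best model is exp((AIC_min − AIC)/2).
    """
    n = {f.nobs for f in fits}
    if len(n) != 1:
        raise THConfigurationError("fits were scored on different numbers of points")
    rows = []
    aics = [f.aic for f in fits]
    amin = min(aics)
    for f, aic in zip(fits, aics):
        rows.append(
            {
                "mechanism": f.model.mechanism.kind,
                "n_params": f.df_model,
                "rss": f.rss,
                "aic": aic,
                "delta_aic": aic - amin,
                "rel_likelihood": math.exp((amin - aic) / 2.0),
            }
        )
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


def nucleus_scan(
    dataset: THDataset,
    mechanism: MechanismSpec,
    s_values: Sequence[int] = range(1, 8),
    free_params: Sequence[str] | None = None,
    **model_kwargs,
) -> pd.DataFrame:
    """Refit a nucleated-polymerisation mechanism for each candidate nucleus size.

    Returns a table of RSS(s) and AIC(s); the row order is by AIC, and the
    attribute ``best_s`` on the frame gives the winning nucleus size.
    """
    if mechanism.kind != "goldstein_stryer":
        raise THConfigurationError("nucleus_scan needs a goldstein_stryer mechanism")
    if len(dataset.traces) < 2:
        warnings.warn("single-trace dataset: nucleus size may be poorly identifiable", stacklevel=2)
    rows = []
    for s in s_values:
        mech_s = replace(mechanism, s=int(s))
        model = THKineticModel(dataset, mech_s, free_params=free_params, **model_kwargs)
        res = model.fit()
        rows.append({"s": int(s), "rss": res.rss, "aic": res.aic, "converged": res.converged})
    frame = pd.DataFrame(rows)
    frame.attrs["best_s"] = int(frame.loc[frame["rss"].idxmin(), "s"])
    return frame
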