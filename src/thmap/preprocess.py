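"""Baseline correction, fraction-unfolded curves and hysteresis diagnostics.

Raw melting/annealing traces carry linear low-temperature (assembled) and
high-temperature (disassembled) baselines bridged by the thermal
transition. The fraction of subunits that are free monomers,
θ_U(T), is estimated by linear-baseline correction:

    θ_U(T) = (signal − folded(T)) / (unfolded(T) − folded(T))

Derivatives dθ_U/dT are taken with a Savitzky–Golay local-polynomial
filter after resampling to a uniform temperature grid (default 0.5 °C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .datasets import THDataset, THTrace
from .exceptions import BaselineError, THDataError, UndefinedTmError

__all__ = [
    "BaselineModel",
    "FractionCurve",
    "fit_baselines",
    "correct_temperature_lag",
    "compute_fraction_unfolded",
    "smooth_derivative",
    "apparent_tm",
    "hysteresis_diagnostics",
    "HysteresisReport",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class BaselineModel:
    """Linear folded (assembled) and unfolded (free) baselines.

    Lines are ``intercept + slope·T`` with T in °C and signal units on the
    intercepts.
    """

    folded_intercept: float
    folded_slope: float
    unfolded_intercept: float
    unfolded_slope: float
    folded_range: tuple[float, float]
    unfolded_range: tuple[float, float]

    def folded(self, T: np.ndarray) -> np.ndarray:
        return self.folded_intercept + self.folded_slope * np.asarray(T)

    def unfolded(self, T: np.ndarray) -> np.ndarray:
        return self.unfolded_intercept + self.unfolded_slope * np.asarray(T)


@dataclass(frozen=True)
class FractionCurve:
    """θ_U(T) for one trace, optionally with its smoothed derivative."""

    temperature: np.ndarray  # °C, increasing
    theta_U: np.ndarray
    dtheta_dT: np.ndarray | None = None  # °C⁻¹
    scan_rate: float = np.nan  # °C min⁻¹ magnitude
    direction: str = "melt"

    @property
    def signed_scan_rate(self) -> float:
        return self.scan_rate if self.direction == "melt" else -self.scan_rate

    @classmethod
    def from_trace(cls, trace: THTrace, theta: np.ndarray, dtheta=None) -> "FractionCurve":
        return cls(
            temperature=trace.temperature,
            theta_U=np.asarray(theta, dtype=float),
            dtheta_dT=dtheta,
            scan_rate=trace.scan_rate,
            direction=trace.direction,
        )


def correct_temperature_lag(trace: THTrace, lag: float) -> THTrace:
    """Apply a linear scan-rate temperature-lag correction.

    The sample temperature trails the block reading on fast scans:
    T_sample = T_block − λ·(dT/dt), with λ in minutes and dT/dt signed
    (so melts are corrected downward, anneals upward). λ is instrument-
    specific and must be calibrated; the default everywhere is λ = 0.
    """
    if lag == 0.0:
        return trace
    from dataclasses import replace as _replace

    return _replace(trace, temperature=trace.temperature - lag * trace.signed_scan_rate)


def _default_ranges(trace: THTrace, frac: float = 0.15) -> tuple[tuple[float, float], tuple[float, float]]:
    lo, hi = trace.temperature[0], trace.temperature[-1]
    span = hi - lo
    return (lo, lo + frac * span), (hi - frac * span, hi)


def fit_baselines(
    trace: THTrace,
    folded_range: tuple[float, float] | None = None,
    unfolded_range: tuple[float, float] | None = None,
) -> BaselineModel:
    """Ordinary least-squares lines on the folded and unfolded regions.

    Defaults: the lowest and highest 15 % of the trace's temperature span.
    The two ranges must be disjoint and contain at least 3 points each.
    """
    if folded_range is None or unfolded_range is None:
        d_f, d_u = _default_ranges(trace)
        folded_range = folded_range or d_f
        unfolded_range = unfolded_range or d_u
    f_lo, f_hi = sorted(folded_range)
    u_lo, u_hi = sorted(unfolded_range)
    if f_hi > u_lo:
        raise BaselineError("folded and unfolded baseline ranges overlap")
    T, S = trace.temperature, trace.signal
    coeffs = []
    for lo, hi in ((f_lo, f_hi), (u_lo, u_hi)):
        m = (T >= lo) & (T <= hi)
        if m.sum() < 3:
            raise BaselineError(f"baseline range ({lo}, {hi}) °C contains {m.sum()} points; need >= 3")
        slope, intercept = np.polyfit(T[m], S[m], 1)
        coeffs.append((intercept, slope))
    return BaselineModel(
        folded_intercept=coeffs[0][0],
        folded_slope=coeffs[0][1],
        unfolded_intercept=coeffs[1][0],
        unfolded_slope=coeffs[1][1],
        folded_range=(f_lo, f_hi),
        unfolded_range=(u_lo, u_hi),
    )


def compute_fraction_unfolded(
    trace: THTrace, baselines: BaselineModel, clip: bool = False, tol: float = 0.25
) -> FractionCurve:
    """Baseline-correct a trace to θ_U(T).

    With ``clip`` the curve is clamped to [0, 1]; otherwise mild excursions
    (up to ``tol`` beyond the interval, from noise) are retained so rates
    remain unbiased, and larger excursions raise a data error.
    """
    T = trace.temperature
    denom = baselines.unfolded(T) - baselines.folded(T)
    if np.any(np.abs(denom) < 1e-12) or np.any(np.sign(denom) != np.sign(denom[0])):
        raise BaselineError("baseline lines intersect inside the temperature window")
    theta = (trace.signal - baselines.folded(T)) / denom
    if theta.min() < -tol or theta.max() > 1.0 + tol:
        raise THDataError(
            f"theta_U outside [-{tol}, 1+{tol}] — check baseline ranges "
            f"(range {theta.min():.3f}..{theta.max():.3f})"
        )
    if clip:
        theta = np.clip(theta, 0.0, 1.0)
    return FractionCurve.from_trace(trace, theta)


def smooth_derivative(
    curve: FractionCurve,
    window: float = 2.5,
    polyorder: int = 2,
    grid_step: float = 0.5,
) -> FractionCurve:
    """Resample θ_U to a uniform grid and differentiate by local polynomials.

    ``window`` is in °C; it is converted to an odd number of grid points.
    A Savitzky–Golay filter with polynomial interpolation at the ends gives
    both the smoothed curve and dθ_U/dT; polynomials of degree ≤
    ``polyorder`` are reproduced exactly.
    """
    T, th = curve.temperature, curve.theta_U
    span = T[-1] - T[0]
    if window > span:
        raise THDataError(f"smoothing window {window} °C exceeds trace span {span:.3g} °C")
    grid = _snap_grid(T[0], T[-1], grid_step)
    th_g = np.interp(grid, T, th)
    n_win = max(polyorder + 1, int(round(window / grid_step)) | 1)
    n_win = min(n_win, len(grid) if len(grid) % 2 == 1 else len(grid) - 1)
    smooth = savgol_filter(th_g, n_win, polyorder, mode="interp")
    deriv = savgol_filter(th_g, n_win, polyorder, deriv=1, delta=grid_step, mode="interp")
    return replace(curve, temperature=grid, theta_U=smooth, dtheta_dT=deriv)


def _snap_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Uniform grid aligned to multiples of ``step`` (shared across traces)."""
    start = np.ceil(lo / step - 1e-9) * step
    stop = np.floor(hi / step + 1e-9) * step
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def apparent_tm(curve: FractionCurve) -> float:
    """Temperature (°C) at which θ_U crosses 0.5, by linear interpolation.

    Uses the first crossing (warning if several). Raises
    :class:`~thmap.exceptions.UndefinedTmError` when the curve never
    crosses one half.
    """
    th = curve.theta_U - 0.5
    sign_change = np.nonzero(np.diff(np.signbit(th)))[0]
    exact = np.nonzero(th == 0.0)[0]
    if exact.size:
        if sign_change.size + exact.size > 1:
            warnings.warn("theta_U crosses 0.5 more than once; using first crossing", stacklevel=2)
        return float(curve.temperature[exact[0]])
    if sign_change.size == 0:
        raise UndefinedTmError("theta_U never crosses 0.5; apparent Tm undefined")
    if sign_change.size > 1:
        warnings.warn("theta_U crosses 0.5 more than once; using first crossing", stacklevel=2)
    i = sign_change[0]
    T0, T1 = curve.temperature[i], curve.temperature[i + 1]
    y0, y1 = th[i], th[i + 1]
    return float(T0 - y0 * (T1 - T0) / (y1 - y0))


@dataclass(frozen=True)
class HysteresisReport:
    """Adequacy diagnostics for the large-hysteresis approximation.

    ``tm_shift`` is the largest melt-minus-anneal apparent-Tm difference
    over matching scan rates; ``slope_ratio`` compares |dθ/dT| of the
    slowest annealing scan to the slowest melting scan at the anneal
    mid-transition temperature. Adequate when the shift is ≥ 1 °C and the
    ratio ≥ 3.
    """

    tm_shift: float
    tm_shift_per_rate: Mapping[float, float]
    slope_ratio: float
    adequate: bool
    shift_threshold: float = 1.0
    ratio_threshold: float = 3.0


def hysteresis_diagnostics(
    curves: Sequence[FractionCurve],
    shift_threshold: float = 1.0,
    ratio_threshold: float = 3.0,
) -> HysteresisReport:
    """Judge whether hysteresis is large enough for model-free order extraction."""
    melts = [c for c in curves if c.direction == "melt"]
    anneals = [c for c in curves if c.direction == "anneal"]
    if not melts or not anneals:
        raise THDataError("diagnostics need at least one melt and one anneal curve")

    shifts: dict[float, float] = {}
    for an in anneals:
        matching = [m for m in melts if np.isclose(m.scan_rate, an.scan_rate)]
        for me in matching:
            try:
                shifts[an.scan_rate] = apparent_tm(me) - apparent_tm(an)
            except UndefinedTmError:
                continue
    if not shifts:  # fall back: extreme curves regardless of rate pairing
        try:
            shifts[np.nan] = apparent_tm(melts[0]) - apparent_tm(anneals[0])
        except UndefinedTmError:
            shifts[np.nan] = 0.0
    tm_shift = max(shifts.values())

    slow_anneal = min(anneals, key=lambda c: c.scan_rate)
    slow_melt = min(melts, key=lambda c: c.scan_rate)
    ratio = 0.0
    try:
        t_mid = apparent_tm(slow_anneal)
        s_anneal = _slope_at(slow_anneal, t_mid)
        s_melt = _slope_at(slow_melt, t_mid)
        ratio = np.inf if s_melt == 0 else abs(s_anneal) / abs(s_melt)
    except UndefinedTmError:
        ratio = 0.0
    adequate = (tm_shift >= shift_threshold) and (ratio >= ratio_threshold)
    return HysteresisReport(
        tm_shift=float(tm_shift),
        tm_shift_per_rate=shifts,
        slope_ratio=float(ratio),
        adequate=bool(adequate),
        shift_threshold=shift_threshold,
        ratio_threshold=ratio_threshold,
    )


def _slope_at(curve: FractionCurve, T: float) -> float:
    c = curve if curve.dtheta_dT is not None else smooth_derivative(curve)
    return float(np.interp(T, c.temperature, c.dtheta_dT))


def preprocess_dataset(
    dataset: THDataset,
    folded_range: tuple[float, float] | None = None,
    unfolded_range: tuple[float, float] | None = None,
    shared_baselines: bool = False,
    window: float = 2.5,
    polyorder: int = 2,
    grid_step: float = 0.5,
    signal_is_theta: bool = False,
    lag: float = 0.0,
) -> list[FractionCurve]:
    """Run baseline correction + smoothing over every trace of a dataset.

    With ``shared_baselines`` one baseline model (fitted on the slowest
    melt) is applied to all traces. ``signal_is_theta`` skips baseline
    correction for datasets whose signal already is θ_U (e.g. simulated
    ones). ``lag`` applies the scan-rate temperature-lag correction
    (minutes; see :func:`correct_temperature_lag`).
    """
    if lag != 0.0:
        dataset = THDataset(
            traces=[correct_temperature_lag(t, lag) for t in dataset.traces],
            C_T=dataset.C_T,
            N=dataset.N,
            label=dataset.label,
        )
    shared = None
    if shared_baselines and not signal_is_theta:
        ref = min(dataset.traces, key=lambda t: (t.direction != "melt", t.scan_rate))
        shared = fit_baselines(ref, folded_range, unfolded_range)
    curves = []
    for trace in dataset.traces:
        if signal_is_theta:
            fc = FractionCurve.from_trace(trace, trace.signal)
        else:
            bl = shared or fit_baselines(trace, folded_range, unfolded_range)
            fc = compute_fraction_unfolded(trace, bl)
        curves.append(smooth_derivative(fc, window=window, polyorder=polyorder, grid_step=grid_step))
    return curves
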