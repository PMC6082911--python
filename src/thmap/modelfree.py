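"""Model-free extraction of effective reaction orders from TH rate surfaces.

Each fraction-unfolded curve converts to instantaneous reaction rates via

    d[M]/dt = C_T · (dθ_U/dT) · (dT/dt)

with dT/dt signed (negative on cooling). Pooling the curves from several
scan rates yields, at every grid temperature, a set of ([M], d[M]/dt)
points — a 3-D temperature/concentration/rate surface. Under strong
hysteresis the annealing rate is dominated by the assembly term
(−k_on[M]^n), so an ordinary least-squares line of ln(−d[M]/dt) against
ln[M] has slope n and intercept ln k_on; on melts, ln(d[M]/dt) against
ln(C_T − [M]) has slope m and intercept (1 − m)·ln N + ln k_off. Natural
logarithms are used throughout; slopes are base-invariant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import THDataset
from .exceptions import THDataError
from .preprocess import FractionCurve

__all__ = [
    "RateSurface",
    "OrderSlice",
    "OrderProfile",
    "build_rate_surface",
    "extract_order_slice",
    "order_profile",
    "aggregate_profiles",
]


@dataclass(frozen=True)
class RateSurface:
    """Pooled (temperature, [M], rate) points across scan rates.

    ``rate`` is the signed monomer release rate d[M]/dt in M min⁻¹
    (negative during annealing, when monomers are consumed).
    """

    temperature: np.ndarray  # °C
    monomer: np.ndarray  # M
    rate: np.ndarray  # M min⁻¹ (signed)
    theta_U: np.ndarray
    scan_rate: np.ndarray  # °C min⁻¹ magnitude
    direction: np.ndarray  # object array of "melt"/"anneal"
    C_T: float

    def slice_at(self, temperature: float, direction: str, tol: float = 1e-6):
        m = (np.abs(self.temperature - temperature) <= tol) & (self.direction == direction)
        return m

    def grid(self, direction: str | None = None) -> np.ndarray:
        m = slice(None) if direction is None else self.direction == direction
        return np.unique(self.temperature[m])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        ax.scatter(self.temperature, self.monomer * 1e6, np.abs(self.rate) * 1e6, c=self.scan_rate)
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("[M] (µM)")
        ax.set_zlabel("|d[M]/dt| (µM min⁻¹)")
        return ax


def build_rate_surface(dataset: THDataset, curves: Sequence[FractionCurve]) -> RateSurface:
    """Assemble the rate surface from preprocessed fraction curves.

    Every curve must carry a smoothed derivative (see
    :func:`thmap.preprocess.smooth_derivative`).
    """
    Ts, Ms, rates, thetas, srs, dirs = [], [], [], [], [], []
    for c in curves:
        if c.dtheta_dT is None:
            raise THDataError("curves must carry dtheta_dT; run smooth_derivative first")
        Ts.append(c.temperature)
        thetas.append(c.theta_U)
        Ms.append(c.theta_U * dataset.C_T)
        rates.append(dataset.C_T * c.dtheta_dT * c.signed_scan_rate)
        srs.append(np.full(c.temperature.size, c.scan_rate))
        dirs.append(np.full(c.temperature.size, c.direction, dtype=object))
    return RateSurface(
        temperature=np.concatenate(Ts),
        monomer=np.concatenate(Ms),
        rate=np.concatenate(rates),
        theta_U=np.concatenate(thetas),
        scan_rate=np.concatenate(srs),
        direction=np.concatenate(dirs),
        C_T=dataset.C_T,
    )


@dataclass(frozen=True)
class OrderSlice:
    """OLS result for one isothermal slice through the rate surface."""

    temperature: float
    direction: str
    order: float
    order_stderr: float
    intercept: float
    intercept_stderr: float
    n_points: int

    def k_on(self) -> float:
        """Phenomenological assembly rate constant (anneal slices)."""
        return math.exp(self.intercept)

    def k_off(self, N: int) -> float:
        """Disassembly rate constant from a melt slice, given stoichiometry N."""
        return math.exp(self.intercept - (1.0 - self.order) * math.log(N))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    n = x.size
    X = np.column_stack([x, np.ones(n)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(beta[0]), float(beta[1]), math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))


def extract_order_slice(
    surface: RateSurface,
    temperature: float,
    direction: str,
    theta_window: tuple[float, float] = (0.10, 0.90),
    noise_floor_frac: float = 1e-4,
) -> OrderSlice:
    """Fit one isothermal log–log line through the rate surface.

    Anneal slices regress ln(−rate) on ln[M] (slope n, intercept ln k_on);
    melt slices regress ln(rate) on ln(C_T − [M]) (slope m, intercept
    (1 − m)·ln N + ln k_off). Points with θ_U outside the transition
    window, on the wrong side of zero rate, or below the noise floor
    (``noise_floor_frac · C_T`` per minute) are excluded.
    """
    m = surface.slice_at(temperature, direction)
    theta = surface.theta_U[m]
    rate = surface.rate[m]
    mono = surface.monomer[m]
    lo, hi = theta_window
    if direction == "anneal":
        keep = (theta >= lo) & (theta <= hi) & (rate < 0) & (mono > 0)
        x_raw, y_raw = mono, -rate
    elif direction == "melt":
        comp = surface.C_T - mono
        keep = ((1 - theta) >= lo) & ((1 - theta) <= hi) & (rate > 0) & (comp > 0)
        x_raw, y_raw = comp, rate
    else:
        raise THDataError(f"unknown direction {direction!r}")
    keep &= np.abs(rate) >= noise_floor_frac * surface.C_T
    # need points from distinct scan rates for a meaningful line
    if keep.sum() < 2 or np.unique(surface.scan_rate[m][keep]).size < 2:
        raise THDataError(
            f"slice at {temperature:g} °C ({direction}): "
            f"{int(keep.sum())} usable point(s) from "
            f"{np.unique(surface.scan_rate[m][keep]).size} scan rate(s); need >= 2"
        )
    slope, intercept, s_se, i_se = _ols_line(np.log(x_raw[keep]), np.log(y_raw[keep]))
    return OrderSlice(
        temperature=float(temperature),
        direction=direction,
        order=slope,
        order_stderr=s_se,
        intercept=intercept,
        intercept_stderr=i_se,
        n_points=int(keep.sum()),
    )


@dataclass
class OrderProfile:
    """Effective reaction order versus temperature for one scan direction."""

    temperature: np.ndarray
    order: np.ndarray
    order_stderr: np.ndarray
    intercept: np.ndarray
    intercept_stderr: np.ndarray
    points_used: np.ndarray
    direction: str
    skipped: dict[float, str] = field(default_factory=dict)
    hysteresis_adequate: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_C": self.temperature,
                "order": self.order,
                "order_stderr": self.order_stderr,
                "intercept": self.intercept,
                "intercept_stderr": self.intercept_stderr,
                "points_used": self.points_used,
                "direction": self.direction,
            }
        )

    def __len__(self) -> int:
        return self.temperature.size

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.temperature, self.order, yerr=self.order_stderr, fmt="o", ms=4)
        ax.set_xlabel("temperature (°C)")
        label = "n" if self.direction == "anneal" else "m"
        ax.set_ylabel(f"effective order {label}")
        return ax


def order_profile(
    surface: RateSurface,
    direction: str,
    theta_window: tuple[float, float] = (0.10, 0.90),
    noise_floor_frac: float = 1e-4,
    hysteresis_adequate: bool | None = None,
) -> OrderProfile:
    """Extract order slices at every grid temperature with enough usable points.

    Slices that cannot be fitted are recorded in ``skipped`` with the
    reason. When ``hysteresis_adequate`` is False (from
    :func:`thmap.preprocess.hysteresis_diagnostics`) the profile carries a
    warning flag: the single-term rate-law approximations need large
    hysteresis.
    """
    rows, skipped = [], {}
    for T in surface.grid(direction):
        try:
            rows.append(extract_order_slice(surface, T, direction, theta_window, noise_floor_frac))
        except THDataError as exc:
            skipped[float(T)] = str(exc)
    if hysteresis_adequate is False:
        warnings.warn(
            "hysteresis diagnostics flagged this dataset as inadequate; "
            "model-free orders may be biased",
            stacklevel=2,
        )
    return OrderProfile(
        temperature=np.array([r.temperature for r in rows]),
        order=np.array([r.order for r in rows]),
        order_stderr=np.array([r.order_stderr for r in rows]),
        intercept=np.array([r.intercept for r in rows]),
        intercept_stderr=np.array([r.intercept_stderr for r in rows]),
        points_used=np.array([r.n_points for r in rows], dtype=int),
        direction=direction,
        skipped=skipped,
        hysteresis_adequate=hysteresis_adequate,
    )


def aggregate_profiles(profiles: Sequence[OrderProfile]) -> OrderProfile:
    """Combine replicate profiles: mean order ± standard deviation per temperature.

    Mirrors the triplicate treatment where error bars are the standard
    deviations across replicate TH datasets.
    """
    if not profiles:
        raise THDataError("no profiles to aggregate")
    direction = profiles[0].direction
    if any(p.direction != direction for p in profiles):
        raise THDataError("profiles mix scan directions")
    temps = sorted(set().union(*[set(np.round(p.temperature, 9)) for p in profiles]))
    rows = []
    for T in temps:
        orders, intercepts, npts = [], [], 0
        for p in profiles:
            i = np.nonzero(np.isclose(p.temperature, T))[0]
            if i.size:
                orders.append(p.order[i[0]])
                intercepts.append(p.intercept[i[0]])
                npts += int(p.points_used[i[0]])
        if orders:
            rows.append(
                (
                    T,
                    np.mean(orders),
                    np.std(orders, ddof=0),
                    np.mean(intercepts),
                    np.std(intercepts, ddof=0),
                    npts,
                )
            )
    arr = np.array(rows)
    return OrderProfile(
        temperature=arr[:, 0],
        order=arr[:, 1],
        order_stderr=arr[:, 2],
        intercept=arr[:, 3],
        intercept_stderr=arr[:, 4],
        points_used=arr[:, 5].astype(int),
        direction=direction,
        hysteresis_adequate=profiles[0].hysteresis_adequate,
    )
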