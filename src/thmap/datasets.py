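"""Thermal-hysteresis trace containers and plain-text I/O.

A *trace* is one melting or annealing scan: temperature (°C) versus a
spectroscopic signal (absorbance, ellipticity, ...), recorded at a known
temperature scan rate. A *dataset* bundles the traces acquired on one sample
(shared total subunit concentration ``C_T``) across several scan rates and
both scan directions.

On disk a trace is a two-column CSV (``temperature_C,signal``) with metadata
either in ``#``-prefixed header lines or in a YAML/JSON sidecar next to the
file; a dataset is a directory of such traces plus a ``dataset.yaml`` holding
the shared metadata. Units at the boundary are °C, molar and minutes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .exceptions import THConfigurationError, THDataError

__all__ = [
    "THTrace",
    "THDataset",
    "load_trace",
    "load_th_dataset",
    "save_th_dataset",
    "write_results",
]

_DIRECTIONS = ("melt", "anneal")


@dataclass(frozen=True)
class THTrace:
    """One melting or annealing scan.

    Parameters
    ----------
    temperature : ndarray
        Sample temperature in °C. Must be strictly monotone; traces are
        normalised on construction so that temperature is increasing, with
        the scan direction kept in :attr:`direction`.
    signal : ndarray
        Spectroscopic signal in arbitrary units (same length as temperature).
    scan_rate : float
        Magnitude of dT/dt in °C min⁻¹ (> 0).
    direction : str
        ``"melt"`` (heating) or ``"anneal"`` (cooling).
    wavelength : float, optional
        Detection wavelength in nm (metadata only).
    replicate_id : str, optional
        Label distinguishing replicate acquisitions.
    """

    temperature: np.ndarray
    signal: np.ndarray
    scan_rate: float
    direction: str
    wavelength: float | None = None
    replicate_id: str | None = None

    def __post_init__(self):
        temperature = np.asarray(self.temperature, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if temperature.ndim != 1 or temperature.shape != signal.shape:
            raise THDataError("temperature and signal must be 1-D arrays of equal length")
        if temperature.size < 10:
            raise THDataError(f"trace has {temperature.size} points; need >= 10")
        if self.direction not in _DIRECTIONS:
            raise THConfigurationError(f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")
        if not (np.isfinite(self.scan_rate) and self.scan_rate > 0):
            raise THConfigurationError("scan_rate must be a positive magnitude in degC/min")
        dT = np.diff(temperature)
        if np.all(dT > 0):
            pass
        elif np.all(dT < 0):
            # recorded in scan order for a cooling ramp; normalise to increasing T
            temperature = temperature[::-1].copy()
            signal = signal[::-1].copy()
        else:
            raise THDataError("temperature is not strictly monotone within the scan")
        object.__setattr__(self, "temperature", temperature)
        object.__setattr__(self, "signal", signal)

    @property
    def signed_scan_rate(self) -> float:
        """dT/dt in °C min⁻¹, negative for annealing scans."""
        return self.scan_rate if self.direction == "melt" else -self.scan_rate

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.temperature[0]), float(self.temperature[-1])

    def with_signal(self, signal: np.ndarray) -> "THTrace":
        return replace(self, signal=np.asarray(signal, dtype=float))


@dataclass
class THDataset:
    """A multi-scan-rate TH dataset sharing one total subunit concentration.

    ``C_T`` is the total concentration of subunits in monomer equivalents
    (molar). ``N`` is the assembly stoichiometry when the final structure is
    finite (e.g. 4 for a tetramolecular quadruplex); leave ``None`` for
    open-ended polymerisation.
    """

    traces: list[THTrace]
    C_T: float
    N: int | None = None
    label: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (np.isfinite(self.C_T) and self.C_T > 0):
            raise THConfigurationError("C_T must be a positive molar concentration")
        self.traces = list(self.traces)
        for direction in _DIRECTIONS:
            rates = self.scan_rates(direction)
            if rates and len(rates) < 2:
                msg = f"only {len(rates)} scan rate(s) in direction {direction!r}; order extraction needs >= 2"
                self.flags.append(msg)
                warnings.warn(msg, stacklevel=2)

    def scan_rates(self, direction: str | None = None) -> list[float]:
        """Sorted distinct scan rates, optionally restricted to one direction."""
        rates = {t.scan_rate for t in self.traces if direction is None or t.direction == direction}
        return sorted(rates)

    def select(self, direction: str | None = None, scan_rate: float | None = None) -> list[THTrace]:
        out = []
        for t in self.traces:
            if direction is not None and t.direction != direction:
                continue
            if scan_rate is not None and not np.isclose(t.scan_rate, scan_rate):
                continue
            out.append(t)
        return out

    def __len__(self) -> int:
        return len(self.traces)


# ---------------------------------------------------------------------------
# reading


def _parse_header_metadata(lines: Iterable[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or ":" not in body:
            continue
        key, value = body.split(":", 1)
        meta[key.strip()] = yaml.safe_load(value.strip())
    return meta


def _sidecar_metadata(path: Path) -> dict:
    for ext in (".yaml", ".yml", ".json"):
        side = path.with_suffix(ext)
        if side.exists():
            with open(side) as fh:
                return yaml.safe_load(fh) if ext != ".json" else json.load(fh)
    return {}


def load_trace(path: str | Path, metadata: dict | None = None) -> THTrace:
    """Read one trace CSV; metadata from ``#`` header lines, sidecar, or argument.

    Explicit ``metadata`` overrides the sidecar, which overrides header lines.
    """
    path = Path(path)
    header_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    meta = _parse_header_metadata(header_lines)
    meta.update(_sidecar_metadata(path))
    meta.update(metadata or {})
    try:
        data = np.loadtxt(path, delimiter=",", comments="#", skiprows=len(header_lines) + 1, ndmin=2)
    except ValueError as exc:
        raise THDataError(f"{path}: could not parse two numeric columns: {exc}") from exc
    if data.shape[1] < 2:
        raise THDataError(f"{path}: expected two columns temperature_C,signal")
    for key in ("scan_rate", "direction"):
        if key not in meta:
            raise THConfigurationError(f"{path}: metadata is missing {key!r}")
    return THTrace(
        temperature=data[:, 0],
        signal=data[:, 1],
        scan_rate=float(meta["scan_rate"]),
        direction=str(meta["direction"]),
        wavelength=meta.get("wavelength"),
        replicate_id=str(meta["replicate_id"]) if "replicate_id" in meta else None,
    )


def load_th_dataset(path: str | Path, metadata: dict | None = None) -> THDataset:
    """Load a dataset directory (trace CSVs + ``dataset.yaml``).

    The dataset file must supply ``C_T`` (molar); it may supply ``N``,
    ``label`` and a ``traces`` list restricting/ordering the CSV files.
    ``metadata`` overrides dataset-level keys.
    """
    path = Path(path)
    if not path.is_dir():
        raise THConfigurationError(f"{path} is not a dataset directory")
    meta = {}
    for name in ("dataset.yaml", "dataset.yml", "dataset.json"):
        f = path / name
        if f.exists():
            with open(f) as fh:
                meta = yaml.safe_load(fh) or {}
            break
    meta.update(metadata or {})
    if "C_T" not in meta:
        raise THConfigurationError(f"{path}: dataset metadata is missing C_T")
    if "traces" in meta:
        files = [path / name for name in meta["traces"]]
    else:
        files = sorted(p for p in path.glob("*.csv"))
    if not files:
        raise THDataError(f"{path}: no trace CSVs found")
    traces = [load_trace(f) for f in files]
    return THDataset(
        traces=traces,
        C_T=float(meta["C_T"]),
        N=int(meta["N"]) if meta.get("N") is not None else None,
        label=str(meta.get("label", path.name)),
    )


# ---------------------------------------------------------------------------
# writing


def _trace_filename(trace: THTrace, index: int) -> str:
    rep = f"_{trace.replicate_id}" if trace.replicate_id else ""
    return f"{index:02d}_{trace.direction}_{trace.scan_rate:g}{rep}.csv"


def save_trace(trace: THTrace, path: str | Path) -> Path:
    """Write one trace CSV with ``#`` header metadata. Full float precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scan_rate: {trace.scan_rate!r}\n")
        fh.write(f"# direction: {trace.direction}\n")
        if trace.wavelength is not None:
            fh.write(f"# wavelength: {trace.wavelength!r}\n")
        if trace.replicate_id is not None:
            fh.write(f"# replicate_id: {trace.replicate_id}\n")
        fh.write("temperature_C,signal\n")
        for T, sig in zip(trace.temperature, trace.signal):
            fh.write(f"{float(T)!r},{float(sig)!r}\n")
    return path


def save_th_dataset(dataset: THDataset, directory: str | Path) -> Path:
    """Write a dataset directory (one CSV per trace + ``dataset.yaml``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, trace in enumerate(dataset.traces):
        name = _trace_filename(trace, i)
        save_trace(trace, directory / name)
        names.append(name)
    meta = {"C_T": float(dataset.C_T), "label": dataset.label, "traces": names}
    if dataset.N is not None:
        meta["N"] = int(dataset.N)
    with open(directory / "dataset.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return directory


def write_results(obj, path: str | Path) -> Path:
    """Write an analysis result to disk.

    * An :class:`~thmap.modelfree.OrderProfile` becomes a tidy CSV, one row
      per temperature.
    * A :class:`~thmap.fitting.THKineticResults` (or anything exposing
      ``to_report()``) becomes a JSON report with parameters, standard
      errors, RSS and AIC.
    """
    path = Path(path)
    if hasattr(obj, "to_frame"):  # OrderProfile and friends
        frame = obj.to_frame()
        frame.to_csv(path, index=False, float_format="%.12g")
        return path
    if hasattr(obj, "to_report"):
        if path.suffix == ".csv" and hasattr(obj, "params"):
            import pandas as pd

            pd.DataFrame(
                {
                    "parameter": list(obj.params.index),
                    "estimate": obj.params.to_numpy(),
                    "stderr": obj.bse.to_numpy(),
                }
            ).to_csv(path, index=False, float_format="%.12g")
            return path
        with open(path, "w") as fh:
            json.dump(obj.to_report(), fh, indent=2)
        return path
    raise TypeError(f"do not know how to serialise {type(obj).__name__}")
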