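"""Chamber state and CO2 time series with unit conversions.

The estimators work in number concentration n_CO2 (molecules per cubic
metre); sensors usually report mole fraction in ppm.  Conversion assumes
ideal-gas behaviour at the chamber temperature and pressure:

    n = x * 1e-6 * P / (k_B * T)

with k_B the Boltzmann constant (exact SI value).  Mass concentration in
kg/m^3 divides by the mass of one CO2 molecule.  Multiplying a number
concentration by the chamber volume V gives the molecule count
N_CO2 = n_CO2 * V.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann

from .stoichiometry import CO2_MOLECULE_MASS_KG

__all__ = [
    "GasUnit",
    "ChamberSpec",
    "GasSeries",
    "Injection",
    "ppm_to_number_concentration",
    "number_concentration_to_ppm",
    "to_number_concentration",
    "molecule_count",
    "read_gas_series",
    "write_gas_series",
]


class GasUnit(str, enum.Enum):
    """Supported CO2 level units."""

    PPM = "ppm"                      # mole fraction, parts per million
    NUMBER = "molecules_per_m3"      # number concentration
    MASS = "kg_per_m3"               # mass concentration

    @classmethod
    def parse(cls, text: Union[str, "GasUnit"]) -> "GasUnit":
        if isinstance(text, cls):
            return text
        aliases = {
            "ppm": cls.PPM,
            "molecules_per_m3": cls.NUMBER,
            "molecules/m3": cls.NUMBER,
            "m-3": cls.NUMBER,
            "kg_per_m3": cls.MASS,
            "kg/m3": cls.MASS,
        }
        key = str(text).strip().lower()
        if key not in aliases:
            raise ValueError(f"unknown CO2 unit {text!r}; use ppm, molecules_per_m3 or kg_per_m3")
        return aliases[key]


@dataclass(frozen=True)
class Injection:
    """An instantaneous CO2 injection: `amount` molecules added at `time` s."""

    time: float
    amount: float

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError("injection amount must be non-negative")


@dataclass(frozen=True)
class ChamberSpec:
    """Cultivation chamber: geometry, thermodynamic state and exchange terms.

    Parameters
    ----------
    volume : float
        Chamber air volume, m^3.
    temperature : float
        Air temperature, K (assumed constant).
    pressure : float
        Air pressure, Pa (assumed constant).
    leak_coefficient : float
        First-order leak rate k, 1/s; the chamber loses CO2 at
        k * V * (n - n_ambient).  0 means sealed.
    ambient_co2_ppm : float
        CO2 mole fraction of the outside air, ppm (used only when leaking).
    injections : tuple of Injection
        Scheduled instantaneous CO2 additions, strictly increasing in time.
    """

    volume: float
    temperature: float = 293.15
    pressure: float = 101325.0
    leak_coefficient: float = 0.0
    ambient_co2_ppm: float = 0.0
    injections: tuple[Injection, ...] = ()

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("chamber volume must be positive")
        if self.temperature <= 0 or self.pressure <= 0:
            raise ValueError("temperature and pressure must be positive")
        if self.leak_coefficient < 0:
            raise ValueError("leak coefficient must be non-negative")
        if self.ambient_co2_ppm < 0:
            raise ValueError("ambient CO2 must be non-negative")
        inj = tuple(
            i if isinstance(i, Injection) else Injection(*i) for i in self.injections
        )
        times = [i.time for i in inj]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("injection times must be strictly increasing")
        object.__setattr__(self, "injections", inj)

    @property
    def is_sealed(self) -> bool:
        return self.leak_coefficient == 0 and not self.injections

    @property
    def ambient_number_concentration(self) -> float:
        return ppm_to_number_concentration(
            self.ambient_co2_ppm, self.temperature, self.pressure
        )


def ppm_to_number_concentration(x_ppm: float, temperature: float, pressure: float) -> float:
    """Mole fraction in ppm -> number concentration in molecules/m^3.

    Ideal gas: n = x * 1e-6 * P / (k_B * T).
    """
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be positive")
    x = np.asarray(x_ppm, dtype=float)
    if np.any(x < 0):
        raise ValueError("mole fraction must be non-negative")
    out = x * 1e-6 * pressure / (Boltzmann * temperature)
    return float(out) if out.ndim == 0 else out


def number_concentration_to_ppm(n: float, temperature: float, pressure: float) -> float:
    """Inverse of :func:`ppm_to_number_concentration`."""
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be positive")
    n_arr = np.asarray(n, dtype=float)
    out = n_arr * Boltzmann * temperature / pressure * 1e6
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GasSeries:
    """A time-ordered CO2 series in a declared unit.

    Times are seconds from the first sample (strictly increasing); values
    are non-negative CO2 levels.  Any estimation requires length >= 2.
    """

    times: np.ndarray
    values: np.ndarray
    unit: GasUnit = GasUnit.PPM

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("CO2 values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "unit", GasUnit.parse(self.unit))

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "co2": self.values})


def to_number_concentration(series: GasSeries, chamber: ChamberSpec) -> GasSeries:
    """Convert a series to number concentration (molecules/m^3) pointwise."""
    if series.unit is GasUnit.NUMBER:
        return series
    if series.unit is GasUnit.PPM:
        vals = ppm_to_number_concentration(
            series.values, chamber.temperature, chamber.pressure
        )
    elif series.unit is GasUnit.MASS:
        vals = series.values / CO2_MOLECULE_MASS_KG
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unsupported unit {series.unit}")
    return GasSeries(series.times, vals, GasUnit.NUMBER)


def molecule_count(series: GasSeries, chamber: ChamberSpec) -> np.ndarray:
    """Total CO2 molecule count N(t) = n(t) * V for every sample."""
    n = to_number_concentration(series, chamber)
    return n.values * chamber.volume


# ---------------------------------------------------------------------------
# Delimited text I/O


def _normalise_times(raw: pd.Series) -> np.ndarray:
    """Accept numeric seconds or ISO-8601 timestamps; return seconds from start."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if not numeric.isna().any():
        return numeric.to_numpy(dtype=float)
    stamps = pd.to_datetime(raw, errors="raise", format="ISO8601")
    return (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy(dtype=float)


def read_gas_series(
    path_or_buf,
    unit: Optional[Union[str, GasUnit]] = None,
    sep: Optional[str] = None,
) -> GasSeries:
    """Read a delimited (comma or tab) CO2 time series.

    Required columns: ``time`` (numeric seconds or ISO-8601) and ``co2``.
    A leading comment line ``# unit: ppm`` declares the unit; an explicit
    `unit` argument overrides it; default is ppm.
    """
    header_unit = None
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = text.splitlines()
    data_lines = []
    for ln in lines:
        if ln.lstrip().startswith("#"):
            stripped = ln.lstrip("# ").strip()
            if stripped.lower().startswith("unit:"):
                header_unit = stripped.split(":", 1)[1].strip()
            continue
        if ln.strip():
            data_lines.append(ln)
    if not data_lines:
        raise ValueError("empty series file")
    if sep is None:
        sep = "\t" if "\t" in data_lines[0] else ","
    df = pd.read_csv(io.StringIO("\n".join(data_lines)), sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("time", "co2"):
        if col not in df.columns:
            raise ValueError(f"series file missing required column {col!r}")
    resolved = GasUnit.parse(unit) if unit is not None else (
        GasUnit.parse(header_unit) if header_unit else GasUnit.PPM
    )
    return GasSeries(
        _normalise_times(df["time"]),
        df["co2"].to_numpy(dtype=float),
        resolved,
    )


def write_gas_series(series: GasSeries, path, sep: str = ",") -> None:
    """Write a series as delimited text with a unit header directive."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit: {series.unit.value}\n")
        series.to_frame().to_csv(fh, sep=sep, index=False)
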