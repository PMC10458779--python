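"""Model/Results interface over the estimators.

Usage mirrors the fit-and-summarise pattern of statistical modelling
packages: a model object is built from data (a CO2 trace or a flux curve
plus chamber and plant parameters), ``fit()`` runs the estimator, and the
returned :class:`TuberMassResults` carries the mass trajectory, headline
numbers, diagnostics and a ``summary()`` table.

>>> model = SealedChamberModel(series, chamber, plant)
>>> res = model.fit()
>>> res.final_mass
>>> print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from scipy.constants import Avogadro

from . import estimators, leaky
from .estimators import (
    ComparisonReport,
    FluxSeries,
    PlantParams,
    StoichMode,
    TuberMassSeries,
    compare_to_observation,
)
from .gas import ChamberSpec, GasSeries, GasUnit, read_gas_series, to_number_concentration
from .stoichiometry import CO2_MOLECULE_MASS_KG

__all__ = [
    "SealedChamberModel",
    "LeakyChamberModel",
    "FluxIntegralModel",
    "TuberMassResults",
]


@dataclass
class TuberMassResults:
    """Results of a tuber-mass estimation.

    Attributes
    ----------
    series : TuberMassSeries
        The estimated trajectory (raw, unclamped).
    model : object
        The model instance that produced the fit.
    absorption : leaky.AbsorptionEstimate or None
        Leak/injection bookkeeping when the leaky estimator ran.
    warnings_ : list of str
        Conditions worth surfacing (as_published mode, negative-mass
        segments, ...).
    """

    series: TuberMassSeries
    model: object
    absorption: Optional[leaky.AbsorptionEstimate] = None
    warnings_: list[str] = field(default_factory=list)

    @property
    def params(self) -> PlantParams:
        return self.series.params

    @property
    def times(self) -> np.ndarray:
        return self.series.times

    @property
    def mass(self) -> np.ndarray:
        return self.series.mass

    @property
    def final_mass(self) -> float:
        return self.series.final_mass

    @property
    def mass_gain(self) -> float:
        return self.series.final_mass - self.params.m_tubers0

    @property
    def absorbed_molecules(self) -> float:
        return float(self.series.absorbed_co2_molecules[-1])

    @property
    def absorbed_mol(self) -> float:
        return self.absorbed_molecules / Avogadro

    @property
    def absorbed_kg(self) -> float:
        return self.absorbed_molecules * CO2_MOLECULE_MASS_KG

    def compare_to(self, observed_final: float, decimals: int = 2) -> ComparisonReport:
        """Compare the fitted final mass against a measured one."""
        return compare_to_observation(self.final_mass, observed_final, decimals)

    def to_frame(self) -> pd.DataFrame:
        return self.series.to_frame()

    def headline(self) -> dict:
        """Headline numbers as a plain dict (machine-readable)."""
        return {
            "final_tuber_mass_kg": self.final_mass,
            "final_tuber_mass_g": self.final_mass * 1e3,
            "tuber_mass_gain_kg": self.mass_gain,
            "final_starch_mass_kg": float(self.series.starch_mass[-1]),
            "absorbed_co2_molecules": self.absorbed_molecules,
            "absorbed_co2_mol": self.absorbed_mol,
            "absorbed_co2_kg": self.absorbed_kg,
            "stoichiometry_mode": self.params.mode.value,
            "eta_starch": self.params.eta_starch,
            "partition_ratio": self.params.partition_ratio,
            "m_tubers0_kg": self.params.m_tubers0,
            "warnings": list(self.warnings_),
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        h = self.headline()
        lines = [
            "Tuber Mass Estimation Results",
            "=" * 46,
            f"{'Model:':<28}{type(self.model).__name__}",
            f"{'Stoichiometry mode:':<28}{h['stoichiometry_mode']}",
            f"{'Starch fraction eta:':<28}{h['eta_starch']:.3f}",
            f"{'Partition ratio:':<28}{h['partition_ratio']:.2f}",
            f"{'Initial tuber mass:':<28}{h['m_tubers0_kg'] * 1e3:.1f} g",
            f"{'Samples:':<28}{len(self.series)}",
            f"{'Span:':<28}{self.times[-1] - self.times[0]:.0f} s "
            f"({(self.times[-1] - self.times[0]) / 86400:.2f} d)",
            "-" * 46,
            f"{'Final tuber mass:':<28}{h['final_tuber_mass_kg']:.4f} kg "
            f"({h['final_tuber_mass_g']:.1f} g)",
            f"{'Mass gain:':<28}{h['tuber_mass_gain_kg']:.4f} kg",
            f"{'Final starch mass:':<28}{h['final_starch_mass_kg']:.4f} kg",
            f"{'CO2 absorbed:':<28}{h['absorbed_co2_molecules']:.3e} molecules",
            f"{'':<28}{h['absorbed_co2_mol']:.3f} mol / {h['absorbed_co2_kg']:.4f} kg",
        ]
        if self.absorption is not None:
            lines.append(
                f"{'CO2 leaked (net):':<28}{float(self.absorption.leaked_molecules[-1]):.3e} molecules"
            )
            lines.append(
                f"{'CO2 injected:':<28}{float(self.absorption.injected_molecules[-1]):.3e} molecules"
            )
        for w in self.warnings_:
            lines.append(f"Warning: {w}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the mass trajectory (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times / 86400, self.mass, label="tuber mass")
        ax.set_xlabel("time (d)")
        ax.set_ylabel("tuber mass (kg)")
        ax.legend()
        return ax


def _collect_warnings(series: TuberMassSeries, extra: list[str]) -> list[str]:
    out = list(extra)
    if series.params.mode is not StoichMode.MASS_BALANCE:
        out.append(
            f"as_published stoichiometric mode '{series.params.mode.value}' active "
            "(not mass-conserving)"
        )
    if series.has_negative:
        out.append("estimate dips below zero (net CO2 release); clamped view available")
    return out


class _ChamberModelBase:
    """Shared constructor plumbing for chamber-trace models."""

    def __init__(self, series: GasSeries, chamber: ChamberSpec, plant: PlantParams):
        self.series = series
        self.chamber = chamber
        self.plant = plant

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        chamber: ChamberSpec,
        plant: PlantParams,
        unit: GasUnit | str = GasUnit.PPM,
        time_col: str = "time",
        co2_col: str = "co2",
    ):
        series = GasSeries(
            np.asarray(df[time_col], dtype=float),
            np.asarray(df[co2_col], dtype=float),
            GasUnit.parse(unit),
        )
        return cls(series, chamber, plant)

    @classmethod
    def from_file(cls, path, chamber: ChamberSpec, plant: PlantParams, unit=None):
        return cls(read_gas_series(path, unit=unit), chamber, plant)

    def drawdown_ppm(self) -> float:
        """Start-to-end CO2 drawdown expressed in ppm."""
        from .gas import number_concentration_to_ppm

        n = to_number_concentration(self.series, self.chamber).values
        return float(
            number_concentration_to_ppm(
                n[0] - n[-1], self.chamber.temperature, self.chamber.pressure
            )
        )


class SealedChamberModel(_ChamberModelBase):
    """Tuber mass from CO2 drawdown in a sealed chamber.

    Data: a CO2 trace, the chamber spec (must be sealed: no leak, no
    injections) and plant parameters.
    """

    def fit(self) -> TuberMassResults:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", estimators.AsPublishedModeWarning)
            series = estimators.tuber_mass_sealed(self.series, self.chamber, self.plant)
        return TuberMassResults(
            series=series, model=self, warnings_=_collect_warnings(series, [])
        )


class LeakyChamberModel(_ChamberModelBase):
    """Tuber mass from a chamber with first-order leakage and/or injections."""

    def fit(self) -> TuberMassResults:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", estimators.AsPublishedModeWarning)
            absorption = leaky.recover_absorption(self.series, self.chamber)
            series = leaky.tuber_mass_unsealed(self.series, self.chamber, self.plant)
        return TuberMassResults(
            series=series,
            model=self,
            absorption=absorption,
            warnings_=_collect_warnings(series, []),
        )


class FluxIntegralModel:
    """Tuber mass from an area-specific CO2 mass absorption rate.

    Data: a flux curve (kg m^-2 s^-1) with leaf area S; the cumulative CO2
    mass S * int flux dt is converted to tuber mass by the active mode.
    """

    def __init__(self, flux: FluxSeries, plant: PlantParams):
        self.flux = flux
        self.plant = plant

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        leaf_area: float,
        plant: PlantParams,
        time_col: str = "time",
        flux_col: str = "flux",
    ):
        return cls(
            FluxSeries(
                np.asarray(df[time_col], dtype=float),
                np.asarray(df[flux_col], dtype=float),
                leaf_area,
            ),
            plant,
        )

    def fit(self) -> TuberMassResults:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", estimators.AsPublishedModeWarning)
            series = estimators.tuber_mass_from_flux(self.flux, self.plant)
        return TuberMassResults(
            series=series, model=self, warnings_=_collect_warnings(series, [])
        )
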