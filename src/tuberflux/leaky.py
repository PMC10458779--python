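"""Non-sealed chambers: first-order leakage and scheduled CO2 injections.

A chamber held above ambient CO2 partial pressure loses CO2 continuously.
The simplest law consistent with that picture is first-order relaxation
toward the ambient level,

    leak rate = k * V * (n(t) - n_ambient)   [molecules/s],

with k a user-supplied coefficient (1/s), not estimated from the trace.
Scheduled injections are instantaneous impulses of known molecule count
(well-mixed chamber).  The plant-absorbed CO2 then follows from the chamber
mass balance

    V * (n(0) - n(t)) = absorbed(t) + leaked(t) - injected(t),

where leaked(t) integrates the leak rate by the trapezoid rule on the
sample grid.  With k = 0 and no injections this reduces exactly to the
sealed-chamber bookkeeping.

A convenience fit of k from a plant-free decay trace (log-linear regression
on n - n_ambient) is included as plumbing beyond the core model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .estimators import PlantParams, TuberMassSeries, _assemble, _warn_if_as_published
from .gas import ChamberSpec, GasSeries, to_number_concentration

__all__ = [
    "AbsorptionEstimate",
    "recover_absorption",
    "tuber_mass_unsealed",
    "fit_leak_coefficient",
]


@dataclass(frozen=True)
class AbsorptionEstimate:
    """Cumulative chamber CO2 bookkeeping per sample time.

    At every t the identity
    V * (n(0) - n(t)) = absorbed(t) + leaked(t) - injected(t)
    holds by construction.  leaked is signed (negative if the chamber sits
    below ambient and gains CO2 through the leak).
    """

    times: np.ndarray
    absorbed_molecules: np.ndarray
    leaked_molecules: np.ndarray
    injected_molecules: np.ndarray

    @property
    def final_absorbed(self) -> float:
        return float(self.absorbed_molecules[-1])


def recover_absorption(series: GasSeries, chamber: ChamberSpec) -> AbsorptionEstimate:
    """Recover cumulative plant absorption from a non-sealed trace.

    leaked(t) = k * V * int_0^t (n - n_amb) dt' (trapezoid); injected(t)
    sums scheduled impulses at or before t; absorbed(t) closes the balance.
    Injection times must fall within the series span.
    """
    if len(series) < 2:
        raise ValueError("at least two samples are required")
    t = series.times
    for inj in chamber.injections:
        if not (t[0] <= inj.time <= t[-1]):
            raise ValueError(
                f"injection at t={inj.time} s lies outside the series span "
                f"[{t[0]}, {t[-1]}] s"
            )
    n = to_number_concentration(series, chamber).values
    n_amb = chamber.ambient_number_concentration
    leaked = chamber.leak_coefficient * chamber.volume * cumulative_trapezoid(
        n - n_amb, t, initial=0.0
    )
    injected = np.zeros_like(t)
    for inj in chamber.injections:
        injected[t >= inj.time] += inj.amount
    absorbed = chamber.volume * (n[0] - n) + injected - leaked
    return AbsorptionEstimate(
        times=t,
        absorbed_molecules=absorbed,
        leaked_molecules=leaked,
        injected_molecules=injected,
    )


def tuber_mass_unsealed(
    series: GasSeries, chamber: ChamberSpec, params: PlantParams
) -> TuberMassSeries:
    """Tuber mass from a leaky/injected chamber trace.

    m(t) = m0 + f * absorbed(t) / rho with absorbed(t) from
    :func:`recover_absorption`; identical to the sealed estimator when the
    chamber is in fact sealed.
    """
    _warn_if_as_published(params)
    est = recover_absorption(series, chamber)
    return _assemble(est.times, est.absorbed_molecules, params)


def fit_leak_coefficient(series: GasSeries, chamber: ChamberSpec) -> float:
    """Estimate k from a plant-free decay trace.

    Log-linear least squares on n(t) - n_ambient, which decays as
    exp(-k t) when nothing absorbs CO2.  Utility plumbing for chamber
    characterisation, not part of the estimation model itself.
    """
    n = to_number_concentration(series, chamber).values
    excess = n - chamber.ambient_number_concentration
    if np.any(excess <= 0):
        raise ValueError(
            "decay fit requires the trace to stay strictly above ambient CO2"
        )
    slope, _ = np.polyfit(series.times, np.log(excess), 1)
    return float(-slope)
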