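"""Run reports: parameter echo, headline numbers, provenance.

Every number in a report is recomputable from the echoed parameters and
the input digest; reports serialise to both a human-readable text block and
JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .gas import ChamberSpec
from .models import TuberMassResults

__all__ = ["RunReport", "file_digest"]


def file_digest(path) -> str:
    """SHA-256 hex digest of an input file, for provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunReport:
    """A complete, reproducible record of one estimation run."""

    headline: dict
    chamber: dict
    drawdown_ppm: Optional[float] = None
    input_digest: Optional[str] = None
    seed: Optional[int] = None
    warnings: list[str] = field(default_factory=list)
    tool_version: str = __version__

    @classmethod
    def from_results(
        cls,
        results: TuberMassResults,
        chamber: Optional[ChamberSpec] = None,
        drawdown_ppm: Optional[float] = None,
        input_digest: Optional[str] = None,
        seed: Optional[int] = None,
    ) -> "RunReport":
        ch = {}
        if chamber is not None:
            ch = {
                "volume_m3": chamber.volume,
                "temperature_K": chamber.temperature,
                "pressure_Pa": chamber.pressure,
                "leak_coefficient_per_s": chamber.leak_coefficient,
                "ambient_co2_ppm": chamber.ambient_co2_ppm,
                "injections": [
                    {"time_s": i.time, "molecules": i.amount} for i in chamber.injections
                ],
            }
        return cls(
            headline=results.headline(),
            chamber=ch,
            drawdown_ppm=drawdown_ppm,
            input_digest=input_digest,
            seed=seed,
            warnings=list(results.warnings_),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        h = self.headline
        lines = ["Run report", "-" * 40]
        if self.chamber:
            lines.append(
                f"Chamber: V={self.chamber['volume_m3']} m^3, "
                f"T={self.chamber['temperature_K']} K, "
                f"P={self.chamber['pressure_Pa']} Pa, "
                f"k={self.chamber['leak_coefficient_per_s']} 1/s"
            )
        lines += [
            f"Mode: {h['stoichiometry_mode']}  eta={h['eta_starch']}  "
            f"rho={h['partition_ratio']}  m0={h['m_tubers0_kg'] * 1e3:.1f} g",
            f"Final tuber mass: {h['final_tuber_mass_kg']:.4f} kg "
            f"({h['final_tuber_mass_g']:.1f} g)",
            f"CO2 absorbed: {h['absorbed_co2_molecules']:.3e} molecules = "
            f"{h['absorbed_co2_mol']:.3f} mol = {h['absorbed_co2_kg']:.4f} kg",
        ]
        if self.drawdown_ppm is not None:
            lines.append(f"CO2 drawdown: {self.drawdown_ppm:.1f} ppm")
        if self.input_digest:
            lines.append(f"Input sha256: {self.input_digest}")
        if self.seed is not None:
            lines.append(f"Seed: {self.seed}")
        lines.append(f"tuberflux version {self.tool_version}")
        for w in self.warnings:
            lines.append(f"Warning: {w}")
        return "\n".join(lines)
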