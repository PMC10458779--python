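"""Chemical formulas, reaction algebra, and the starch-synthesis stoichiometry.

Starch accumulation in potato tubers can be written as four lumped reaction
stages: light capture into ATP, carbon fixation of CO2 and water into
glucose, glucose respiration back to CO2 (releasing ATP in the tuber), and
polymerisation of glucose into the starch monomer C6H10O5.  Eliminating the
intermediates (glucose, and the ATP produced in the tuber) from the stage
reactions yields the net balanced reaction

    6 CO2 + 5 H2O + 2 ATP -> C6H10O5 + 6 O2

so one starch monomer is laid down per six CO2 molecules absorbed.  This
module provides the formula/ reaction machinery to carry out that
elimination exactly (rational coefficients), and exposes the derived net
stoichiometry that the tuber-mass estimators consume.

ATP and the photon energy term are treated as opaque energy-carrier tokens:
they participate in the reaction algebra but are excluded from the
per-element balance ledger, since they appear in the lumped stages without
structural formulas.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

from scipy.constants import Avogadro

__all__ = [
    "Formula",
    "Reaction",
    "NetStoichiometry",
    "parse_formula",
    "molar_mass",
    "molecule_mass_kg",
    "combine_reactions",
    "check_balanced",
    "derive_net_stoichiometry",
    "ATP_SYNTHESIS",
    "GLUCOSE_SYNTHESIS",
    "GLUCOSE_RESPIRATION",
    "STARCH_POLYMERISATION",
    "STARCH_MONOMER",
    "CO2",
    "WATER",
    "OXYGEN",
    "GLUCOSE",
    "CHLOROPHYLL",
]

# IUPAC 2021 standard atomic weights, g/mol, abridged to 3 d.p.
# Only elements that can plausibly appear in plant-biochemistry formulas are
# tabulated; molar_mass raises for anything else.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Mn": 54.938,
    "Zn": 65.38,
    "Cu": 63.546,
}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental formula as a map from element symbol to count.

    Counts are positive integers; the canonical string form lists elements
    in Hill order (C first, then H, then the rest alphabetically).
    """

    element_counts: Mapping[str, int]

    def __post_init__(self):
        for el, cnt in self.element_counts.items():
            if el not in ATOMIC_WEIGHTS:
                raise ValueError(f"unknown element symbol {el!r}")
            if not (isinstance(cnt, int) and cnt >= 1):
                raise ValueError(f"count for {el} must be a positive integer, got {cnt!r}")
        # freeze the mapping
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __hash__(self) -> int:
        return hash(frozenset(self.element_counts.items()))

    def __eq__(self, other) -> bool:
        if isinstance(other, Formula):
            return dict(self.element_counts) == dict(other.element_counts)
        return NotImplemented

    def hill_order(self) -> list[tuple[str, int]]:
        """Element/count pairs in Hill convention order."""
        items = dict(self.element_counts)
        out: list[tuple[str, int]] = []
        if "C" in items:
            out.append(("C", items.pop("C")))
            if "H" in items:
                out.append(("H", items.pop("H")))
        out.extend(sorted(items.items()))
        return out

    def __str__(self) -> str:
        return "".join(
            f"{el}{cnt}" if cnt != 1 else el for el, cnt in self.hill_order()
        )

    def __repr__(self) -> str:
        return f"Formula({self!s})"


# A reaction species is either an elemental formula or an opaque token
# (a bare string) such as "ATP" or "E_hv".
Species = Union[Formula, str]


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string like ``"C6H10O5"``.

    Parentheses, charges and isotopes are not supported.  Raises
    ``ValueError`` naming the offending position on malformed input.
    """
    if not isinstance(text, str) or not text:
        raise ValueError("formula string must be non-empty")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(
                f"malformed formula {text!r}: cannot parse at position {pos} ({text[pos]!r})"
            )
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_WEIGHTS:
            raise ValueError(
                f"unknown element symbol {el!r} at position {pos} in {text!r}"
            )
        n = int(digits) if digits else 1
        if n < 1:
            raise ValueError(f"zero count for element {el} at position {pos} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return Formula(counts)


def molar_mass(f: Formula) -> float:
    """Molar mass in g/mol from the bundled standard atomic weights."""
    return sum(ATOMIC_WEIGHTS[el] * cnt for el, cnt in f.element_counts.items())


def molecule_mass_kg(f: Formula) -> float:
    """Mass of a single molecule in kg (molar mass over the Avogadro constant)."""
    return molar_mass(f) / Avogadro * 1e-3


def _species_key(sp: Species) -> tuple:
    if isinstance(sp, Formula):
        return ("formula", str(sp))
    return ("token", sp)


@dataclass(frozen=True)
class Reaction:
    """A reaction: coefficient/species multisets for each side.

    Coefficients are positive rationals (`fractions.Fraction`), so linear
    combination and cancellation are exact.  A species never appears on both
    sides after canonicalisation, and never more than once per side.
    """

    reactants: tuple[tuple[Fraction, Species], ...]
    products: tuple[tuple[Fraction, Species], ...]

    @staticmethod
    def from_sides(
        reactants: Iterable[tuple[Union[int, Fraction], Species]],
        products: Iterable[tuple[Union[int, Fraction], Species]],
    ) -> "Reaction":
        """Build a canonical reaction, merging duplicates and cancelling
        species that appear on both sides down to the net amount."""
        net: dict[tuple, Fraction] = {}
        species_by_key: dict[tuple, Species] = {}
        for sign, side in ((-1, reactants), (+1, products)):
            for coeff, sp in side:
                coeff = Fraction(coeff)
                if coeff <= 0:
                    raise ValueError(f"coefficient must be positive, got {coeff}")
                key = _species_key(sp)
                species_by_key[key] = sp
                net[key] = net.get(key, Fraction(0)) + sign * coeff
        reac, prod = [], []
        for key, amount in net.items():
            if amount < 0:
                reac.append((-amount, species_by_key[key]))
            elif amount > 0:
                prod.append((amount, species_by_key[key]))
        reac.sort(key=lambda t: _species_key(t[1]))
        prod.sort(key=lambda t: _species_key(t[1]))
        return Reaction(tuple(reac), tuple(prod))

    def reverse(self) -> "Reaction":
        return Reaction(self.products, self.reactants)

    def is_empty(self) -> bool:
        return not self.reactants and not self.products

    def coefficient(self, sp: Species) -> Fraction:
        """Signed net coefficient of a species: negative on the reactant
        side, positive on the product side, zero if absent."""
        key = _species_key(sp)
        for coeff, s in self.reactants:
            if _species_key(s) == key:
                return -coeff
        for coeff, s in self.products:
            if _species_key(s) == key:
                return coeff
        return Fraction(0)

    def _side_str(self, side: Sequence[tuple[Fraction, Species]]) -> str:
        if not side:
            return "0"
        parts = []
        for coeff, sp in side:
            c = "" if coeff == 1 else (f"{coeff} " if coeff.denominator != 1 else f"{int(coeff)} ")
            parts.append(f"{c}{sp}")
        return " + ".join(parts)

    def __str__(self) -> str:
        return f"{self._side_str(self.reactants)} -> {self._side_str(self.products)}"

    def __repr__(self) -> str:
        return f"Reaction({self!s})"


def combine_reactions(
    terms: Sequence[tuple[Union[int, Fraction], Reaction]],
) -> Reaction:
    """Linear combination of reactions with positive rational multipliers.

    Coefficients are scaled and summed per species; species appearing on
    both sides of the combination cancel to the net amount and vanish when
    the net is zero.
    """
    reactants: list[tuple[Fraction, Species]] = []
    products: list[tuple[Fraction, Species]] = []
    for mult, rxn in terms:
        mult = Fraction(mult)
        if mult <= 0:
            raise ValueError(f"multiplier must be positive, got {mult}")
        reactants.extend((mult * c, sp) for c, sp in rxn.reactants)
        products.extend((mult * c, sp) for c, sp in rxn.products)
    return Reaction.from_sides(reactants, products)


def check_balanced(r: Reaction) -> dict[str, tuple[Fraction, Fraction]]:
    """Per-element balance report: element -> (reactant total, product total).

    Opaque tokens (ATP, photon energy) carry no elements and are excluded.
    Imbalance is reported, never raised; a reaction is balanced iff every
    pair in the report is equal.
    """
    ledger: dict[str, list[Fraction]] = {}
    for idx, side in ((0, r.reactants), (1, r.products)):
        for coeff, sp in side:
            if not isinstance(sp, Formula):
                continue
            for el, cnt in sp.element_counts.items():
                ledger.setdefault(el, [Fraction(0), Fraction(0)])[idx] += coeff * cnt
    return {el: (tot[0], tot[1]) for el, tot in sorted(ledger.items())}


def is_balanced(r: Reaction) -> bool:
    return all(a == b for a, b in check_balanced(r).values())


# ---------------------------------------------------------------------------
# Bundled species and the four lumped photosynthesis/starch stages.

STARCH_MONOMER = parse_formula("C6H10O5")
GLUCOSE = parse_formula("C6H12O6")
CO2 = parse_formula("CO2")
WATER = parse_formula("H2O")
OXYGEN = parse_formula("O2")
CHLOROPHYLL = parse_formula("C55H72MgN4O5")

ATP = "ATP"
LIGHT = "E_hv"

#: Light capture: chlorophyll-mediated storage of photon energy as ATP.
#: Qualitative only — the photon energy token has no magnitude and the
#: chlorophyll formula is never consumed stoichiometrically downstream.
ATP_SYNTHESIS = Reaction.from_sides(
    [(1, CHLOROPHYLL), (1, LIGHT)], [(1, ATP)]
)

#: Carbon fixation in the leaves: 6 CO2 + 6 H2O + ATP -> glucose + 6 O2.
GLUCOSE_SYNTHESIS = Reaction.from_sides(
    [(6, CO2), (6, WATER), (1, ATP)], [(1, GLUCOSE), (6, OXYGEN)]
)

#: Glucose respiration in the tuber, releasing ATP:
#: glucose + 6 O2 -> 6 CO2 + 6 H2O + ATP.
GLUCOSE_RESPIRATION = Reaction.from_sides(
    [(1, GLUCOSE), (6, OXYGEN)], [(6, CO2), (6, WATER), (1, ATP)]
)

#: Starch polymerisation in the tuber: glucose + ATP -> C6H10O5 + H2O.
STARCH_POLYMERISATION = Reaction.from_sides(
    [(1, GLUCOSE), (1, ATP)], [(1, STARCH_MONOMER), (1, WATER)]
)


@dataclass(frozen=True)
class NetStoichiometry:
    """Derived net stoichiometry of starch-monomer synthesis from CO2."""

    co2_per_monomer: int
    h2o_per_monomer: int
    atp_per_monomer: int
    o2_released_per_monomer: int
    monomer_mass_kg: float
    net_reaction: Reaction = field(compare=False)


def derive_net_stoichiometry() -> NetStoichiometry:
    """Eliminate glucose and tuber-side ATP from the stage reactions.

    Two fixation stages feed one respiration and one polymerisation stage:
    2 x fixation + 1 x respiration + 1 x polymerisation cancels glucose
    exactly and leaves the net reaction
    6 CO2 + 5 H2O + 2 ATP -> C6H10O5 + 6 O2.  An internal assertion guards
    the elemental balance of the result.
    """
    net = combine_reactions(
        [
            (2, GLUCOSE_SYNTHESIS),
            (1, GLUCOSE_RESPIRATION),
            (1, STARCH_POLYMERISATION),
        ]
    )
    if not is_balanced(net):
        raise AssertionError(
            f"stage reactions do not cancel to a balanced net reaction: {net}"
        )
    monomers = net.coefficient(STARCH_MONOMER)
    if monomers != 1:
        raise AssertionError(f"expected one starch monomer in net reaction, got {monomers}")

    def _count(sp: Species, sign: int) -> int:
        c = sign * net.coefficient(sp)
        if c <= 0 or c.denominator != 1:
            raise AssertionError(f"unexpected net coefficient {c} for {sp}")
        return int(c)

    return NetStoichiometry(
        co2_per_monomer=_count(CO2, -1),
        h2o_per_monomer=_count(WATER, -1),
        atp_per_monomer=_count(ATP, -1),
        o2_released_per_monomer=_count(OXYGEN, +1),
        monomer_mass_kg=molecule_mass_kg(STARCH_MONOMER),
        net_reaction=net,
    )


#: Mass of one CO2 molecule, kg — the per-mass estimator path divides by it.
CO2_MOLECULE_MASS_KG = molecule_mass_kg(CO2)
#: Mass of one starch monomer (the constant m1 ~ 27e-26 kg).
STARCH_MONOMER_MASS_KG = molecule_mass_kg(STARCH_MONOMER)
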