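"""Elemental formulas, degrees of reduction, and reaction balance checking.

The central quantity is the generalized degree of reduction γ of a compound:
the number of electron equivalents released per molecule upon complete
oxidation to the reference states CO2, H2O and NH3,

    γ = 4·nC + 1·nH − 2·nO − 3·nN.

Multiplying a net concentration change of a compound by (nC, γ) converts it
to carbon and reductant (electron-equivalent) turnover, the common currency
in which fermentation and methanogenesis budgets are closed. Organic acids
are registered as their neutral protonated formulas (acetic acid C2H4O2,
formic acid CH2O2, propionic acid C3H6O2): the standard factor pairs —
(8,32) N-acetylglucosamine, (1,2) formate, (2,12) ethanol, (2,8) acetate,
(3,14) propionate, (1,8) methane, (1,0) CO2 — hold under this convention,
which also avoids an explicit charge term. The nitrogen reference state is
NH3 (weight −3); this is the convention under which an amino sugar such as
N-acetylglucosamine (C8H15NO6) carries 32 electron equivalents.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from numbers import Rational
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ElementalFormula",
    "Compound",
    "Reaction",
    "BalanceReport",
    "FormulaError",
    "NegativeGammaWarning",
    "parse_formula",
    "degree_of_reduction",
    "carbon_reductant_factors",
    "check_reaction_balance",
    "parse_reaction",
    "load_registry",
    "default_registry",
]

logger = logging.getLogger(__name__)

#: Elements accepted in formulas. S and P parse but are rejected by the
#: degree-of-reduction rule (no reference state is defined for them here).
ALLOWED_ELEMENTS = ("C", "H", "N", "O", "S", "P")

#: Electron equivalents contributed per atom, relative to CO2/H2O/NH3.
GAMMA_WEIGHTS = {"C": 4, "H": 1, "O": -2, "N": -3}


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


class NegativeGammaWarning(UserWarning):
    """A formula has a negative degree of reduction (more oxidized than CO2)."""


@dataclass(frozen=True, eq=False)
class ElementalFormula:
    """Atom counts per molecule, e.g. ``{"C": 2, "H": 6, "O": 1}`` for ethanol.

    Counts are non-negative integers; at least one element must be present.
    Supports ``+`` (combining molecules), which makes the additivity of the
    degree of reduction directly testable.
    """

    counts: Mapping[str, int]

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementalFormula) and self.counts == other.counts

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in ALLOWED_ELEMENTS:
                raise FormulaError(f"unknown element symbol {element!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise FormulaError(f"atom count for {element} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative atom count for {element}: {n}")
            if n > 0:
                cleaned[element] = n
        if not cleaned:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", dict(cleaned))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        ordered = sorted(
            self.counts,
            key=lambda e: (e != "C", e != "H", e),
        )
        return "".join(f"{e}{self.counts[e] if self.counts[e] != 1 else ''}" for e in ordered)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C8H15NO6"``.

    An element symbol may be followed by a positive integer count; an
    omitted count means 1. Repeated symbols accumulate. Raises
    :class:`FormulaError` naming the position of the first offending
    character for malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.group(1), match.group(2)
        if element not in ALLOWED_ELEMENTS:
            raise FormulaError(
                f"unknown element {element!r} in formula {text!r} at position {pos}"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero atom count for {element} in {text!r} at position {pos}")
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    return ElementalFormula(counts)


def degree_of_reduction(formula: ElementalFormula) -> int:
    """Electron equivalents per molecule: γ = 4·C + H − 2·O − 3·N.

    Defined relative to the reference states CO2, H2O and NH3, so fully
    oxidized species (CO2, H2O, NH3 itself) have γ = 0. Only C, H, N, O are
    supported; a formula containing S or P is rejected naming the element.
    Negative values (species more oxidized than the reference, which do not
    occur among common fermentation intermediates) are returned but flagged
    with :class:`NegativeGammaWarning`.
    """
    for element in formula.counts:
        if element not in GAMMA_WEIGHTS:
            raise FormulaError(
                f"degree of reduction undefined for element {element!r} "
                "(only C, H, N, O are supported)"
            )
    gamma = sum(GAMMA_WEIGHTS[e] * n for e, n in formula.counts.items())
    if gamma < 0:
        warnings.warn(
            f"degree of reduction of {formula} is negative ({gamma})",
            NegativeGammaWarning,
            stacklevel=2,
        )
    return gamma


@dataclass(frozen=True)
class Compound:
    """A named chemical species with its molecular formula and phase.

    ``carbon_factor`` (C atoms per molecule) and ``reductant_factor``
    (degree of reduction) are always recomputed from the formula — they are
    derived quantities, never free text.
    """

    name: str
    formula: ElementalFormula
    phase: str = "dissolved"

    def __post_init__(self) -> None:
        if self.phase not in ("dissolved", "gaseous"):
            raise ValueError(f"phase must be 'dissolved' or 'gaseous', got {self.phase!r}")

    @property
    def carbon_factor(self) -> int:
        return self.formula["C"]

    @property
    def reductant_factor(self) -> int:
        return degree_of_reduction(self.formula)


def carbon_reductant_factors(compound: Compound) -> tuple[int, int]:
    """The (carbon, reductant) conversion-factor pair of a compound.

    E.g. acetate (as acetic acid, C2H4O2) → (2, 8); ethanol → (2, 12).
    """
    return compound.carbon_factor, compound.reductant_factor


def _as_fraction(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(x).limit_denominator(10**9)
    raise TypeError(f"stoichiometric coefficient must be a number, got {x!r}")


@dataclass(frozen=True)
class Reaction:
    """A chemical reaction as signed rational coefficients per compound.

    Negative coefficients are consumed species, positive are produced. At
    least one of each is required. Balance is never assumed: it is checked
    explicitly with :func:`check_reaction_balance`.
    """

    name: str
    stoichiometry: Mapping[Compound, Fraction]

    def __post_init__(self) -> None:
        coeffs = {c: _as_fraction(v) for c, v in self.stoichiometry.items() if v != 0}
        if not coeffs:
            raise ValueError(f"reaction {self.name!r} is empty")
        if not any(v < 0 for v in coeffs.values()):
            raise ValueError(f"reaction {self.name!r} has no consumed compound")
        if not any(v > 0 for v in coeffs.values()):
            raise ValueError(f"reaction {self.name!r} has no produced compound")
        object.__setattr__(self, "stoichiometry", coeffs)

    @property
    def reactants(self) -> dict[Compound, Fraction]:
        return {c: -v for c, v in self.stoichiometry.items() if v < 0}

    @property
    def products(self) -> dict[Compound, Fraction]:
        return {c: v for c, v in self.stoichiometry.items() if v > 0}

    def __str__(self) -> str:
        def side(items: dict[Compound, Fraction]) -> str:
            return " + ".join(
                (f"{v} " if v != 1 else "") + c.name for c, v in items.items()
            )

        return f"{side(self.reactants)} -> {side(self.products)}"


@dataclass(frozen=True)
class BalanceReport:
    """Per-element and electron-equivalent residuals of a reaction.

    A residual is Σ coefficient × atom count (or × degree of reduction);
    the reaction is balanced iff every residual is exactly zero. Residuals
    are exact rationals, so "balanced" carries no floating-point tolerance.
    """

    reaction: str
    element_residuals: Mapping[str, Fraction]
    electron_residual: Fraction
    balanced: bool = field(init=False)

    def __post_init__(self) -> None:
        ok = all(v == 0 for v in self.element_residuals.values()) and self.electron_residual == 0
        object.__setattr__(self, "balanced", ok)


def check_reaction_balance(reaction: Reaction) -> BalanceReport:
    """Check conservation of every element and of electron equivalents.

    A reaction that balances all of C, H, N, O necessarily balances
    electrons too (γ is a linear function of the atom counts), so the
    electron residual is a redundant but independently computed check.
    """
    elements = sorted(
        {e for c in reaction.stoichiometry for e in c.formula.counts},
        key=ALLOWED_ELEMENTS.index,
    )
    element_residuals = {
        e: sum((v * c.formula[e] for c, v in reaction.stoichiometry.items()), Fraction(0))
        for e in elements
    }
    electron_residual = sum(
        (v * degree_of_reduction(c.formula) for c, v in reaction.stoichiometry.items()),
        Fraction(0),
    )
    report = BalanceReport(reaction.name, element_residuals, electron_residual)
    if not report.balanced:
        logger.debug("reaction %r is unbalanced: %s", reaction.name, report)
    return report


_COEF_TERM = re.compile(r"^\s*(?:(\d+(?:/\d+)?(?:\.\d+)?)\s+)?(\S+)\s*$")


def parse_reaction(text: str, registry: Mapping[str, Compound], name: str | None = None) -> Reaction:
    """Parse a reaction string like ``"4 formate -> CH4 + 3 CO2 + 2 H2O"``.

    Species are looked up by name in ``registry``; coefficients may be
    integers, fractions (``1/2``) or decimals, and default to 1.
    """
    if "->" not in text:
        raise ValueError(f"reaction string needs '->': {text!r}")
    left, right = text.split("->", maxsplit=1)
    stoich: dict[Compound, Fraction] = {}
    for side, sign in ((left, -1), (right, +1)):
        for term in side.split("+"):
            m = _COEF_TERM.match(term)
            if m is None:
                raise ValueError(f"malformed reaction term {term!r}")
            coef_text, species = m.group(1), m.group(2)
            coef = Fraction(coef_text) if coef_text else Fraction(1)
            if species not in registry:
                raise KeyError(f"compound {species!r} not in registry")
            compound = registry[species]
            stoich[compound] = stoich.get(compound, Fraction(0)) + sign * coef
    return Reaction(name or text.strip(), stoich)


def load_registry(source) -> dict[str, Compound]:
    """Load a compound registry from a YAML mapping ``name -> {formula, phase}``.

    ``source`` may be a path or an open text stream.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("registry must be a mapping of name -> {formula, phase}")
    registry: dict[str, Compound] = {}
    for name, entry in raw.items():
        if isinstance(entry, str):
            entry = {"formula": entry}
        formula = parse_formula(entry["formula"])
        registry[str(name)] = Compound(
            name=str(name), formula=formula, phase=entry.get("phase", "dissolved")
        )
    return registry


def default_registry() -> dict[str, Compound]:
    """The built-in registry of common anaerobic food-chain compounds.

    Covers the amino sugar N-acetylglucosamine (NAG), sugars, volatile fatty
    acids (as neutral acids), alcohols, and the gases CO2, CH4 and H2.
    """
    ref = resources.files("anoxmet.data").joinpath("compounds.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_registry(fh)
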