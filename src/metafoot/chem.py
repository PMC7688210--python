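"""Molecular formulas, nominal oxidation state of carbon, and carbon-mass
unit conversions.

The nominal oxidation state of carbon (NOSC) summarises the average
oxidation state of the carbon atoms implied by a bulk molecular formula.
For a species :math:`\\mathrm{C}_c\\mathrm{H}_h\\mathrm{N}_n\\mathrm{O}_o
\\mathrm{S}_s\\mathrm{P}_p` carrying net charge :math:`Z`,

.. math::

    \\mathrm{NOSC} = 4 - \\frac{-Z + 4c + h - 3n - 2o - 2s + 5p}{c}

Higher values mean more oxidised (CO2 = +4, lower energy content per C),
lower values more reduced (CH4 = -4).  The convention used throughout this
package is the charge-neutral, fully protonated species (Z = 0), which is
how organic and amino acids are tabulated in exometabolomic work.

Carbon masses use the standard atomic weight 12.011 g/mol to bridge
micromolar compound concentrations and mg C/L pool measurements.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "CARBON_MOLAR_MASS",
    "NITROGEN_MOLAR_MASS",
    "CompoundFormula",
    "CarbonAmount",
    "FormulaError",
    "parse_formula",
    "nosc",
    "carbon_mass",
    "round_half_away",
]

#: Standard atomic weight of carbon, g/mol.
CARBON_MOLAR_MASS = 12.011
#: Standard atomic weight of nitrogen, g/mol.
NITROGEN_MOLAR_MASS = 14.007


class FormulaError(ValueError):
    """Raised for malformed formula text or chemistry domain errors."""


@dataclass(frozen=True)
class CompoundFormula:
    """Element counts and net charge of a compound.

    Parameters
    ----------
    name
        Free-text label; defaults to the rendered formula.
    counts
        Mapping element symbol -> count.  Absent elements count as zero.
    charge
        Net charge Z (default 0, the neutral protonated form).
    """

    name: str
    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if not isinstance(n, int) or n < 0:
                raise FormulaError(
                    f"element count must be a non-negative integer: {el}={n!r}"
                )

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def n_carbon(self) -> int:
        return self["C"]

    @property
    def n_nitrogen(self) -> int:
        return self["N"]

    def render(self) -> str:
        """Hill-notation text (C, H, then remaining elements alphabetically)."""
        parts = []
        for el in ("C", "H"):
            n = self[el]
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(set(self.counts) - {"C", "H"}):
            n = self.counts[el]
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        body = "".join(parts)
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            mag = abs(self.charge)
            body += sign if mag == 1 else f"{sign}{mag}"
        return body


@dataclass(frozen=True)
class CarbonAmount:
    """Unit bridge between a compound concentration and its carbon mass.

    ``mass_c`` is derived: concentration (µM) x carbon count x 12.011/1000
    mg C/L.
    """

    concentration: float     # µM
    n_carbon: int

    @property
    def mass_c(self) -> float:
        return carbon_mass(self.concentration, self.n_carbon)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# sign-then-digits needs no caret ("+2", "-"); digits-then-sign ("2-")
# must be caret-prefixed ("^2-") or it is ambiguous with element counts
_CHARGE = re.compile(r"(?:\^(\d+)([+-])|\^?([+-])(\d*))$")


def parse_formula(formula_text: str, name: str | None = None) -> CompoundFormula:
    """Parse a Hill-notation molecular formula such as ``"C5H11NO2S"``.

    An optional trailing charge token is accepted (``"+"``, ``"2-"``,
    ``"-2"``, ``"^2-"``).  Malformed input raises :class:`FormulaError`
    naming the offending token.  Zero carbon is allowed here; it is rejected
    later by :func:`nosc`.
    """
    text = formula_text.strip()
    if not text:
        raise FormulaError("empty formula")
    charge = 0
    m = _CHARGE.search(text)
    if m and m.start() > 0:
        mag1, sign1, sign2, mag2 = m.groups()
        if sign1:
            charge = int(mag1) * (1 if sign1 == "+" else -1)
        else:
            charge = (int(mag2) if mag2 else 1) * (1 if sign2 == "+" else -1)
        text = text[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula_text!r}: "
                f"unexpected token at {text[pos:pos + 3]!r}"
            )
        el, digits = m.groups()
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return CompoundFormula(name=name or formula_text.strip(), counts=counts,
                           charge=charge)


def nosc(f: CompoundFormula) -> float:
    """Nominal oxidation state of carbon of a formula.

    Requires at least one carbon atom; values lie in [-4, +4].  Rounding to
    the customary two decimals is left to presentation
    (:func:`round_half_away`).
    """
    c = f.n_carbon
    if c < 1:
        raise FormulaError("NOSC undefined without carbon")
    z = f.charge
    h, n, o, s, p = f["H"], f["N"], f["O"], f["S"], f["P"]
    return 4.0 - (-z + 4 * c + h - 3 * n - 2 * o - 2 * s + 5 * p) / c


def carbon_mass(concentration_uM: float, n_carbon: float) -> float:
    """Convert a compound concentration (µM) to carbon mass (mg C/L).

    ``mg C/L = µM × nC × 12.011 / 1000``.
    """
    if concentration_uM < 0 or n_carbon < 0:
        raise ValueError("concentration and carbon count must be non-negative")
    return concentration_uM * n_carbon * CARBON_MOLAR_MASS / 1000.0


def nitrogen_mass(concentration_uM: float, n_nitrogen: float) -> float:
    """Convert a compound concentration (µM) to nitrogen mass (mg N/L)."""
    if concentration_uM < 0 or n_nitrogen < 0:
        raise ValueError("concentration and nitrogen count must be non-negative")
    return concentration_uM * n_nitrogen * NITROGEN_MOLAR_MASS / 1000.0


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed tables).

    Python's builtin ``round`` is banker's rounding; printed chemistry
    tables round 0.005 -> 0.01 and -0.005 -> -0.01.
    """
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
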