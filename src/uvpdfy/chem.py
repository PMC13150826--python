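"""Elemental compositions and monoisotopic mass arithmetic.

Chemistry constants (isotope masses/abundances, residue formulas) are loaded
once from versioned TSV tables bundled with the package, so the numbers that
every downstream mass calculation depends on live in one inspectable place.
"""

from __future__ import annotations

import re
from importlib.resources import files

__all__ = [
    "Composition",
    "ISOTOPES",
    "MONO_MASS",
    "RESIDUE_FORMULAS",
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "WATER",
    "element_mass",
    "parse_formula",
]

PROTON_MASS = 1.007276466  # H+ (proton), Da
HYDROGEN_MASS = 1.0078250319  # neutral H atom, Da

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class Composition(dict):
    """Element -> signed atom count. Supports +, -, integer *, and mass()."""

    def __add__(self, other: "Composition") -> "Composition":
        out = Composition(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return out.trimmed()

    def __sub__(self, other: "Composition") -> "Composition":
        out = Composition(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
        return out.trimmed()

    def __mul__(self, k: int) -> "Composition":
        return Composition({el: n * k for el, n in self.items()}).trimmed()

    __rmul__ = __mul__

    def trimmed(self) -> "Composition":
        """Drop zero-count elements (keeps equality semantics clean)."""
        return Composition({el: n for el, n in self.items() if n != 0})

    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(n * element_mass(el) for el, n in self.items())

    def formula(self) -> str:
        return "".join(
            f"{el}{n}" for el, n in sorted(self.items()) if n != 0
        )


def _load_isotopes() -> dict[str, list[tuple[float, float]]]:
    table: dict[str, list[tuple[float, float]]] = {}
    text = files("uvpdfy.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sym, mass, ab = line.split("\t")
        table.setdefault(sym, []).append((float(mass), float(ab)))
    for sym, rows in table.items():
        rows.sort()  # by mass, ascending
    return table


ISOTOPES: dict[str, list[tuple[float, float]]] = _load_isotopes()

# Monoisotopic convention: the most abundant isotope of each element.
MONO_MASS: dict[str, float] = {
    sym: max(rows, key=lambda r: r[1])[0] for sym, rows in ISOTOPES.items()
}


def element_mass(symbol: str) -> float:
    try:
        return MONO_MASS[symbol]
    except KeyError:
        raise KeyError(
            f"unknown element {symbol!r}; known: {sorted(MONO_MASS)}"
        ) from None


def parse_formula(formula: str) -> Composition:
    """Parse 'C2H3NO' style formulas into a Composition."""
    comp = Composition()
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
        pos = m.end()
        el = m.group(1)
        if el not in ISOTOPES:
            raise KeyError(f"unknown element {el!r} in formula {formula!r}")
        n = int(m.group(2)) if m.group(2) else 1
        comp[el] = comp.get(el, 0) + n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
    return comp.trimmed()


def _load_residues() -> dict[str, Composition]:
    table: dict[str, Composition] = {}
    text = files("uvpdfy.data").joinpath("residues.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        code, formula = line.split("\t")
        table[code] = parse_formula(formula)
    return table


RESIDUE_FORMULAS: dict[str, Composition] = _load_residues()

WATER = parse_formula("H2O")
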