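"""Protein sequences, region schemes, ion-series chemistry and the theoretical
fragment database.

Coordinate conventions
----------------------
Residues are 1-based. A cleavage site ``i`` (1 <= i <= L-1) is the backbone
bond between residues ``i`` and ``i+1``; the N-terminal fragment at site ``i``
spans residues ``1..i`` and the C-terminal fragment spans ``i+1..L``, so the
two fragments at one site are complementary.

Ion-series neutral masses are expressed relative to the summed residue masses
of the fragment span: ``b`` carries no offset, ``y`` adds H2O, ``a = b - CO``,
``c = b + NH3``, ``x = y + CO - H2``, ``z = y - NH3 + H`` (z-radical), and
every ``+k``/``-k`` satellite shifts its base series by k hydrogen atoms —
the hydrogen-transfer satellites characteristic of photodissociation spectra.

Zn2+ adducts: native metal binding is usually charge-compensated, so the
default per-zinc neutral delta is Zn - 2H (+61.913492 Da); bare Zn addition
(+63.929142 Da) is available as an alternative convention.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import numpy as np

from .chem import (
    Composition,
    HYDROGEN_MASS,
    RESIDUE_FORMULAS,
    WATER,
    parse_formula,
)

__all__ = [
    "ProteinSequence",
    "RegionScheme",
    "IonSeries",
    "ION_SERIES",
    "SERIES_PRIORITY",
    "N_TERMINAL_SERIES",
    "C_TERMINAL_SERIES",
    "AdductConvention",
    "ZN_MINUS_2H",
    "ZN_BARE",
    "FragmentSpecies",
    "FragmentDatabase",
    "residue_composition",
    "fragment_neutral_mass",
    "species_composition",
    "build_fragment_database",
    "alpha_synuclein",
]

_CO = parse_formula("CO")
_NH3 = parse_formula("NH3")
_H = parse_formula("H")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein as an ordered string of one-letter residue codes.

    ``n_terminus``/``c_terminus`` are composition deltas added to the bare
    residue chain (defaults H and OH, i.e. a free, unmodified protein).
    """

    identifier: str
    residues: str
    n_terminus: Composition = field(default_factory=lambda: parse_formula("H"))
    c_terminus: Composition = field(default_factory=lambda: parse_formula("OH"))

    def __post_init__(self) -> None:
        bad = sorted(set(self.residues) - set(RESIDUE_FORMULAS))
        if bad:
            raise ValueError(f"non-standard residue codes: {bad}")
        if len(self.residues) < 2:
            raise ValueError("sequence must have at least 2 residues")

    @property
    def length(self) -> int:
        return len(self.residues)

    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass of the intact protein."""
        m = sum(RESIDUE_FORMULAS[r].mass() for r in self.residues)
        return m + self.n_terminus.mass() + self.c_terminus.mass()

    def composition(self) -> Composition:
        return residue_composition(self, 1, self.length)

    @classmethod
    def from_fasta(cls, path: str | Path, identifier: str | None = None) -> "ProteinSequence":
        header = None
        chunks: list[str] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    break  # first record only
                header = line[1:].split()[0]
            else:
                chunks.append(line)
        if header is None or not chunks:
            raise ValueError(f"no FASTA record found in {path}")
        return cls(identifier or header, "".join(chunks).upper())


def alpha_synuclein() -> ProteinSequence:
    """The bundled human α-synuclein sequence (UniProt P37840, 140 aa)."""
    with files("uvpdfy.data").joinpath("P37840.fasta").open("r") as fh:
        lines = fh.read().splitlines()
    seq = "".join(l.strip() for l in lines if l and not l.startswith(">"))
    return ProteinSequence("P37840", seq)


@dataclass(frozen=True)
class RegionScheme:
    """Named, ordered, disjoint 1-based inclusive residue ranges covering [1, L]."""

    regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.regions:
            if start != prev_end + 1 or end < start:
                raise ValueError(
                    f"regions must be contiguous and ordered; bad range {name}=[{start},{end}]"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return self.regions[-1][2]

    def label(self, residue: int) -> str:
        for name, start, end in self.regions:
            if start <= residue <= end:
                return name
        raise ValueError(f"residue {residue} outside [1, {self.length}]")

    @classmethod
    def synuclein_default(cls, L: int = 140) -> "RegionScheme":
        """Nterm 1-60 (amphipathic), NAC 61-95 (aggregation core), Cterm 96-L (acidic)."""
        return cls((("Nterm", 1, 60), ("NAC", 61, 95), ("Cterm", 96, L)))


@dataclass(frozen=True)
class IonSeries:
    name: str
    terminus: str  # "N" or "C"
    offset: Composition  # relative to summed residue formulas of the span
    hydrogen_shift: int = 0  # satellite H-atom transfers relative to base series

    def offset_mass(self) -> float:
        return self.offset.mass() + self.hydrogen_shift * HYDROGEN_MASS


def _series_table() -> dict[str, IonSeries]:
    zero = Composition()
    base = {
        "b": IonSeries("b", "N", zero),
        "a": IonSeries("a", "N", zero - _CO),
        "c": IonSeries("c", "N", zero + _NH3),
        "y": IonSeries("y", "C", WATER),
        "x": IonSeries("x", "C", WATER + _CO - 2 * _H),
        "z": IonSeries("z", "C", WATER - _NH3 + _H),
    }
    sats = {
        "a+1": IonSeries("a+1", "N", base["a"].offset, +1),
        "a+2": IonSeries("a+2", "N", base["a"].offset, +2),
        "x+1": IonSeries("x+1", "C", base["x"].offset, +1),
        "y-1": IonSeries("y-1", "C", base["y"].offset, -1),
        "y-2": IonSeries("y-2", "C", base["y"].offset, -2),
        "z+1": IonSeries("z+1", "C", base["z"].offset, +1),
    }
    return {**base, **sats}


ION_SERIES: dict[str, IonSeries] = _series_table()

N_TERMINAL_SERIES = ("a", "a+1", "a+2", "b", "c")
C_TERMINAL_SERIES = ("x", "x+1", "y", "y-1", "y-2", "z", "z+1")
ALL_SERIES = N_TERMINAL_SERIES + C_TERMINAL_SERIES

# the five series that define the per-site UVPD fragment yield
FY_SERIES = ("a", "a+1", "a+2", "x", "x+1")

# deterministic tie-break order for ambiguous assignments: base series first
SERIES_PRIORITY = ("b", "y", "a", "x", "c", "z", "a+1", "x+1", "y-1", "z+1", "a+2", "y-2")


@dataclass(frozen=True)
class AdductConvention:
    """Per-zinc neutral mass/composition delta applied to holo species."""

    name: str
    delta: Composition

    def delta_mass(self) -> float:
        return self.delta.mass()


ZN_MINUS_2H = AdductConvention("Zn-2H", parse_formula("Zn") - 2 * _H)
ZN_BARE = AdductConvention("Zn", parse_formula("Zn"))


def residue_composition(seq: ProteinSequence, start: int, end: int) -> Composition:
    """Summed residue composition of residues ``start..end`` (1-based inclusive).

    Terminus deltas are added only when the span touches the corresponding end
    of the protein. ``end < start`` denotes the empty span.
    """
    if end < start:
        return Composition()
    if start < 1 or end > seq.length:
        raise IndexError(f"span [{start},{end}] outside [1,{seq.length}]")
    comp = Composition()
    for r in seq.residues[start - 1 : end]:
        comp = comp + RESIDUE_FORMULAS[r]
    if start == 1:
        comp = comp + seq.n_terminus
    if end == seq.length:
        comp = comp + seq.c_terminus
    return comp


def fragment_neutral_mass(
    seq: ProteinSequence,
    series: str | IonSeries,
    site: int,
    zinc_count: int = 0,
    adduct: AdductConvention = ZN_MINUS_2H,
) -> float:
    """Neutral monoisotopic mass of the ``series`` fragment at cleavage ``site``."""
    ser = ION_SERIES[series] if isinstance(series, str) else series
    if not 1 <= site <= seq.length - 1:
        raise IndexError(f"site {site} outside [1,{seq.length - 1}]")
    if zinc_count < 0:
        raise ValueError("zinc_count must be >= 0")
    if ser.terminus == "N":
        span = seq.residues[:site]
    else:
        span = seq.residues[site:]
    m = sum(RESIDUE_FORMULAS[r].mass() for r in span)
    return m + ser.offset_mass() + zinc_count * adduct.delta_mass()


@dataclass(frozen=True)
class FragmentSpecies:
    """One theoretical fragment: (series, cleavage site, zinc count)."""

    series: str
    site: int
    zinc_count: int
    mass: float

    @property
    def terminus(self) -> str:
        return ION_SERIES[self.series].terminus

    @property
    def is_holo(self) -> bool:
        return self.zinc_count > 0


def species_composition(
    seq: ProteinSequence,
    species: FragmentSpecies,
    adduct: AdductConvention = ZN_MINUS_2H,
) -> Composition:
    """Elemental composition of a fragment species, including satellite H shifts
    and zinc adducts. Satellites are whole hydrogen-atom transfers, so the
    composition stays integral."""
    ser = ION_SERIES[species.series]
    if ser.terminus == "N":
        start, end = 1, species.site
    else:
        start, end = species.site + 1, seq.length
    comp = Composition()
    for r in seq.residues[start - 1 : end]:
        comp = comp + RESIDUE_FORMULAS[r]
    comp = comp + ser.offset
    if ser.hydrogen_shift:
        comp = comp + ser.hydrogen_shift * _H
    if species.zinc_count:
        comp = comp + species.zinc_count * adduct.delta
    return comp


class FragmentDatabase:
    """All theoretical fragment species of one protein, sorted by neutral mass,
    with relative-tolerance mass queries."""

    def __init__(
        self,
        seq: ProteinSequence,
        species: list[FragmentSpecies],
        adduct: AdductConvention,
        max_zinc: int,
    ):
        self.sequence = seq
        self.adduct = adduct
        self.max_zinc = max_zinc
        self.species = sorted(species, key=lambda s: s.mass)
        self.masses = np.array([s.mass for s in self.species])

    def __len__(self) -> int:
        return len(self.species)

    def query(self, mass: float, tol: float = 2e-6) -> list[int]:
        """Indices of species whose theoretical mass m satisfies
        |mass - m| / m <= tol (relative error w.r.t. the theoretical mass)."""
        lo = mass / (1.0 + tol)
        hi = mass / (1.0 - tol) if tol < 1 else np.inf
        i = bisect.bisect_left(self.masses, lo)
        j = bisect.bisect_right(self.masses, hi)
        return list(range(i, j))

    def query_many(self, masses: np.ndarray, tol: float = 2e-6) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized window bounds: (lo_idx, hi_idx) per query mass."""
        masses = np.asarray(masses, dtype=float)
        lo = np.searchsorted(self.masses, masses / (1.0 + tol), side="left")
        hi = np.searchsorted(self.masses, masses / (1.0 - tol), side="right")
        return lo, hi


def build_fragment_database(
    seq: ProteinSequence,
    series_set: tuple[str, ...] = ALL_SERIES,
    max_zinc: int = 0,
    adduct: AdductConvention = ZN_MINUS_2H,
) -> FragmentDatabase:
    """One species per (series, site, zinc count) triple; |series| x (L-1) x (max_zinc+1)."""
    if not series_set:
        raise ValueError("series_set must be non-empty")
    if max_zinc < 0:
        raise ValueError("max_zinc must be >= 0")
    unknown = [s for s in series_set if s not in ION_SERIES]
    if unknown:
        raise KeyError(f"unknown ion series: {unknown}")

    residue_masses = np.array([RESIDUE_FORMULAS[r].mass() for r in seq.residues])
    prefix = np.concatenate([[0.0], np.cumsum(residue_masses)])
    total = prefix[-1]
    dzn = adduct.delta_mass()

    out: list[FragmentSpecies] = []
    for name in series_set:
        ser = ION_SERIES[name]
        off = ser.offset_mass()
        for site in range(1, seq.length):
            if ser.terminus == "N":
                base = prefix[site] + off
            else:
                base = total - prefix[site] + off
            for n in range(max_zinc + 1):
                out.append(FragmentSpecies(name, site, n, base + n * dzn))
    return FragmentDatabase(seq, out, adduct, max_zinc)
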