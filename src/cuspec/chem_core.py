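"""Elemental mass bookkeeping, molecular-formula arithmetic and theoretical
isotope patterns.

This module is the arithmetic backbone of the copper-speciation chain.  Two
mass conventions are supported throughout the package:

``nominal``
    Integer mass built from the most abundant isotope of each element.  This
    is the convention of unit-resolution triple-quadrupole data, and every
    quasi-molecular and product ion handled downstream is an integer m/z.
``monoisotopic``
    Exact mass built from the lightest isotope of each element, accurate to
    better than 1e-4 Da for the elements shipped here.

The copper entry deliberately carries the rounded 69/31 abundance pair for
63Cu/65Cu: the downstream isotope screen keys on the A/A+2 doublet with an
intensity ratio of 31/69 = 0.449, and the element table is the single source
of that number.

Element and amino-acid tables can be overridden from a YAML configuration
file (see :func:`load_tables`); the built-in defaults cover H, C, N, O, S and
Cu plus the 20 proteinogenic amino acids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ChemError",
    "UnknownElementError",
    "UnknownAminoAcidError",
    "Isotope",
    "Element",
    "MolecularFormula",
    "AminoAcid",
    "IsotopePattern",
    "ComplexIon",
    "DEFAULT_ELEMENTS",
    "AMINO_ACIDS",
    "WATER",
    "nominal_mass",
    "monoisotopic_mass",
    "isotope_pattern",
    "complex_formula",
    "load_tables",
]


class ChemError(ValueError):
    """Base error for formula/table problems."""


class UnknownElementError(ChemError):
    def __init__(self, symbol: str):
        super().__init__(f"unknown element symbol: {symbol!r}")
        self.symbol = symbol


class UnknownAminoAcidError(ChemError):
    def __init__(self, code: str):
        super().__init__(f"unknown amino-acid code: {code!r}")
        self.code = code


@dataclass(frozen=True)
class Isotope:
    mass: float  # Da, exact
    abundance: float  # fraction in [0, 1]


@dataclass(frozen=True)
class Element:
    symbol: str
    isotopes: tuple[Isotope, ...]

    def __post_init__(self) -> None:
        total = sum(i.abundance for i in self.isotopes)
        if abs(total - 1.0) > 1e-6:
            raise ChemError(
                f"isotope abundances of {self.symbol} sum to {total}, not 1"
            )

    @property
    def most_abundant(self) -> Isotope:
        return max(self.isotopes, key=lambda i: i.abundance)

    @property
    def lightest(self) -> Isotope:
        return min(self.isotopes, key=lambda i: i.mass)

    @property
    def nominal_mass(self) -> int:
        """Integer Da of the most abundant isotope."""
        return round(self.most_abundant.mass)

    @property
    def monoisotopic_mass(self) -> float:
        """Exact mass of the lightest isotope."""
        return self.lightest.mass


def _elements(spec: dict[str, list[tuple[float, float]]]) -> dict[str, Element]:
    return {
        sym: Element(sym, tuple(Isotope(m, a) for m, a in isos))
        for sym, isos in spec.items()
    }


# Exact masses: CODATA/IUPAC values. Cu abundances use the rounded 69/31
# convention on which the doublet screen is built.
DEFAULT_ELEMENTS: dict[str, Element] = _elements(
    {
        "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
        "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
        "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
        "O": [
            (15.9949146221, 0.99757),
            (16.9991315, 0.00038),
            (17.9991604, 0.00205),
        ],
        "S": [
            (31.97207069, 0.9499),
            (32.97145850, 0.0075),
            (33.96786683, 0.0425),
            (35.96708088, 0.0001),
        ],
        "Cu": [(62.9295989, 0.69), (64.9277929, 0.31)],
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class MolecularFormula:
    """An element→count mapping with an integer charge.

    Immutable in practice: arithmetic returns new instances.  Supports
    ``+``/``-`` (element-wise; subtraction raises if any count would go
    negative) and ``*`` by a non-negative integer.
    """

    __slots__ = ("_counts", "charge")

    def __init__(self, counts: Mapping[str, int] | None = None, charge: int = 0):
        clean: dict[str, int] = {}
        for sym, n in (counts or {}).items():
            if not isinstance(n, int):
                raise ChemError(f"count for {sym} must be an integer, got {n!r}")
            if n < 0:
                raise ChemError(f"negative count for element {sym}: {n}")
            if n > 0:
                clean[sym] = n
        self._counts = clean
        self.charge = int(charge)

    @classmethod
    def from_string(cls, s: str, charge: int = 0) -> "MolecularFormula":
        """Parse a plain formula string such as ``'C4H7NO'`` or ``'H2O'``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos:
                raise ChemError(f"cannot parse formula {s!r} at position {pos}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        if pos != len(s):
            raise ChemError(f"cannot parse formula {s!r} at position {pos}")
        return cls(counts, charge)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def is_empty(self) -> bool:
        return not self._counts

    def replace_charge(self, charge: int) -> "MolecularFormula":
        return MolecularFormula(self._counts, charge)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self._counts)
        for sym, n in other._counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return MolecularFormula(counts, self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self._counts)
        for sym, n in other._counts.items():
            new = counts.get(sym, 0) - n
            if new < 0:
                raise ChemError(
                    f"subtraction would give negative count for {sym}"
                )
            counts[sym] = new
        return MolecularFormula(counts, self.charge - other.charge)

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            raise ChemError(f"formula multiplier must be a non-negative int: {k!r}")
        return MolecularFormula({s: n * k for s, n in self._counts.items()},
                                self.charge * k)

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self._counts == other._counts and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((frozenset(self._counts.items()), self.charge))

    def __repr__(self) -> str:
        # Hill order: C, H, then alphabetical
        syms = sorted(
            self._counts,
            key=lambda s: (s != "C", s != "H", s),
        )
        body = "".join(
            f"{s}{self._counts[s] if self._counts[s] > 1 else ''}" for s in syms
        )
        q = {0: "", 1: "+", -1: "-"}.get(self.charge, f"{self.charge:+d}")
        return f"MolecularFormula({body or 'empty'}{q})"

    # -- masses ---------------------------------------------------------

    def nominal_mass(self, elements: Mapping[str, Element] | None = None) -> int:
        return nominal_mass(self, elements)

    def monoisotopic_mass(
        self, elements: Mapping[str, Element] | None = None
    ) -> float:
        return monoisotopic_mass(self, elements)


WATER = MolecularFormula.from_string("H2O")
_H = MolecularFormula.from_string("H")


def _check_nonempty(formula: MolecularFormula) -> None:
    if formula.is_empty():
        raise ChemError("empty molecular formula has no mass")


def nominal_mass(
    formula: MolecularFormula, elements: Mapping[str, Element] | None = None
) -> int:
    """Integer mass from the most abundant isotope of each element.

    The charge does not alter the mass: protonation/deprotonation is
    bookkeeping done on the formula itself (±H), not here.
    """
    _check_nonempty(formula)
    table = DEFAULT_ELEMENTS if elements is None else elements
    total = 0
    for sym, n in formula.counts.items():
        if sym not in table:
            raise UnknownElementError(sym)
        total += n * table[sym].nominal_mass
    return total


def monoisotopic_mass(
    formula: MolecularFormula, elements: Mapping[str, Element] | None = None
) -> float:
    """Exact mass from the lightest isotope of each element (electron mass
    neglected for ions; < 6e-4 Da at charge 1)."""
    _check_nonempty(formula)
    table = DEFAULT_ELEMENTS if elements is None else elements
    total = 0.0
    for sym, n in formula.counts.items():
        if sym not in table:
            raise UnknownElementError(sym)
        total += n * table[sym].monoisotopic_mass
    return total


@dataclass(frozen=True)
class IsotopePattern:
    """Unit-mass-aggregated isotopologue distribution.

    ``peaks`` are (m/z, relative intensity in % of base peak), ascending in
    m/z, base peak exactly 100.
    """

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ChemError("isotope pattern must contain at least one peak")
        mzs = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ChemError("pattern peaks must be strictly ascending in m/z")
        rels = [p[1] for p in self.peaks]
        if not any(r == 100.0 for r in rels):
            raise ChemError("pattern base peak must have intensity exactly 100")
        if any(not (0.0 < r <= 100.0) for r in rels):
            raise ChemError("pattern intensities must lie in (0, 100]")

    @property
    def base_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]

    def binned(self) -> dict[int, float]:
        """Intensities keyed by unit mass (rounded m/z)."""
        out: dict[int, float] = {}
        for mz, rel in self.peaks:
            key = round(mz)
            out[key] = out.get(key, 0.0) + rel
        return out


def isotope_pattern(
    formula: MolecularFormula,
    min_rel_intensity: float = 1.0,
    elements: Mapping[str, Element] | None = None,
) -> IsotopePattern:
    """Full isotopologue distribution aggregated at unit-mass resolution.

    Per-element distributions are convolved atom by atom on an integer
    nominal-mass grid; isotopologues landing in the same unit bin are merged
    (probability-weighted mean exact mass).  The result is normalised to base
    peak = 100 and truncated below ``min_rel_intensity`` (percent).
    """
    _check_nonempty(formula)
    if not (0.0 < min_rel_intensity < 100.0):
        raise ChemError("min_rel_intensity must lie strictly between 0 and 100")
    table = DEFAULT_ELEMENTS if elements is None else elements

    # bin -> [probability, probability-weighted exact mass]
    dist: dict[int, list[float]] = {0: [1.0, 0.0]}
    for sym, count in formula.counts.items():
        if sym not in table:
            raise UnknownElementError(sym)
        single = [
            (round(i.mass), i.mass, i.abundance) for i in table[sym].isotopes
        ]
        for _ in range(count):
            new: dict[int, list[float]] = {}
            for b, (p, wm) in dist.items():
                for ib, im, ia in single:
                    q = p * ia
                    if q < 1e-15:
                        continue
                    slot = new.setdefault(b + ib, [0.0, 0.0])
                    slot[0] += q
                    slot[1] += q * (wm / p + im) if p else 0.0
            dist = new

    base_p = max(p for p, _ in dist.values())
    peaks = []
    for b in sorted(dist):
        p, wm = dist[b]
        rel = 100.0 * (p / base_p)
        if rel >= min_rel_intensity:
            peaks.append((wm / p, rel))
    return IsotopePattern(tuple(peaks))


# ---------------------------------------------------------------------------
# Amino acids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AminoAcid:
    """A proteinogenic amino acid: free-molecule formula plus the residue
    (free − H2O) used for peptide-bond and residue-loss bookkeeping."""

    code: str  # 3-letter code
    free_formula: MolecularFormula = field(compare=False)

    @property
    def residue_formula(self) -> MolecularFormula:
        return self.free_formula - WATER

    def free_nominal(self, elements=None) -> int:
        return self.free_formula.nominal_mass(elements)

    def residue_nominal(self, elements=None) -> int:
        return self.residue_formula.nominal_mass(elements)


def _aa_table(spec: dict[str, str]) -> dict[str, AminoAcid]:
    return {
        code: AminoAcid(code, MolecularFormula.from_string(f))
        for code, f in spec.items()
    }


AMINO_ACIDS: dict[str, AminoAcid] = _aa_table(
    {
        "Gly": "C2H5NO2",
        "Ala": "C3H7NO2",
        "Ser": "C3H7NO3",
        "Pro": "C5H9NO2",
        "Val": "C5H11NO2",
        "Thr": "C4H9NO3",
        "Cys": "C3H7NO2S",
        "Leu": "C6H13NO2",
        "Ile": "C6H13NO2",
        "Asn": "C4H8N2O3",
        "Asp": "C4H7NO4",
        "Gln": "C5H10N2O3",
        "Lys": "C6H14N2O2",
        "Glu": "C5H9NO4",
        "Met": "C5H11NO2S",
        "His": "C6H9N3O2",
        "Phe": "C9H11NO2",
        "Arg": "C6H14N4O2",
        "Tyr": "C9H11NO3",
        "Trp": "C11H12N2O2",
    }
)


# ---------------------------------------------------------------------------
# Cu(II) complex assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComplexIon:
    """A singly charged metal–ligand complex ion with both mass readings."""

    formula: MolecularFormula
    nominal_mz: int
    monoisotopic_mz: float
    polarity: str


def complex_formula(
    ligands: Iterable[str],
    n_peptide_bonds: int = 0,
    n_water_adducts: int = 0,
    metal: str | None = "Cu",
    polarity: str = "+",
    aa_table: Mapping[str, AminoAcid] | None = None,
    elements: Mapping[str, Element] | None = None,
) -> ComplexIon:
    """Assemble a singly charged metal–amino-acid complex ion.

    The composition model: sum of free amino acids, minus one H2O per peptide
    bond, plus whole H2O adducts, plus the metal displacing two protons (the
    divalent-metal binding convention), then ±H for the electrospray charge::

        M = Σ free(AA) − n_bonds·H2O + n_waters·H2O + metal − 2H
        m/z = M + H   (positive mode)   or   M − H   (negative mode)

    With ``metal=None`` the ion is the plain (de)protonated species.
    """
    ligs = list(ligands)
    if not ligs:
        raise ChemError("at least one ligand is required")
    if polarity not in ("+", "-"):
        raise ChemError(f"polarity must be '+' or '-', got {polarity!r}")
    if not (0 <= n_peptide_bonds <= len(ligs) - 1):
        raise ChemError(
            f"n_peptide_bonds={n_peptide_bonds} invalid for {len(ligs)} ligand(s)"
        )
    if n_water_adducts < 0:
        raise ChemError("n_water_adducts must be >= 0")
    table = AMINO_ACIDS if aa_table is None else aa_table

    total = MolecularFormula()
    for code in ligs:
        if code not in table:
            raise UnknownAminoAcidError(code)
        total = total + table[code].free_formula
    total = total - n_peptide_bonds * WATER + n_water_adducts * WATER
    if metal is not None:
        total = (total + MolecularFormula({metal: 1})) - 2 * _H
    if polarity == "+":
        total = (total + _H).replace_charge(+1)
    else:
        total = (total - _H).replace_charge(-1)

    return ComplexIon(
        formula=total,
        nominal_mz=total.nominal_mass(elements),
        monoisotopic_mz=total.monoisotopic_mass(elements),
        polarity=polarity,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_tables(path) -> tuple[dict[str, Element], dict[str, AminoAcid]]:
    """Load element/amino-acid overrides from a YAML file.

    Schema::

        elements:
          Cu:
            isotopes: [[62.9295989, 0.69], [64.9277929, 0.31]]
        amino_acids:
          Gly: C2H5NO2

    Entries merge over the built-in defaults; either section may be absent.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    elements = dict(DEFAULT_ELEMENTS)
    for sym, entry in (cfg.get("elements") or {}).items():
        isos = tuple(Isotope(float(m), float(a)) for m, a in entry["isotopes"])
        elements[sym] = Element(sym, isos)
    aas = dict(AMINO_ACIDS)
    for code, f in (cfg.get("amino_acids") or {}).items():
        aas[code] = AminoAcid(code, MolecularFormula.from_string(f))
    return elements, aas
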