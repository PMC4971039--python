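"""Neutral-loss annotation of CID product-ion lists.

Product ions of a Cu(II)–amino-acid complex are explained as chains of
neutral losses from the precursor: small molecules (H2O, CO, CO2, NH3, ...),
whole free amino acids, or amino-acid residues (free − H2O).  Unit-resolution
CID interpretation additionally needs small ±H2 corrections (hydrogen
transfer during Cu-mediated fragmentation); these are allowed but penalized
and capped, because an unbounded ±nH2 term could explain any even mass
difference.

For interpreting a specific complex, restrict the amino-acid entries to the
precursor's proposed ligands (:meth:`LossLibrary.for_ligands`); with the full
20-amino-acid library, chemically meaningless ties appear (e.g. a valine loss
masquerading for −Thr+H2 on a complex that contains no valine).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping

import pandas as pd

from .chem_core import (
    AMINO_ACIDS,
    AminoAcid,
    ChemError,
    MolecularFormula,
    WATER,
)
from .isotope_screen import PeakList, find_doublets
from . import chem_core

__all__ = [
    "LossEntry",
    "LossLibrary",
    "FragmentAnnotation",
    "annotate_products",
    "annotate_chain",
    "cu_fragment_mz",
    "flag_cu_products",
    "formula_matches_mz",
]


@dataclass(frozen=True)
class LossEntry:
    label: str
    nominal: int  # Da
    exact: float  # Da

    def __post_init__(self) -> None:
        if self.nominal <= 0 or self.exact <= 0:
            raise ChemError(f"loss {self.label!r} must have positive mass")


def _entry(label: str, formula: str) -> LossEntry:
    f = MolecularFormula.from_string(formula)
    return LossEntry(label, f.nominal_mass(), f.monoisotopic_mass())


_SMALL_LOSSES: tuple[LossEntry, ...] = (
    _entry("H2O", "H2O"),
    LossEntry("2H2O", 36, 2 * WATER.monoisotopic_mass()),
    _entry("CO", "CO"),
    _entry("CO2", "CO2"),
    _entry("NH3", "NH3"),
    _entry("C2H3NO", "C2H3NO"),
    # H2 is listed for completeness; the annotator handles hydrogen
    # adjustments through its dedicated ±H2 channel, never as a step.
    _entry("H2", "H2"),
)


class LossLibrary:
    """An immutable set of labelled neutral losses with unique labels."""

    def __init__(self, entries: Iterable[LossEntry]):
        entries = tuple(entries)
        labels = [e.label for e in entries]
        if len(set(labels)) != len(labels):
            raise ChemError("loss labels must be unique")
        self.entries = entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @staticmethod
    def _aa_entries(codes, aa_table: Mapping[str, AminoAcid]):
        out = []
        for code in sorted(set(codes)):
            if code not in aa_table:
                raise ChemError(f"unknown amino-acid code: {code!r}")
            aa = aa_table[code]
            out.append(
                LossEntry(code, aa.free_nominal(),
                          aa.free_formula.monoisotopic_mass())
            )
            res = aa.residue_formula
            out.append(
                LossEntry(f"{code}(res)", res.nominal_mass(),
                          res.monoisotopic_mass())
            )
        return out

    @classmethod
    def default(cls, aa_table: Mapping[str, AminoAcid] | None = None
                ) -> "LossLibrary":
        """Small losses plus every free amino acid and every residue."""
        table = AMINO_ACIDS if aa_table is None else aa_table
        return cls(_SMALL_LOSSES + tuple(cls._aa_entries(table, table)))

    @classmethod
    def for_ligands(cls, ligands: Iterable[str],
                    aa_table: Mapping[str, AminoAcid] | None = None
                    ) -> "LossLibrary":
        """Small losses plus free/residue entries for the given ligands only
        — the library to use when interpreting a proposed complex."""
        table = AMINO_ACIDS if aa_table is None else aa_table
        return cls(_SMALL_LOSSES + tuple(cls._aa_entries(ligands, table)))


@dataclass(frozen=True)
class FragmentAnnotation:
    """A precursor→product edge labelled with neutral losses.

    ``losses`` are library labels (each a loss); ``n_h2_adjustments`` is the
    signed H2 count (positive = additional H2 lost, negative = H2 gained).
    Conservation: sum of loss masses + 2·n_h2 = parent − product, exactly, in
    nominal mode.  ``explained`` is False when no combination within the step
    and H2 caps matches; such products are returned unannotated.
    """

    parent_mz: int
    product_mz: int
    losses: tuple[str, ...]
    n_h2_adjustments: int
    explained: bool
    cu_retained: bool | None = None

    def net_loss_mass(self, library: "LossLibrary") -> int:
        by_label = {e.label: e.nominal for e in library}
        return sum(by_label[l] for l in self.losses) + 2 * self.n_h2_adjustments

    def describe(self) -> str:
        if not self.explained:
            return f"{self.parent_mz} -> {self.product_mz}  (unexplained)"
        parts = [f"-{l}" for l in self.losses]
        if self.n_h2_adjustments > 0:
            parts.append(f"-{self.n_h2_adjustments}H2"
                         if self.n_h2_adjustments > 1 else "-H2")
        elif self.n_h2_adjustments < 0:
            k = -self.n_h2_adjustments
            parts.append(f"+{k}H2" if k > 1 else "+H2")
        label = " ".join(parts) if parts else "(no loss)"
        return f"{self.parent_mz} {label} -> {self.product_mz}"


def annotate_products(
    precursor_mz: float,
    products: Iterable[float],
    library: LossLibrary | None = None,
    max_steps: int = 3,
    max_h2: int = 3,
) -> list[FragmentAnnotation]:
    """Explain each product as a minimal-step neutral-loss combination.

    Search: all multisets of up to ``max_steps`` library losses, each with a
    signed H2 adjustment of at most ``max_h2`` units, matched exactly against
    the nominal mass difference.  Preference order: fewest steps, then fewest
    |H2| adjustments, then lexicographic loss labels.
    """
    if max_steps < 1:
        raise ChemError("max_steps must be >= 1")
    lib = LossLibrary.default() if library is None else library
    prec = round(float(precursor_mz))
    prods = [round(float(p)) for p in products]
    for p in prods:
        if p >= prec:
            raise ChemError(
                f"product m/z {p} is not below precursor m/z {prec}"
            )
    steppable = [e for e in lib if e.label != "H2"]

    annotations = []
    for p in prods:
        diff = prec - p
        best = None
        for n_steps in range(0, max_steps + 1):
            for combo in combinations_with_replacement(steppable, n_steps):
                rem = diff - sum(e.nominal for e in combo)
                if rem % 2 != 0:
                    continue
                h2 = rem // 2
                if abs(h2) > max_h2:
                    continue
                if n_steps == 0 and h2 == 0:
                    continue  # product == precursor is rejected above anyway
                labels = tuple(sorted(e.label for e in combo))
                key = (n_steps, abs(h2), labels)
                if best is None or key < best[0]:
                    best = (key, labels, h2)
            if best is not None:
                break  # minimal step count found
        if best is None:
            annotations.append(
                FragmentAnnotation(prec, p, (), 0, explained=False)
            )
        else:
            _, labels, h2 = best
            annotations.append(
                FragmentAnnotation(prec, p, labels, h2, explained=True)
            )
    return annotations


def annotate_chain(
    mzs: Iterable[float],
    library: LossLibrary | None = None,
    max_steps: int = 3,
    max_h2: int = 3,
) -> list[FragmentAnnotation]:
    """Annotate a sequential fragmentation path: each m/z is explained as a
    loss from the previous one (precursor first)."""
    seq = [float(m) for m in mzs]
    if len(seq) < 2:
        raise ChemError("a chain needs a precursor and at least one product")
    out = []
    for parent, child in zip(seq, seq[1:]):
        out.extend(annotate_products(parent, [child], library, max_steps, max_h2))
    return out


def cu_fragment_mz(
    amino_acid: str,
    polarity: str = "+",
    aa_table: Mapping[str, AminoAcid] | None = None,
) -> int:
    """Nominal m/z of the single-amino-acid copper fragment: free amino acid
    + Cu − 2H, then ±H for the charge (e.g. Phe → 227 positive, 225
    negative)."""
    ion = chem_core.complex_formula(
        [amino_acid], 0, 0, metal="Cu", polarity=polarity, aa_table=aa_table
    )
    return ion.nominal_mz


def flag_cu_products(
    products: Iterable[float],
    spectrum: PeakList,
    mz_tolerance: float = 0.5,
    **screen_kwargs,
) -> dict[float, bool]:
    """True for each product m/z at which the isotope screen confirms a
    copper doublet anchored within ``mz_tolerance``."""
    prods = [float(p) for p in products]
    if len(spectrum) == 0:
        return {p: False for p in prods}
    hits = find_doublets(spectrum, mz_tolerance=mz_tolerance, **screen_kwargs)
    anchors = [h.mz_A for h in hits]
    return {
        p: any(abs(p - a) <= mz_tolerance for a in anchors) for p in prods
    }


def formula_matches_mz(formula: str | MolecularFormula, mz: float) -> bool:
    """Match a small neutral fragment formula against an observed nominal
    m/z, accepting the neutral mass ± 1 H (printed small-fragment formulas
    are often quoted as the neutral of a protonated ion)."""
    f = (MolecularFormula.from_string(formula)
         if isinstance(formula, str) else formula)
    return abs(f.nominal_mass() - round(float(mz))) <= 1


def write_annotations_tsv(annotations: list[FragmentAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "parent_mz": a.parent_mz,
                "product_mz": a.product_mz,
                "losses": ";".join(a.losses),
                "h2_adjustments": a.n_h2_adjustments,
                "explained": a.explained,
                "cu_retained": a.cu_retained,
            }
            for a in annotations
        ],
        columns=["parent_mz", "product_mz", "losses", "h2_adjustments",
                 "explained", "cu_retained"],
    ).to_csv(path, sep="\t", index=False)
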