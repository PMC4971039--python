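"""Enumeration and ranking of Cu(II)–amino-acid complex compositions that
match an observed quasi-molecular ion m/z.

The search space is every multiset of up to ``max_ligands`` proteinogenic
amino acids, combined with 0..(n−1) peptide bonds (each condensing out one
H2O), 0..``allow_water_adducts`` whole-H2O adducts, one copper displacing two
protons, and the polarity's protonation.  All compositions within the mass
tolerance are returned; ambiguity is surfaced, not resolved — fragmentation
evidence is the tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping

import pandas as pd

from . import chem_core
from .chem_core import AMINO_ACIDS, AminoAcid, ChemError

__all__ = [
    "AssignmentQuery",
    "ComplexCandidate",
    "AssignmentResult",
    "enumerate_candidates",
    "verify_assignment",
    "write_candidates_tsv",
]


@dataclass(frozen=True)
class AssignmentQuery:
    """Parameters of one composition search.

    tolerance defaults: 0.5 Da in nominal mode (unit-resolution quadrupole),
    0.01 Da in monoisotopic mode.
    """

    target_mz: float
    polarity: str = "+"
    mass_mode: str = "nominal"
    tolerance: float | None = None
    max_ligands: int = 4
    allow_water_adducts: int = 2
    candidate_cap: int = 10000

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ChemError(f"polarity must be '+' or '-': {self.polarity!r}")
        if self.mass_mode not in ("nominal", "monoisotopic"):
            raise ChemError(f"unknown mass_mode: {self.mass_mode!r}")
        if not (1 <= self.max_ligands <= 5):
            raise ChemError("max_ligands must be between 1 and 5")
        if not (0 <= self.allow_water_adducts <= 2):
            raise ChemError("allow_water_adducts must be between 0 and 2")
        if not (50.0 <= self.target_mz <= 1000.0):
            raise ChemError(
                f"target m/z {self.target_mz} outside scan range 50-1000"
            )
        if self.tolerance is None:
            object.__setattr__(
                self,
                "tolerance",
                0.5 if self.mass_mode == "nominal" else 0.01,
            )
        if self.tolerance <= 0:
            raise ChemError("tolerance must be positive")


@dataclass(frozen=True)
class ComplexCandidate:
    """One proposed composition; ``mass_error = computed_mz − target_mz``."""

    ligands: tuple[str, ...]  # sorted multiset
    n_peptide_bonds: int
    n_water_adducts: int
    computed_mz: float
    mass_error: float

    @property
    def rank_key(self):
        # fewest-modification parsimony after mass error
        return (
            abs(self.mass_error),
            self.n_peptide_bonds + self.n_water_adducts,
            self.ligands,
        )


class AssignmentResult(list):
    """Ranked candidate list; ``truncated`` is set when the candidate cap was
    hit (tolerance too generous)."""

    def __init__(self, candidates, truncated: bool = False):
        super().__init__(candidates)
        self.truncated = truncated


def _mass_terms(mass_mode: str, elements=None):
    table = chem_core.DEFAULT_ELEMENTS if elements is None else elements
    if mass_mode == "nominal":
        water = 18.0
        h = 1.0
        cu = float(table["Cu"].nominal_mass)
    else:
        water = chem_core.WATER.monoisotopic_mass(table)
        h = table["H"].monoisotopic_mass
        cu = table["Cu"].monoisotopic_mass
    return water, h, cu


def enumerate_candidates(
    query: AssignmentQuery,
    aa_table: Mapping[str, AminoAcid] | None = None,
    elements=None,
) -> AssignmentResult:
    """Exhaustively enumerate compositions matching ``query.target_mz``.

    Returns candidates sorted by (|mass error|, modification count,
    lexicographic ligand multiset); deterministic for fixed inputs.
    """
    table = AMINO_ACIDS if aa_table is None else aa_table
    water, h, cu = _mass_terms(query.mass_mode, elements)
    charge_term = h if query.polarity == "+" else -h

    codes = sorted(table)
    masses = {
        code: (
            float(table[code].free_nominal(elements))
            if query.mass_mode == "nominal"
            else table[code].free_formula.monoisotopic_mass(elements)
        )
        for code in codes
    }

    out: list[ComplexCandidate] = []
    for n_lig in range(1, query.max_ligands + 1):
        for combo in combinations_with_replacement(codes, n_lig):
            base = sum(masses[c] for c in combo) + cu - 2.0 * h + charge_term
            for bonds in range(0, n_lig):
                for waters in range(0, query.allow_water_adducts + 1):
                    mz = base + (waters - bonds) * water
                    err = mz - query.target_mz
                    if abs(err) <= query.tolerance:
                        out.append(
                            ComplexCandidate(combo, bonds, waters, mz, err)
                        )
    out.sort(key=lambda c: c.rank_key)
    truncated = len(out) > query.candidate_cap
    return AssignmentResult(out[: query.candidate_cap], truncated)


def verify_assignment(
    candidate: ComplexCandidate,
    target_mz: float,
    polarity: str = "+",
    mass_mode: str = "nominal",
    aa_table: Mapping[str, AminoAcid] | None = None,
) -> float:
    """Recompute the candidate's m/z from first principles via
    :func:`cuspec.chem_core.complex_formula` and return the signed error
    against ``target_mz``.  Must equal ``candidate.mass_error``."""
    ion = chem_core.complex_formula(
        candidate.ligands,
        candidate.n_peptide_bonds,
        candidate.n_water_adducts,
        metal="Cu",
        polarity=polarity,
        aa_table=aa_table,
    )
    mz = ion.nominal_mz if mass_mode == "nominal" else ion.monoisotopic_mz
    return float(mz) - float(target_mz)


def write_candidates_tsv(result: AssignmentResult, path) -> None:
    rows = [
        {
            "rank": i + 1,
            "ligands": "+".join(c.ligands),
            "bonds": c.n_peptide_bonds,
            "waters": c.n_water_adducts,
            "computed_mz": c.computed_mz,
            "error": c.mass_error,
            "truncated": result.truncated,
        }
        for i, c in enumerate(result)
    ]
    pd.DataFrame(
        rows,
        columns=["rank", "ligands", "bonds", "waters", "computed_mz", "error",
                 "truncated"],
    ).to_csv(path, sep="\t", index=False)
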