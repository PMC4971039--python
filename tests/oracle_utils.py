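"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the isotope oracle
enumerates isotopologues by multinomial closed form instead of sequential
convolution, and the composition oracle is a plain nested-loop search that
builds every candidate through cuspec.chem_core.complex_formula one at a
time.
"""

from collections import defaultdict
from itertools import combinations_with_replacement
from math import factorial

from cuspec.chem_core import AMINO_ACIDS, DEFAULT_ELEMENTS, complex_formula


def multinomial(ns) -> int:
    out = factorial(sum(ns))
    for n in ns:
        out //= factorial(n)
    return out


def brute_isotope_bins(counts: dict) -> dict:
    """Unit-mass isotopologue distribution by explicit multinomial
    enumeration: {integer mass: probability}."""
    dist = defaultdict(float)
    dist[0] = 1.0
    for sym, cnt in counts.items():
        isos = DEFAULT_ELEMENTS[sym].isotopes
        elem = defaultdict(float)
        for assign in combinations_with_replacement(range(len(isos)), cnt):
            ns = [assign.count(i) for i in range(len(isos))]
            p = float(multinomial(ns))
            m = 0
            for i, n in enumerate(ns):
                p *= isos[i].abundance ** n
                m += n * round(isos[i].mass)
            elem[m] += p
        new = defaultdict(float)
        for b, pb in dist.items():
            for m, pm in elem.items():
                new[b + m] += pb * pm
        dist = new
    return dict(dist)


def brute_candidates(target_mz, polarity, tolerance, max_ligands,
                     allow_water_adducts):
    """Nested-loop composition search (nominal mode): returns the set of
    (ligand multiset, bonds, waters) within tolerance of target_mz."""
    codes = sorted(AMINO_ACIDS)
    found = set()
    for n in range(1, max_ligands + 1):
        for combo in combinations_with_replacement(codes, n):
            for bonds in range(0, n):
                for waters in range(0, allow_water_adducts + 1):
                    ion = complex_formula(combo, bonds, waters, "Cu", polarity)
                    if abs(ion.nominal_mz - target_mz) <= tolerance:
                        found.add((combo, bonds, waters))
    return found
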