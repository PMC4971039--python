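#!/usr/bin/env python
"""Annotate the reported CID fragmentation chains as neutral-loss paths.

Each precursor is interpreted with a loss library restricted to its proposed
ligands (plus the generic small losses).  Reproduces every printed chain,
including the single-amino-acid copper fragments Phe=Cu at 227 (+) and
225 (−).  Writes results/fragmentation_paths.tsv.
"""

from pathlib import Path

from cuspec.fragment_annotate import (
    LossLibrary,
    annotate_chain,
    cu_fragment_mz,
    write_annotations_tsv,
)

ROOT = Path(__file__).resolve().parent.parent / "results"

CHAINS = [
    ("Phe-Cu-Asp", ["Phe", "Asp"], [360, 247]),
    ("Gly-Cu-Phe", ["Gly", "Phe"], [302, 227, 199]),
    ("His-Asp=Cu", ["His", "Asp"], [330, 185]),
    ("Tyr-Cu-Ser-Thr+2H2O", ["Tyr", "Ser", "Thr"], [483, 447, 390, 273]),
    ("Val-Cu-Phe-Ala", ["Val", "Phe", "Ala"], [429, 385, 298]),
]


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    all_annotations = []
    for name, ligands, chain in CHAINS:
        lib = LossLibrary.for_ligands(ligands)
        anns = annotate_chain(chain, lib)
        all_annotations.extend(anns)
        print(f"{name}:")
        for a in anns:
            print(f"  {a.describe()}")
    print("single-amino-acid Cu fragments: "
          f"Phe(+) -> {cu_fragment_mz('Phe', '+')}, "
          f"Phe(-) -> {cu_fragment_mz('Phe', '-')}, "
          f"His(-) -> {cu_fragment_mz('His', '-')}")
    write_annotations_tsv(all_annotations, ROOT / "fragmentation_paths.tsv")


if __name__ == "__main__":
    main()
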