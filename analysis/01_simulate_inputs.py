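#!/usr/bin/env python
"""Generate the full synthetic input bundle with ground-truth manifests.

Writes to results/inputs/: a negative-mode spectrum containing the five
reported Cu–amino-acid complexes over 10x chemical noise, the four-peak
SDS-like SEC-ICP-MS chromatogram, the five-standard calibration set on the
synthetic log-linear elution law, and a 3-replicate digestion/extraction
concentration table drawn with the reported means and SDs.
"""

from pathlib import Path

import pandas as pd

from cuspec import isotope_screen as isc
from cuspec import synthetic_data as syn

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spectrum, manifest = syn.gen_spectrum(
        syn.SpectrumRecipe(seed=SEED, noise_peaks=50)
    )
    isc.write_tsv(spectrum, OUT / "spectrum.tsv")
    syn.save_manifest(manifest, OUT / "spectrum_manifest.json")
    print(f"spectrum: {len(spectrum)} peaks, "
          f"{len(manifest['complexes'])} planted complexes at "
          f"{[c['mz'] for c in manifest['complexes']]}")

    chrom, cman = syn.gen_chromatogram(syn.ChromatogramRecipe(seed=5))
    chrom.to_csv(OUT / "chromatogram.csv", index=False)
    syn.save_manifest(cman, OUT / "chromatogram_manifest.json")
    print(f"chromatogram: {len(chrom)} samples, peaks planted at "
          f"{[p['rt_min'] for p in cman['peaks']]} min")

    stds, sman = syn.gen_sec_standards()
    pd.DataFrame(
        [{"name": s.name, "mw_kda": s.molecular_weight,
          "rt_min": round(s.retention_time, 4)} for s in stds]
    ).to_csv(OUT / "sec_standards.csv", index=False)
    syn.save_manifest(sman, OUT / "sec_standards_manifest.json")
    print("standards:", ", ".join(
        f"{s.name} {s.molecular_weight} kDa @ {s.retention_time:.2f} min"
        for s in stds))

    table, dman = syn.gen_digestion_table(seed=SEED)
    table.to_csv(OUT / "digestion.csv", index=False)
    syn.save_manifest(dman, OUT / "digestion_manifest.json")
    print(f"digestion table: {len(table)} replicate rows, "
          f"{len(dman['true_percents'])} fractions")


if __name__ == "__main__":
    main()
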