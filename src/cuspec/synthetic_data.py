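"""Seeded generators for every input the pipeline consumes, with ground
truth manifests.

The generators emulate the study conditions end to end:

* ESI-MS spectra containing singly charged one-copper amino-acid complexes
  (full theoretical isotope patterns on the unit-mass grid) over uniform
  chemical noise in the 50–1000 m/z scan window;
* SEC-ICP-MS chromatograms as sums of Gaussian peaks over a constant
  baseline with white noise — by default the four-peak profile of an SDS
  extract (void-volume aggregate ~11 min, ~150 kDa shoulder ~16 min, the
  main ~17 kDa peak at 26.5 min, and a sub-1.4 kDa peak at 34 min);
* the five-standard SEC calibration set drawn from a known log-linear law
  anchored at (17 kDa, 26.5 min) and (1.35 kDa, 34 min);
* replicate copper-concentration tables for the digestion/extraction
  fractions with the study's means and SDs (total copper 23.9 ± 2.6 µg/g;
  fraction percentages 48.0 ± 0.5, 47.1 ± 0.3, 88.2 ± 0.8, 81.2 ± 1.3,
  103.7 ± 2.6).

Every generator is a pure function of its recipe and seed, and every
manifest is machine-readable so tests never reach into generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_core import complex_formula, isotope_pattern
from .isotope_screen import PeakList, DEFAULT_SCAN_RANGE

__all__ = [
    "PlantedComplex",
    "SpectrumRecipe",
    "ChromatogramRecipe",
    "TABLE2_COMPLEXES",
    "FRACTION_PERCENTS",
    "TOTAL_CU_UG_G",
    "DEFAULT_SEC_LAW",
    "SEC_STANDARD_MWS",
    "gen_spectrum",
    "gen_chromatogram",
    "gen_sec_standards",
    "gen_digestion_table",
    "digestion_concentration_params",
]


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedComplex:
    ligands: tuple[str, ...]
    n_peptide_bonds: int = 0
    n_water_adducts: int = 0
    base_intensity: float = 1000.0


#: The five reported Cu complexes (as compositions that mass-balance under
#: the package's binding convention; negative mode).
TABLE2_COMPLEXES: tuple[PlantedComplex, ...] = (
    PlantedComplex(("Phe", "Asp"), 0, 0, 1000.0),
    PlantedComplex(("Gly", "Phe"), 0, 0, 900.0),
    PlantedComplex(("His", "Asp"), 1, 0, 800.0),
    PlantedComplex(("Tyr", "Ser", "Thr"), 1, 2, 700.0),
    PlantedComplex(("Val", "Phe", "Ala"), 0, 0, 600.0),
)


@dataclass(frozen=True)
class SpectrumRecipe:
    complexes: tuple[PlantedComplex, ...] = TABLE2_COMPLEXES
    polarity: str = "-"
    noise_peaks: int = 0
    noise_intensity_range: tuple[float, float] = (1.0, 50.0)
    mz_jitter: float = 0.0
    min_rel_intensity: float = 1.0
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE
    seed: int = 0


def gen_spectrum(recipe: SpectrumRecipe) -> tuple[PeakList, dict]:
    """Synthesise a centroided spectrum plus its ground-truth manifest.

    Each planted complex contributes its full theoretical isotope pattern
    (unit-mass bins) scaled to its base intensity.  Chemical noise peaks are
    uniform in m/z over the scan range with log-uniform intensities.
    Planted peaks landing in the same unit bin are merged and noted.
    """
    rng = np.random.default_rng(recipe.seed)
    peaks: dict[float, float] = {}
    manifest_complexes = []
    merged_bins: set[float] = set()
    for pc in recipe.complexes:
        ion = complex_formula(
            pc.ligands, pc.n_peptide_bonds, pc.n_water_adducts,
            metal="Cu", polarity=recipe.polarity,
        )
        pattern = isotope_pattern(ion.formula, recipe.min_rel_intensity)
        for mz, rel in pattern.peaks:
            pos = float(round(mz))  # unit-resolution centroid
            if recipe.mz_jitter > 0:
                pos += float(rng.normal(0.0, recipe.mz_jitter))
            inten = pc.base_intensity * rel / 100.0
            if pos in peaks:
                merged_bins.add(pos)
            peaks[pos] = peaks.get(pos, 0.0) + inten
        manifest_complexes.append(
            {
                "ligands": list(pc.ligands),
                "n_peptide_bonds": pc.n_peptide_bonds,
                "n_water_adducts": pc.n_water_adducts,
                "mz": ion.nominal_mz,
                "base_intensity": pc.base_intensity,
            }
        )
    lo, hi = recipe.scan_range
    for _ in range(recipe.noise_peaks):
        mz = float(rng.uniform(lo, hi))
        a, b = recipe.noise_intensity_range
        inten = float(np.exp(rng.uniform(np.log(a), np.log(b))))
        if mz in peaks:
            merged_bins.add(mz)
        peaks[mz] = peaks.get(mz, 0.0) + inten

    spectrum = PeakList.from_peaks(
        peaks.items(), polarity=recipe.polarity, scan_range=recipe.scan_range
    )
    manifest = {
        "kind": "spectrum",
        "seed": recipe.seed,
        "polarity": recipe.polarity,
        "complexes": manifest_complexes,
        "noise_peaks": recipe.noise_peaks,
        "merged_bins": sorted(merged_bins),
    }
    return spectrum, manifest


# ---------------------------------------------------------------------------
# Chromatograms and SEC standards
# ---------------------------------------------------------------------------

#: Fig. 1a-like SDS-extract profile: (retention time min, height, sigma min).
SDS_PROFILE: tuple[tuple[float, float, float], ...] = (
    (11.0, 3000.0, 0.40),
    (16.0, 1500.0, 0.35),
    (26.5, 10000.0, 0.50),
    (34.0, 6000.0, 0.45),
)

#: Fig. 1b-like enzymatic-digest profile.
ENZYMATIC_PROFILE: tuple[tuple[float, float, float], ...] = (
    (27.0, 8000.0, 0.50),
    (31.0, 5000.0, 0.45),
)


@dataclass(frozen=True)
class ChromatogramRecipe:
    peaks: tuple[tuple[float, float, float], ...] = SDS_PROFILE
    baseline: float = 100.0
    noise_sd: float = 10.0
    t_start: float = 5.0
    t_end: float = 40.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for _, _, w in self.peaks):
            raise ValueError("peak widths must be positive")


def gen_chromatogram(recipe: ChromatogramRecipe) -> tuple[pd.DataFrame, dict]:
    """Sum of Gaussians + constant baseline + seeded white noise on a
    uniform time grid; returns (time_min/intensity table, manifest)."""
    rng = np.random.default_rng(recipe.seed)
    n = int(round((recipe.t_end - recipe.t_start) / recipe.dt)) + 1
    t = recipe.t_start + recipe.dt * np.arange(n)
    y = np.full(n, recipe.baseline, float)
    for rt, h, w in recipe.peaks:
        y += h * np.exp(-0.5 * ((t - rt) / w) ** 2)
    if recipe.noise_sd > 0:
        y += rng.normal(0.0, recipe.noise_sd, n)
    y = np.maximum(y, 1e-9)
    df = pd.DataFrame({"time_min": t, "intensity": y})
    manifest = {
        "kind": "chromatogram",
        "seed": recipe.seed,
        "peaks": [
            {"rt_min": rt, "height": h, "sigma_min": w}
            for rt, h, w in recipe.peaks
        ],
        "baseline": recipe.baseline,
        "noise_sd": recipe.noise_sd,
    }
    return df, manifest


SEC_STANDARD_MWS: tuple[tuple[str, float], ...] = (
    ("thyroglobulin", 670.0),
    ("gamma-globulin", 158.0),
    ("ovalbumin", 44.0),
    ("myoglobin", 17.0),
    ("vitamin B12", 1.35),
)


def _sec_law() -> tuple[float, float]:
    # log10(MW) line through (26.5 min, 17 kDa) and (34.0 min, 1.35 kDa)
    t1, m1 = 26.5, 17.0
    t2, m2 = 34.0, 1.35
    slope = (np.log10(m2) - np.log10(m1)) / (t2 - t1)
    intercept = np.log10(m1) - slope * t1
    return float(slope), float(intercept)


#: (slope, intercept) of the synthetic log10(MW/kDa) vs t(min) elution law.
DEFAULT_SEC_LAW: tuple[float, float] = _sec_law()


def gen_sec_standards(
    law: tuple[float, float] = DEFAULT_SEC_LAW,
    mws=SEC_STANDARD_MWS,
    rt_jitter: float = 0.0,
    seed: int = 0,
):
    """Place the calibration standards on a log-linear elution law.

    With ``rt_jitter = 0`` (default) the standards are exactly collinear, so
    a calibration fit must recover the law with r² = 1.
    """
    from .sec_mw import SECStandard

    slope, intercept = law
    rng = np.random.default_rng(seed)
    out = []
    for name, mw in mws:
        t = (np.log10(mw) - intercept) / slope
        if rt_jitter > 0:
            t += float(rng.normal(0.0, rt_jitter))
        out.append(SECStandard(name, float(mw), float(t)))
    manifest = {
        "kind": "sec_standards",
        "slope": slope,
        "intercept": intercept,
        "rt_jitter": rt_jitter,
        "seed": seed,
        "standards": [
            {"name": s.name, "mw_kda": s.molecular_weight,
             "rt_min": s.retention_time}
            for s in out
        ],
    }
    return out, manifest


# ---------------------------------------------------------------------------
# Digestion / extraction concentration tables
# ---------------------------------------------------------------------------

#: Reported fraction percentages (mean, SD) of total copper.
FRACTION_PERCENTS: dict[str, tuple[float, float]] = {
    "ammonium_acetate": (48.0, 0.5),
    "tris_hcl": (47.1, 0.3),
    "sds": (88.2, 0.8),
    "gastric": (81.2, 1.3),
    "gastrointestinal": (103.7, 2.6),
}

#: Total copper content of the berry, µg per g dry mass (mean, SD).
TOTAL_CU_UG_G: tuple[float, float] = (23.9, 2.6)


def digestion_concentration_params(
    fraction_percents: dict[str, tuple[float, float]] | None = None,
    total: tuple[float, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-fraction concentration (mean, SD) in µg/g, including 'total'.

    Fraction percentages are converted to concentrations against the mean
    total content.
    """
    pcts = FRACTION_PERCENTS if fraction_percents is None else fraction_percents
    tot = TOTAL_CU_UG_G if total is None else total
    params = {
        label: (pct / 100.0 * tot[0], sd / 100.0 * tot[0])
        for label, (pct, sd) in pcts.items()
    }
    params["total"] = tot
    return params


def gen_digestion_table(
    means_sds: dict[str, tuple[float, float]] | None = None,
    n: int = 3,
    seed: int = 0,
    sample: str = "acai_berry",
) -> tuple[pd.DataFrame, dict]:
    """Replicate concentration table: ``n`` normal draws per fraction,
    truncated at zero.  Columns: sample, fraction, replicate, concentration.
    """
    params = (
        digestion_concentration_params() if means_sds is None else means_sds
    )
    if any(m <= 0 for m, _ in params.values()):
        raise ValueError("all generating means must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for label, (mean, sd) in params.items():
        draws = np.maximum(rng.normal(mean, sd, n), 0.0)
        for k, x in enumerate(draws):
            rows.append(
                {
                    "sample": sample,
                    "fraction": label,
                    "replicate": k + 1,
                    "concentration": float(x),
                }
            )
    df = pd.DataFrame(rows)
    manifest = {
        "kind": "digestion_table",
        "seed": seed,
        "n": n,
        "params": {k: list(v) for k, v in params.items()},
        "true_percents": {
            k: 100.0 * v[0] / params["total"][0]
            for k, v in params.items()
            if k != "total"
        },
    }
    return df, manifest


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
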