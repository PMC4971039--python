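"""End-to-end orchestration: simulate → screen → assign → annotate → SEC
calibration → bioaccessibility, with per-stage outputs and a consolidated
JSON summary.

Inputs may be supplied as files (TSV/MGF spectra, CSV chromatogram and
standards, CSV digestion replicates, JSON fragment lists); any input left
unset is generated by the seeded synthetic module, so a bare config runs the
whole chain self-contained.  A stage failure is logged and its dependent
stages are skipped; the run fails (non-zero status in the CLI) only on hard
errors such as missing input paths.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import bioaccess as ba
from . import complex_assign as ca
from . import fragment_annotate as fa
from . import isotope_screen as isc
from . import sec_mw
from . import synthetic_data as syn

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("cuspec.pipeline")


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    polarity: str = "-"
    mass_mode: str = "nominal"
    mz_tolerance: float = 0.5
    ratio_tolerance: float = 0.25
    score_threshold: float = 0.95
    max_ligands: int = 4
    allow_water_adducts: int = 2
    min_snr: float = 5.0
    noise_peaks: int = 50
    # optional input files; None -> synthesised from the seed
    spectrum_path: str | None = None
    fragments_path: str | None = None
    chromatogram_path: str | None = None
    standards_path: str | None = None
    digestion_path: str | None = None

    def validate_paths(self) -> None:
        for name in ("spectrum_path", "fragments_path", "chromatogram_path",
                     "standards_path", "digestion_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML; keys mirror the dataclass fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _dump_config(config: RunConfig, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def _synthetic_inputs(config: RunConfig, outdir: Path):
    """Generate every input not supplied by the config."""
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    if config.spectrum_path is None:
        recipe = syn.SpectrumRecipe(
            polarity=config.polarity,
            noise_peaks=config.noise_peaks,
            seed=config.seed,
        )
        spectrum, manifest = syn.gen_spectrum(recipe)
        isc.write_tsv(spectrum, inputs / "spectrum.tsv")
        syn.save_manifest(manifest, inputs / "spectrum_manifest.json")
        fragments = []
        for c in manifest["complexes"]:
            prec = c["mz"]
            prods = []
            if prec - 44 >= 50:
                prods.append(prec - 44)  # CO2 loss
            prods.append(fa.cu_fragment_mz(c["ligands"][0], config.polarity))
            fragments.append(
                {"precursor": prec, "products": prods, "ligands": c["ligands"]}
            )
        with open(inputs / "fragments.json", "w") as fh:
            json.dump(fragments, fh, indent=2)
        spectrum_path = inputs / "spectrum.tsv"
        fragments_path = inputs / "fragments.json"
    else:
        spectrum_path = Path(config.spectrum_path)
        fragments_path = (
            Path(config.fragments_path) if config.fragments_path else None
        )

    if config.chromatogram_path is None:
        chrom, cman = syn.gen_chromatogram(
            syn.ChromatogramRecipe(seed=config.seed)
        )
        chrom.to_csv(inputs / "chromatogram.csv", index=False)
        syn.save_manifest(cman, inputs / "chromatogram_manifest.json")
        chromatogram_path = inputs / "chromatogram.csv"
    else:
        chromatogram_path = Path(config.chromatogram_path)

    if config.standards_path is None:
        stds, sman = syn.gen_sec_standards(seed=config.seed)
        pd.DataFrame(
            [
                {"name": s.name, "mw_kda": s.molecular_weight,
                 "rt_min": s.retention_time}
                for s in stds
            ]
        ).to_csv(inputs / "sec_standards.csv", index=False)
        syn.save_manifest(sman, inputs / "sec_standards_manifest.json")
        standards_path = inputs / "sec_standards.csv"
    else:
        standards_path = Path(config.standards_path)

    if config.digestion_path is None:
        table, dman = syn.gen_digestion_table(seed=config.seed)
        table.to_csv(inputs / "digestion.csv", index=False)
        syn.save_manifest(dman, inputs / "digestion_manifest.json")
        digestion_path = inputs / "digestion.csv"
    else:
        digestion_path = Path(config.digestion_path)

    return spectrum_path, fragments_path, chromatogram_path, standards_path, \
        digestion_path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the summary dict (also written to
    ``<output_dir>/summary.json``)."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary: dict = {"seed": config.seed, "stages": {}, "failed_stages": []}
    _dump_config(config, outdir / "config.yaml")

    try:
        (spectrum_path, fragments_path, chromatogram_path, standards_path,
         digestion_path) = _synthetic_inputs(config, outdir)

        # --- screen -----------------------------------------------------
        hits = []
        try:
            if str(spectrum_path).endswith(".mgf"):
                spectra = isc.read_mgf(spectrum_path)
            else:
                spectra = [isc.read_tsv(spectrum_path,
                                        polarity=config.polarity)]
            for spectrum in spectra:
                hits.extend(
                    isc.find_doublets(
                        spectrum,
                        mz_tolerance=config.mz_tolerance,
                        ratio_tolerance=config.ratio_tolerance,
                        score_threshold=config.score_threshold,
                    )
                )
            isc.write_hits_tsv(hits, outdir / "doublet_hits.tsv")
            summary["stages"]["screen"] = {"n_ions": len(hits)}
            log.info("screen: %d candidate Cu ions", len(hits))
        except Exception as exc:  # pragma: no cover - defensive
            log.error("stage screen failed: %s", exc)
            summary["failed_stages"].append("screen")
            hits = None

        # --- assign -----------------------------------------------------
        ions = []
        if hits is not None:
            try:
                frames = []
                for h in hits:
                    query = ca.AssignmentQuery(
                        target_mz=h.mz_A,
                        polarity=config.polarity,
                        mass_mode=config.mass_mode,
                        max_ligands=config.max_ligands,
                        allow_water_adducts=config.allow_water_adducts,
                    )
                    result = ca.enumerate_candidates(query)
                    top = result[0] if result else None
                    ions.append(
                        {
                            "mz": h.mz_A,
                            "score": round(h.pattern_score, 6),
                            "top_composition": (
                                "+".join(top.ligands) if top else None
                            ),
                            "bonds": top.n_peptide_bonds if top else None,
                            "waters": top.n_water_adducts if top else None,
                            "mass_error": top.mass_error if top else None,
                        }
                    )
                    for rank, c in enumerate(result, 1):
                        frames.append(
                            {
                                "target_mz": h.mz_A,
                                "rank": rank,
                                "ligands": "+".join(c.ligands),
                                "bonds": c.n_peptide_bonds,
                                "waters": c.n_water_adducts,
                                "computed_mz": c.computed_mz,
                                "error": c.mass_error,
                            }
                        )
                pd.DataFrame(
                    frames,
                    columns=["target_mz", "rank", "ligands", "bonds",
                             "waters", "computed_mz", "error"],
                ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
                summary["stages"]["assign"] = {"ions": ions}
                log.info("assign: compositions for %d ions", len(ions))
            except Exception as exc:
                log.error("stage assign failed: %s", exc)
                summary["failed_stages"].append("assign")

        # --- annotate ---------------------------------------------------
        if fragments_path is not None:
            try:
                with open(fragments_path) as fh:
                    frag_specs = json.load(fh)
                annotations = []
                paths = []
                for spec_ in frag_specs:
                    lib = (
                        fa.LossLibrary.for_ligands(spec_["ligands"])
                        if spec_.get("ligands")
                        else None
                    )
                    anns = fa.annotate_products(
                        spec_["precursor"], spec_["products"], lib
                    )
                    annotations.extend(anns)
                    paths.append([a.describe() for a in anns])
                fa.write_annotations_tsv(annotations, outdir / "annotations.tsv")
                summary["stages"]["annotate"] = {
                    "n_products": len(annotations),
                    "n_explained": sum(a.explained for a in annotations),
                    "paths": paths,
                }
                log.info("annotate: %d/%d products explained",
                         sum(a.explained for a in annotations),
                         len(annotations))
            except Exception as exc:
                log.error("stage annotate failed: %s", exc)
                summary["failed_stages"].append("annotate")

        # --- SEC calibration + peaks -------------------------------------
        try:
            standards = sec_mw.read_standards_csv(standards_path)
            model = sec_mw.fit_calibration(standards)
            t, y = sec_mw.read_chromatogram_csv(chromatogram_path)
            peaks = sec_mw.detect_peaks(t, y, min_snr=config.min_snr)
            peaks = [
                dataclasses.replace(p, assigned_mw=sec_mw.assign_mw(
                    model, p.retention_time))
                for p in peaks
            ]
            sec_mw.write_peaks_tsv(peaks, outdir / "sec_peaks.tsv")
            summary["stages"]["sec"] = {
                "slope": model.slope,
                "intercept": model.intercept,
                "r_squared": model.r_squared,
                "peaks": [
                    {
                        "rt_min": p.retention_time,
                        "mw_kda": p.assigned_mw.mw_kda,
                        "extrapolated": p.assigned_mw.extrapolated,
                    }
                    for p in peaks
                ],
            }
            log.info("sec: %d peaks, r^2=%.6f", len(peaks), model.r_squared)
        except Exception as exc:
            log.error("stage sec failed: %s", exc)
            summary["failed_stages"].append("sec")

        # --- bioaccessibility --------------------------------------------
        try:
            table = pd.read_csv(digestion_path)
            measurements = ba.summarize_replicates(table)
            result = ba.bioaccessibility_table(measurements)
            result.to_csv(outdir / "bioaccess.tsv", sep="\t", index=False)
            summary["stages"]["bioaccess"] = {
                row["fraction"]: {
                    "percent": row["percent"],
                    "sd_percent": row["sd_percent"],
                    "flag_over_100": bool(row["flag_over_100"]),
                }
                for _, row in result.iterrows()
            }
            log.info("bioaccess: %d fractions", len(result))
        except Exception as exc:
            log.error("stage bioaccess failed: %s", exc)
            summary["failed_stages"].append("bioaccess")

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
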