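"""Bioaccessibility and extraction-efficiency percentages with first-order
uncertainty propagation.

Bioaccessibility of an element is the fraction of its total content that is
solubilised by simulated digestion and hence available for absorption::

    %bioaccessibility = [digest] / [total] * 100

where [digest] is the element concentration in the gastric or
gastrointestinal supernatant and [total] the concentration in the
mineralised sample, both in µg per g dry mass.  Extraction efficiency is the
same ratio for a buffer extract.  The standard deviation is propagated to
first order for a ratio of independent measurements::

    sd% = percent * sqrt((sd_f/f)^2 + (sd_t/t)^2)

Values above 100 % are legal (measurement error can exceed the total) and
are returned flagged, never clipped — a digest percentage of ≈100 reads as
complete bioaccessibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FractionMeasurement",
    "BioaccessResult",
    "percent_bioaccessibility",
    "extraction_efficiency",
    "summarize_replicates",
    "bioaccessibility_table",
]


@dataclass(frozen=True)
class FractionMeasurement:
    """Element concentration of one fraction, µg per g dry mass."""

    label: str
    concentration: float
    sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.label}: concentration must be >= 0")
        if self.sd < 0:
            raise ValueError(f"{self.label}: sd must be >= 0")


@dataclass(frozen=True)
class BioaccessResult:
    label: str
    percent: float
    sd_percent: float
    flag_over_100: bool


def _ratio_percent(
    fraction: FractionMeasurement, total: FractionMeasurement
) -> BioaccessResult:
    if total.concentration <= 0:
        raise ValueError("total concentration must be positive")
    pct = 100.0 * fraction.concentration / total.concentration
    if fraction.concentration > 0:
        rel = math.sqrt(
            (fraction.sd / fraction.concentration) ** 2
            + (total.sd / total.concentration) ** 2
        )
        sd_pct = pct * rel
    else:
        sd_pct = 0.0
    return BioaccessResult(fraction.label, pct, sd_pct, pct > 100.0)


def percent_bioaccessibility(
    fraction: FractionMeasurement, total: FractionMeasurement
) -> BioaccessResult:
    """Digest copper over total copper, as a percentage with propagated SD."""
    return _ratio_percent(fraction, total)


def extraction_efficiency(
    extract: FractionMeasurement, total: FractionMeasurement
) -> BioaccessResult:
    """Buffer-extract copper over total copper; identical contract to
    :func:`percent_bioaccessibility`."""
    return _ratio_percent(extract, total)


def summarize_replicates(df: pd.DataFrame) -> list[FractionMeasurement]:
    """Collapse a long replicate table (columns: fraction, concentration)
    into per-fraction mean/SD measurements."""
    out = []
    for label, grp in df.groupby("fraction", sort=False):
        x = grp["concentration"].to_numpy(float)
        out.append(
            FractionMeasurement(
                label=str(label),
                concentration=float(x.mean()),
                sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
                n_replicates=int(x.size),
            )
        )
    return out


def bioaccessibility_table(
    measurements, total_label: str = "total"
) -> pd.DataFrame:
    """Percentages for every fraction against the total row.

    Input: iterable of FractionMeasurement including one with
    ``total_label``.  Output columns: fraction, percent, sd_percent,
    flag_over_100.
    """
    ms = list(measurements)
    totals = [m for m in ms if m.label == total_label]
    if len(totals) != 1:
        raise ValueError(f"expected exactly one {total_label!r} measurement")
    total = totals[0]
    rows = []
    for m in ms:
        if m.label == total_label:
            continue
        r = _ratio_percent(m, total)
        rows.append(
            {
                "fraction": r.label,
                "percent": r.percent,
                "sd_percent": r.sd_percent,
                "flag_over_100": r.flag_over_100,
            }
        )
    return pd.DataFrame(rows, columns=["fraction", "percent", "sd_percent",
                                       "flag_over_100"])
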