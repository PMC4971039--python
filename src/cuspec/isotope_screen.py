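"""Screening of centroided spectra for the 63Cu/65Cu isotopic doublet.

A singly charged one-copper ion shows an A/A+2 peak pair with intensity
ratio 31/69 = 0.449 (65Cu/63Cu).  The screen walks the spectrum greedily by
descending intensity, anchors a candidate doublet at each unconsumed peak,
checks the 2-Da spacing and the ratio window, and scores the local peak
cluster against the theoretical copper doublet by unit-mass-aligned cosine
similarity.  Peaks inside an accepted doublet footprint (the A+1 and A+2
isotopologues) are consumed as future anchors, so one copper species yields
one hit.

The screen is a pre-filter: it reports candidates and does not attempt to
suppress chance doublets in noise — composition assignment and fragmentation
evidence downstream are the arbiters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem_core import IsotopePattern

__all__ = [
    "PeakList",
    "DoubletHit",
    "CU_DOUBLET_RATIO",
    "find_doublets",
    "score_pattern",
    "read_tsv",
    "write_tsv",
    "read_mgf",
    "write_hits_tsv",
]

#: 65Cu/63Cu abundance ratio, the doublet signature (31/69).
CU_DOUBLET_RATIO = 31.0 / 69.0

DEFAULT_SCAN_RANGE = (50.0, 1000.0)


@dataclass(frozen=True, eq=False)
class PeakList:
    """A centroided spectrum: strictly increasing m/z, positive intensities,
    all peaks inside the scan range."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "+"
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("peak m/z values must be strictly increasing")
        if np.any(inten <= 0):
            raise ValueError("peak intensities must be positive")
        lo, hi = self.scan_range
        if mz.size and (mz[0] < lo or mz[-1] > hi):
            raise ValueError(
                f"peaks outside scan range [{lo}, {hi}]: "
                f"[{mz[0]}, {mz[-1]}]"
            )
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_peaks(
        cls,
        peaks,
        polarity: str = "+",
        scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
        merge_within: float = 1e-9,
    ) -> "PeakList":
        """Build from (m/z, intensity) pairs; sorts, and merges peaks closer
        than ``merge_within`` by intensity sum."""
        pk = sorted((float(m), float(i)) for m, i in peaks)
        merged: list[list[float]] = []
        for m, i in pk:
            if merged and m - merged[-1][0] <= merge_within:
                merged[-1][1] += i
            else:
                merged.append([m, i])
        mz = np.array([m for m, _ in merged])
        inten = np.array([i for _, i in merged])
        return cls(mz, inten, polarity, scan_range)

    def segment(self, lo: float, hi: float) -> "PeakList":
        """Sub-spectrum with m/z in [lo, hi] (may be empty is not allowed:
        caller must ensure at least one peak)."""
        sel = (self.mz >= lo) & (self.mz <= hi)
        return PeakList(self.mz[sel], self.intensity[sel], self.polarity,
                        self.scan_range)


@dataclass(frozen=True)
class DoubletHit:
    mz_A: float
    mz_A2: float
    intensity_A: float
    intensity_A2: float
    ratio: float  # intensity(A+2) / intensity(A)
    pattern_score: float  # cosine vs theoretical Cu doublet, in [0, 1]


def _bin_intensities(mzs, intensities) -> dict[int, float]:
    out: dict[int, float] = {}
    for m, i in zip(mzs, intensities):
        k = round(float(m))
        out[k] = out.get(k, 0.0) + float(i)
    return out


def score_pattern(observed: PeakList, theoretical: IsotopePattern) -> float:
    """Cosine similarity between observed and theoretical intensities after
    alignment on the unit-mass grid.

    1.0 for proportional patterns, 0.0 when no unit-mass bin is shared.
    """
    if len(observed) == 0:
        raise ValueError("observed segment is empty")
    obs = _bin_intensities(observed.mz, observed.intensity)
    theo = theoretical.binned()
    keys = sorted(set(obs) | set(theo))
    a = np.array([obs.get(k, 0.0) for k in keys])
    b = np.array([theo.get(k, 0.0) for k in keys])
    dot = float(a @ b)
    if dot == 0.0:
        return 0.0
    return dot / (float(np.linalg.norm(a)) * float(np.linalg.norm(b)))


def find_doublets(
    spectrum: PeakList,
    mz_tolerance: float = 0.5,
    ratio_center: float = CU_DOUBLET_RATIO,
    ratio_tolerance: float = 0.25,
    delta: float = 2.0,
    score_threshold: float = 0.95,
) -> list[DoubletHit]:
    """Find candidate one-copper ions by their A/A+2 doublet.

    Parameters
    ----------
    mz_tolerance : allowed deviation of the partner peak from ``mz_A + delta``.
    ratio_center, ratio_tolerance : accepted A+2/A ratio window,
        ``ratio_center * (1 ± ratio_tolerance)``.
    delta : doublet spacing; 2 for nominal (unit-resolution) data,
        1.9982 (65Cu − 63Cu) for exact-mass data.
    score_threshold : minimum cosine of the local cluster against the
        theoretical copper doublet.

    Anchors are tried greedily by descending intensity (ties: ascending m/z);
    a peak participates in at most one hit as A, and the peaks inside an
    accepted doublet footprint (mz_A, mz_A2] cannot anchor later hits.
    Hits are returned sorted by descending score, then ascending mz_A.
    """
    if mz_tolerance <= 0 or ratio_tolerance <= 0:
        raise ValueError("tolerances must be positive")
    n = len(spectrum)
    if n == 0:
        return []
    mz, inten = spectrum.mz, spectrum.intensity
    order = np.lexsort((mz, -inten))
    lo_ratio = ratio_center * (1.0 - ratio_tolerance)
    hi_ratio = ratio_center * (1.0 + ratio_tolerance)

    consumed = np.zeros(n, dtype=bool)
    hits: list[DoubletHit] = []
    for i in order:
        if consumed[i]:
            continue
        target = mz[i] + delta
        j_lo = np.searchsorted(mz, target - mz_tolerance, side="left")
        j_hi = np.searchsorted(mz, target + mz_tolerance, side="right")
        if j_hi <= j_lo:
            continue
        cands = [j for j in range(j_lo, j_hi) if j != i]
        if not cands:
            continue
        j = min(cands, key=lambda k: abs(mz[k] - target))
        ratio = float(inten[j] / inten[i])
        if not (lo_ratio <= ratio <= hi_ratio):
            continue
        seg = spectrum.segment(mz[i] - 0.5, mz[j] + 0.5)
        theo = IsotopePattern(
            ((float(mz[i]), 100.0), (float(mz[i]) + delta, 100.0 * ratio_center))
        )
        score = score_pattern(seg, theo)
        if score < score_threshold:
            continue
        hits.append(
            DoubletHit(
                mz_A=float(mz[i]),
                mz_A2=float(mz[j]),
                intensity_A=float(inten[i]),
                intensity_A2=float(inten[j]),
                ratio=ratio,
                pattern_score=score,
            )
        )
        consumed[i] = True
        footprint = (mz > mz[i]) & (mz <= mz[j] + mz_tolerance)
        consumed |= footprint
    hits.sort(key=lambda h: (-h.pattern_score, h.mz_A))
    return hits


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_scan_range(mz: np.ndarray) -> tuple[float, float]:
    lo, hi = DEFAULT_SCAN_RANGE
    if mz.size:
        lo = min(lo, math.floor(mz.min()))
        hi = max(hi, math.ceil(mz.max()))
    return (float(lo), float(hi))


def read_tsv(path, polarity: str = "+", scan_range=None) -> PeakList:
    """Read a two-column (mz, intensity) TSV peak list."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "mz" in cols and "intensity" in cols:
        mz = df[df.columns[cols.index("mz")]].to_numpy(float)
        inten = df[df.columns[cols.index("intensity")]].to_numpy(float)
    else:  # headerless two-column file
        df = pd.read_csv(path, sep="\t", header=None)
        mz = df[0].to_numpy(float)
        inten = df[1].to_numpy(float)
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    if scan_range is None:
        scan_range = _infer_scan_range(mz)
    return PeakList(mz, inten, polarity, scan_range)


def write_tsv(spectrum: PeakList, path) -> None:
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, sep="\t", index=False
    )


def read_mgf(path) -> list[PeakList]:
    """Read an MGF file into a list of peak lists (one per BEGIN/END IONS
    block).  CHARGE polarity is honoured when present; default positive."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            mz = np.asarray(spec["m/z array"], float)
            inten = np.asarray(spec["intensity array"], float)
            order = np.argsort(mz)
            mz, inten = mz[order], inten[order]
            polarity = "+"
            charges = spec["params"].get("charge")
            if charges:
                polarity = "-" if int(charges[0]) < 0 else "+"
            spectra.append(
                PeakList(mz, inten, polarity, _infer_scan_range(mz))
            )
    return spectra


def write_hits_tsv(hits: list[DoubletHit], path) -> None:
    pd.DataFrame(
        [
            {
                "mz_A": h.mz_A,
                "mz_A2": h.mz_A2,
                "ratio": h.ratio,
                "score": h.pattern_score,
            }
            for h in hits
        ],
        columns=["mz_A", "mz_A2", "ratio", "score"],
    ).to_csv(path, sep="\t", index=False)
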