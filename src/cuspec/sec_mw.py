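"""SEC-ICP-MS chromatogram peaks and log-linear molecular-weight calibration.

A size-exclusion column separates by hydrodynamic size; within its
fractionation range, log10(MW) falls linearly with retention time.  The
calibration is a least-squares line through protein standards (here the
classic five-standard mixture: thyroglobulin 670 kDa, γ-globulin 158 kDa,
ovalbumin 44 kDa, myoglobin 17 kDa, vitamin B12 1.35 kDa).  Predictions
outside the standards' retention-time span are flagged as extrapolated: a
peak before the largest standard sits in the void volume (MW above the
fractionation limit), a peak after the smallest standard is below the
smallest calibrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "SECStandard",
    "CalibrationModel",
    "MWAssignment",
    "ChromPeak",
    "fit_calibration",
    "assign_mw",
    "detect_peaks",
    "read_standards_csv",
    "read_chromatogram_csv",
    "write_peaks_tsv",
]


@dataclass(frozen=True)
class SECStandard:
    name: str
    molecular_weight: float  # kDa
    retention_time: float  # min

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"standard {self.name}: MW must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """log10(MW/kDa) = intercept + slope · t(min); slope < 0 by SEC physics."""

    slope: float
    intercept: float
    valid_range: tuple[float, float]  # (t of largest standard, t of smallest)
    r_squared: float
    standards: tuple[SECStandard, ...]


@dataclass(frozen=True)
class MWAssignment:
    mw_kda: float
    extrapolated: bool
    #: MW interval bracketed by the neighbouring standards (low, high), kDa;
    #: open-ended (void / below smallest calibrant) uses inf / 0.
    region: tuple[float, float]


@dataclass(frozen=True)
class ChromPeak:
    retention_time: float  # min
    height: float  # above baseline
    area: float  # baseline-subtracted, trapezoidal
    assigned_mw: MWAssignment | None = None


def fit_calibration(standards) -> CalibrationModel:
    """Least-squares log-linear calibration through the standards.

    Requires at least two standards with distinct retention times and a
    negative fitted slope (retention time must increase as MW decreases).
    Collinear standards are reproduced exactly (up to float precision).
    """
    stds = tuple(standards)
    if len(stds) < 2:
        raise ValueError("at least 2 standards are required")
    t = np.array([s.retention_time for s in stds], float)
    if len(np.unique(t)) != len(t):
        raise ValueError("standards have duplicated retention times")
    logmw = np.log10([s.molecular_weight for s in stds])
    fit = stats.linregress(t, logmw)
    if fit.slope >= 0:
        raise ValueError(
            "fitted slope is non-negative: MW must decrease with retention time"
        )
    order = np.argsort(t)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        valid_range=(float(t.min()), float(t.max())),
        r_squared=float(fit.rvalue**2),
        standards=tuple(stds[i] for i in order),
    )


def assign_mw(model: CalibrationModel, retention_time: float) -> MWAssignment:
    """Molecular weight at a retention time: 10^(intercept + slope·t), with
    an extrapolation flag outside the calibrated span and the MW interval
    bracketed by the neighbouring standards."""
    t = float(retention_time)
    mw = 10.0 ** (model.intercept + model.slope * t)
    lo_t, hi_t = model.valid_range
    extrapolated = not (lo_t <= t <= hi_t)
    stds = model.standards  # sorted by retention time (descending MW)
    if t < lo_t:  # void volume: larger than the biggest calibrant
        region = (stds[0].molecular_weight, math.inf)
    elif t > hi_t:
        region = (0.0, stds[-1].molecular_weight)
    else:
        # neighbouring standards around t
        left = max((s for s in stds if s.retention_time <= t),
                   key=lambda s: s.retention_time)
        right = min((s for s in stds if s.retention_time >= t),
                    key=lambda s: s.retention_time)
        region = (right.molecular_weight, left.molecular_weight)
    return MWAssignment(float(mw), extrapolated, region)


def detect_peaks(time, intensity, min_snr: float = 5.0) -> list[ChromPeak]:
    """Detect chromatographic peaks on a uniform time grid.

    A sample is a peak when it is a local maximum whose height exceeds
    baseline + min_snr·noise and whose prominence exceeds min_snr·noise,
    where baseline is the median intensity and noise is the median absolute
    deviation of the first-differenced trace.  The prominence gate keeps
    noise wiggles on the flank of a large peak from registering as peaks of
    their own.  Invariant to uniform intensity scaling.
    """
    t = np.asarray(time, float)
    y = np.asarray(intensity, float)
    if t.size < 10:
        raise ValueError("chromatogram needs at least 10 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-12):
        raise ValueError("chromatogram time grid is not uniform")
    baseline = float(np.median(y))
    dy = np.diff(y)
    noise = float(np.median(np.abs(dy - np.median(dy))))
    floor = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    thr = baseline + min_snr * max(noise, floor)
    idx, _ = signal.find_peaks(
        y, height=thr, prominence=min_snr * max(noise, floor)
    )
    peaks = []
    for i in idx:
        # integrate down to the nearest threshold crossings around the apex
        l = i
        while l > 0 and y[l - 1] > baseline:
            l -= 1
        r = i
        while r < y.size - 1 and y[r + 1] > baseline:
            r += 1
        area = float(np.trapezoid(y[l:r + 1] - baseline, t[l:r + 1]))
        peaks.append(
            ChromPeak(
                retention_time=float(t[i]),
                height=float(y[i] - baseline),
                area=area,
            )
        )
    peaks.sort(key=lambda p: p.retention_time)
    return peaks


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_standards_csv(path) -> list[SECStandard]:
    """CSV with columns name, mw_kda, rt_min."""
    df = pd.read_csv(path)
    return [
        SECStandard(str(r["name"]), float(r["mw_kda"]), float(r["rt_min"]))
        for _, r in df.iterrows()
    ]


def read_chromatogram_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """CSV with columns time_min, intensity."""
    df = pd.read_csv(path)
    return df["time_min"].to_numpy(float), df["intensity"].to_numpy(float)


def write_peaks_tsv(peaks: list[ChromPeak], path) -> None:
    rows = []
    for p in peaks:
        a = p.assigned_mw
        rows.append(
            {
                "rt_min": p.retention_time,
                "height": p.height,
                "area": p.area,
                "mw_kda": a.mw_kda if a else None,
                "extrapolated": a.extrapolated if a else None,
                "region_low_kda": a.region[0] if a else None,
                "region_high_kda": a.region[1] if a else None,
            }
        )
    pd.DataFrame(
        rows,
        columns=["rt_min", "height", "area", "mw_kda", "extrapolated",
                 "region_low_kda", "region_high_kda"],
    ).to_csv(path, sep="\t", index=False)
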