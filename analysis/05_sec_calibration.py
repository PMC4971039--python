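#!/usr/bin/env python
"""Fit the SEC molecular-weight calibration and assign MW to copper peaks.

Fits log10(MW) vs retention time through the five-standard set from 01,
detects peaks in the simulated SDS-extract chromatogram, and assigns each a
molecular weight (flagged when outside the calibrated span, e.g. the
void-volume peak).  Writes results/sec_peaks.tsv.
"""

import dataclasses
from pathlib import Path

from cuspec import sec_mw

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    standards = sec_mw.read_standards_csv(ROOT / "inputs" / "sec_standards.csv")
    model = sec_mw.fit_calibration(standards)
    print(f"calibration: log10(MW/kDa) = {model.intercept:.4f} "
          f"{model.slope:+.4f} t,  r^2 = {model.r_squared:.9f}, "
          f"valid {model.valid_range[0]:.2f}-{model.valid_range[1]:.2f} min")

    t, y = sec_mw.read_chromatogram_csv(ROOT / "inputs" / "chromatogram.csv")
    peaks = sec_mw.detect_peaks(t, y)
    peaks = [
        dataclasses.replace(p, assigned_mw=sec_mw.assign_mw(
            model, p.retention_time))
        for p in peaks
    ]
    sec_mw.write_peaks_tsv(peaks, ROOT / "sec_peaks.tsv")
    for p in peaks:
        a = p.assigned_mw
        lo, hi = a.region
        note = ("void volume, >%.0f kDa" % lo) if a.extrapolated and hi == float(
            "inf") else (
            f"between {lo:g} and {hi:g} kDa" if not a.extrapolated
            else f"below {hi:g} kDa")
        print(f"  peak {p.retention_time:5.1f} min -> {a.mw_kda:8.3g} kDa "
              f"({note})")


if __name__ == "__main__":
    main()
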