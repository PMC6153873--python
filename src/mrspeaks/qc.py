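"""Spectral quality control gating entry into classification.

Two rules, applied exactly as in the clinical workflow:

1. the creatine (3.0 ppm) and total choline (3.2 ppm) peaks must be
   well separated -- operationalised as the valley between the two
   apexes dipping below 90% of the smaller apex height (the 10%
   valley-depth criterion is configurable; the original rule is visual);
2. the total choline peak height must be at least five times the noise
   level (inclusive, per "at least").

Cases failing either rule are excluded from classification but logged.
QC is monotone in noise: raising the noise estimate with everything else
fixed can only turn a pass into a fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measure import DEFAULT_WINDOWS, PeakHeightSet, PeakWindow, baseline_level
from .spectra import Spectrum


@dataclass(frozen=True)
class QCCheck:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class QCResult:
    passed: bool
    checks: tuple[QCCheck, ...]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": [
                {"name": c.name, "passed": c.passed, "detail": c.detail}
                for c in self.checks
            ],
        }


def check_peak_separation(spectrum: Spectrum, peaks: PeakHeightSet,
                          windows: dict[str, PeakWindow] = DEFAULT_WINDOWS,
                          depth: float = 0.10) -> QCCheck:
    """Creatine and total choline must be visually well separated.

    Passes when the minimum intensity between the two apexes drops below
    ``(1 - depth)`` times the smaller apex height above baseline.
    """
    name = "cr_tcho_separation"
    for peak in ("cr", "tcho"):
        if peaks.heights.get(peak, 0.0) <= 0:
            return QCCheck(name, False, f"{peak} apex not found (height 0)")
    base = baseline_level(spectrum, windows)
    cr_idx = spectrum.slice_indices(windows["cr"].lo_ppm, windows["cr"].hi_ppm)
    tcho_idx = spectrum.slice_indices(windows["tcho"].lo_ppm, windows["tcho"].hi_ppm)
    if len(cr_idx) == 0 or len(tcho_idx) == 0:
        return QCCheck(name, False, "apex not found (empty window)")
    cr_apex = int(cr_idx[np.argmax(spectrum.intensity[cr_idx])])
    tcho_apex = int(tcho_idx[np.argmax(spectrum.intensity[tcho_idx])])
    lo, hi = sorted((cr_apex, tcho_apex))
    if hi - lo < 2:
        return QCCheck(name, False, "apexes adjacent: peaks merged")
    between = spectrum.intensity[lo + 1:hi]
    valley = float(np.min(between)) - base
    cr_h = float(spectrum.intensity[cr_apex]) - base
    tcho_h = float(spectrum.intensity[tcho_apex]) - base
    limit = (1.0 - depth) * min(cr_h, tcho_h)
    passed = valley < limit
    return QCCheck(
        name, passed,
        f"valley {valley:.3g} vs limit {limit:.3g} "
        f"(Cr {cr_h:.3g}, tCho {tcho_h:.3g} above baseline)",
    )


def check_choline_snr(peaks: PeakHeightSet, factor: float = 5.0) -> QCCheck:
    """Total choline height must be at least ``factor`` times the noise."""
    if peaks.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0 for the choline SNR check")
    tcho = peaks.heights.get("tcho", 0.0)
    passed = tcho >= factor * peaks.noise_sd
    return QCCheck(
        "choline_snr", passed,
        f"tCho height {tcho:.3g} vs {factor:g} x noise {peaks.noise_sd:.3g} "
        f"= {factor * peaks.noise_sd:.3g}",
    )


def apply_qc(spectrum: Spectrum, peaks: PeakHeightSet,
             windows: dict[str, PeakWindow] = DEFAULT_WINDOWS,
             depth: float = 0.10, snr_factor: float = 5.0) -> QCResult:
    """Aggregate both rules; any internal error becomes a failing check."""
    checks: list[QCCheck] = []
    try:
        checks.append(check_peak_separation(spectrum, peaks, windows, depth))
    except Exception as exc:  # degenerate spectra become failed checks
        checks.append(QCCheck("cr_tcho_separation", False, f"error: {exc}"))
    try:
        checks.append(check_choline_snr(peaks, snr_factor))
    except Exception as exc:
        checks.append(QCCheck("choline_snr", False, f"error: {exc}"))
    return QCResult(all(c.passed for c in checks), tuple(checks))
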