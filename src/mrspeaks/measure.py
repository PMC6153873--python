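"""Peak-height and noise measurement from a processed spectrum.

Peak height is the vertical distance between the apex of a peak and the
baseline.  Two baseline conventions are used, matching how spectra are
read in practice:

* ``flat`` -- the baseline is visually flat, and every height is taken
  from one set baseline level (the median intensity of the peak-free
  regions) to the apex;
* ``local_base`` -- the baseline wanders, and each height is taken from
  the base of the individual peak (linear interpolation between the
  nearest flanking local minima) to its apex.

Which convention applies is decided per spectrum by a flatness test: a
smooth baseline estimate fitted through the peak-free regions counts as
flat when it never strays more than twice the noise level from its
median.

NAA needs special care at short echo time: a broad lipid/macromolecule
hump at 2.0-2.5 ppm often swallows the narrow 2.02-ppm singlet.  When a
local maximum with prominence above twice the noise level exists near
2.0 ppm its height is used (``narrow`` mode); otherwise the intensity of
the broad structure at 2.0 ppm stands in (``broad`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .spectra import Spectrum

PEAK_ORDER: tuple[str, ...] = ("naa", "cr", "tcho", "mins", "lmm09", "lmm13")


@dataclass(frozen=True)
class PeakWindow:
    """A named ppm window expected to contain one peak apex."""

    name: str
    centre_ppm: float
    lo_ppm: float
    hi_ppm: float

    def __post_init__(self):
        if not (self.lo_ppm < self.centre_ppm < self.hi_ppm):
            raise ValueError(
                f"window {self.name}: need lo < centre < hi "
                f"({self.lo_ppm}, {self.centre_ppm}, {self.hi_ppm})"
            )


DEFAULT_WINDOWS: dict[str, PeakWindow] = {
    "naa": PeakWindow("naa", 2.02, 1.90, 2.10),
    "cr": PeakWindow("cr", 3.03, 2.90, 3.10),
    "tcho": PeakWindow("tcho", 3.20, 3.10, 3.30),
    "mins": PeakWindow("mins", 3.56, 3.45, 3.65),
    "lmm09": PeakWindow("lmm09", 0.90, 0.80, 1.00),
    "lmm13": PeakWindow("lmm13", 1.30, 1.20, 1.40),
}

# Peak-free interval used for the noise estimate: upfield of myo-inositol,
# clear of every default window and of the water-residual tail.
DEFAULT_NOISE_REGION: tuple[float, float] = (4.05, 4.45)

# ppm margin added around each window when selecting baseline support
# points, keeping Lorentzian tails out of the baseline estimate.
_BASELINE_MARGIN = 0.15


@dataclass
class PeakHeightSet:
    """Measured heights for the six peaks plus the context they need."""

    heights: dict[str, float]
    baseline_mode: dict[str, str]          # per peak: "flat" | "local_base"
    noise_sd: float
    naa_mode: str                          # "narrow" | "broad"
    baseline_level: float = 0.0
    apex_ppm: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def scaled(self, k: float) -> "PeakHeightSet":
        return PeakHeightSet(
            heights={p: h * k for p, h in self.heights.items()},
            baseline_mode=dict(self.baseline_mode),
            noise_sd=self.noise_sd * k,
            naa_mode=self.naa_mode,
            baseline_level=self.baseline_level * k,
            apex_ppm=dict(self.apex_ppm),
            flags=self.flags,
        )


def estimate_noise(spectrum: Spectrum,
                   region: tuple[float, float] = DEFAULT_NOISE_REGION,
                   windows: dict[str, PeakWindow] = DEFAULT_WINDOWS) -> float:
    """Standard deviation of linearly detrended intensities in ``region``.

    The region must lie on the axis, contain at least 32 points and not
    overlap any configured peak window.
    """
    lo, hi = min(region), max(region)
    if lo < spectrum.ppm_min - 1e-9 or hi > spectrum.ppm_max + 1e-9:
        raise ValueError(
            f"noise region [{lo}, {hi}] outside axis "
            f"[{spectrum.ppm_min:.2f}, {spectrum.ppm_max:.2f}]"
        )
    for w in windows.values():
        if lo < w.hi_ppm and hi > w.lo_ppm:
            raise ValueError(
                f"noise region [{lo}, {hi}] overlaps peak window {w.name!r}"
            )
    idx = spectrum.slice_indices(lo, hi)
    if len(idx) < 32:
        raise ValueError(
            f"noise region [{lo}, {hi}] contains only {len(idx)} points; "
            "at least 32 required"
        )
    detrended = signal.detrend(spectrum.intensity[idx], type="linear")
    return float(np.std(detrended, ddof=1))


def _baseline_support(spectrum: Spectrum,
                      windows: dict[str, PeakWindow]) -> np.ndarray:
    """Indices of baseline support points: away from every peak window
    (with margin) and below the water-residual shoulder."""
    mask = (spectrum.ppm <= 4.45) & (spectrum.ppm >= spectrum.ppm_min)
    for w in windows.values():
        mask &= ~((spectrum.ppm >= w.lo_ppm - _BASELINE_MARGIN)
                  & (spectrum.ppm <= w.hi_ppm + _BASELINE_MARGIN))
    return np.nonzero(mask)[0]


def baseline_level(spectrum: Spectrum,
                   windows: dict[str, PeakWindow] = DEFAULT_WINDOWS) -> float:
    """The set baseline level: median intensity over peak-free regions."""
    idx = _baseline_support(spectrum, windows)
    if len(idx) == 0:
        return 0.0
    return float(np.median(spectrum.intensity[idx]))


def assess_baseline(spectrum: Spectrum, noise_sd: float,
                    windows: dict[str, PeakWindow] = DEFAULT_WINDOWS,
                    threshold_factor: float = 2.0) -> str:
    """Classify the baseline as ``"flat"`` or ``"non_flat"``.

    A degree-4 polynomial is fitted through the peak-free support points;
    the baseline counts as flat when the fit never deviates from its own
    median by more than ``threshold_factor`` times the noise level.  A
    degenerate (zero-noise) spectrum is judged against a tiny absolute
    tolerance instead.
    """
    idx = _baseline_support(spectrum, windows)
    if len(idx) < 8:
        return "non_flat"
    x = spectrum.ppm[idx]
    y = spectrum.intensity[idx]
    fit = np.polynomial.Chebyshev.fit(x, y, deg=4)
    smooth = fit(x)
    deviation = float(np.max(np.abs(smooth - np.median(smooth))))
    tol = threshold_factor * noise_sd if noise_sd > 0 else 1e-9
    return "flat" if deviation < tol else "non_flat"


def _local_base(spectrum: Spectrum, apex_idx: int,
                search_halfwidth_ppm: float = 0.25,
                smooth_points: int = 9) -> float:
    """Baseline under the apex by linear interpolation between the
    nearest flanking local minima of a lightly smoothed trace."""
    step = abs(float(np.mean(np.diff(spectrum.ppm))))
    reach = max(3, int(round(search_halfwidth_ppm / step)))
    lo = max(0, apex_idx - reach)
    hi = min(len(spectrum) - 1, apex_idx + reach)
    y = spectrum.intensity
    if smooth_points >= 5 and hi - lo + 1 > smooth_points:
        ys = signal.savgol_filter(y[lo:hi + 1], smooth_points, 2)
    else:
        ys = y[lo:hi + 1].copy()
    centre = apex_idx - lo

    def nearest_min(direction: int) -> int:
        i = centre
        while 0 < i + direction < len(ys) - 1:
            i += direction
            if ys[i] <= ys[i - 1] and ys[i] <= ys[i + 1]:
                return i
        return max(0, min(i + direction, len(ys) - 1))

    left = nearest_min(-1)
    right = nearest_min(+1)
    x = spectrum.ppm[lo:hi + 1]
    if x[right] == x[left]:
        return float(ys[left])
    frac = (x[centre] - x[left]) / (x[right] - x[left])
    return float(ys[left] + frac * (ys[right] - ys[left]))


def measure_peak_height(spectrum: Spectrum, window: PeakWindow,
                        mode: str = "flat", *,
                        base_level: float | None = None,
                        windows: dict[str, PeakWindow] = DEFAULT_WINDOWS):
    """Height of the peak in ``window`` under the given baseline mode.

    Returns ``(height, flags)``.  ``flags`` warns when the apex sits on
    a window edge (possible mis-windowing).  Heights are clipped at 0.
    """
    idx = spectrum.slice_indices(window.lo_ppm, window.hi_ppm)
    if len(idx) == 0:
        raise ValueError(f"window {window.name!r} contains no axis points")
    seg = spectrum.intensity[idx]
    local = int(np.argmax(seg))
    apex_idx = int(idx[local])
    flags: list[str] = []
    if local in (0, len(idx) - 1):
        flags.append(f"{window.name}: apex on window edge")
    apex = float(seg[local])
    if mode == "flat":
        if base_level is None:
            base_level = baseline_level(spectrum, windows)
        height = apex - base_level
    elif mode == "local_base":
        height = apex - _local_base(spectrum, apex_idx)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    if height < 0:
        flags.append(f"{window.name}: negative height clipped to 0")
        height = 0.0
    return height, float(spectrum.ppm[apex_idx]), flags


def measure_naa(spectrum: Spectrum, noise_sd: float, *,
                mode: str = "flat",
                base_level: float | None = None,
                windows: dict[str, PeakWindow] = DEFAULT_WINDOWS,
                narrow_range: tuple[float, float] = (1.95, 2.10),
                prominence_factor: float = 2.0):
    """NAA height with narrow/broad disambiguation.

    A local maximum in ``narrow_range`` with prominence above
    ``prominence_factor * noise_sd`` selects narrow mode and its apex
    height; otherwise the broad structure's intensity at 2.0 ppm (above
    the set baseline) is used.  Returns ``(height, naa_mode, flags)``.
    """
    if base_level is None:
        base_level = baseline_level(spectrum, windows)
    idx = spectrum.slice_indices(*narrow_range)
    flags: list[str] = []
    if len(idx) >= 3:
        seg = spectrum.intensity[idx][::-1]  # ascending ppm for find_peaks
        prominence = max(prominence_factor * noise_sd, 1e-12)
        peaks, props = signal.find_peaks(seg, prominence=prominence)
        if len(peaks) > 0:
            best = peaks[int(np.argmax(props["prominences"]))]
            apex = float(seg[best])
            apex_ppm = float(spectrum.ppm[idx][::-1][best])
            if mode == "local_base":
                apex_idx = int(np.argmin(np.abs(spectrum.ppm - apex_ppm)))
                height = apex - _local_base(spectrum, apex_idx)
            else:
                height = apex - base_level
            if height < 0:
                flags.append("naa: negative height clipped to 0")
                height = 0.0
            return height, "narrow", flags
    height = spectrum.value_at(2.0) - base_level
    if noise_sd <= 0 and height == 0:
        flags.append("naa: degenerate flat spectrum")
    if height < 0:
        flags.append("naa: negative height clipped to 0")
        height = 0.0
    return height, "broad", flags


def measure_all(spectrum: Spectrum,
                windows: dict[str, PeakWindow] = DEFAULT_WINDOWS,
                noise_region: tuple[float, float] = DEFAULT_NOISE_REGION,
                ) -> PeakHeightSet:
    """Measure noise, baseline mode and all six peak heights.

    Deterministic: repeated calls on the same spectrum give identical
    results.
    """
    noise_sd = estimate_noise(spectrum, noise_region, windows)
    flags: list[str] = []
    if noise_sd == 0:
        flags.append("noise: zero noise estimate (degenerate spectrum)")
    flatness = assess_baseline(spectrum, noise_sd, windows)
    mode = "flat" if flatness == "flat" else "local_base"
    base = baseline_level(spectrum, windows)

    heights: dict[str, float] = {}
    modes: dict[str, str] = {}
    apexes: dict[str, float] = {}

    naa_h, naa_mode, naa_flags = measure_naa(
        spectrum, noise_sd, mode=mode, base_level=base, windows=windows)
    heights["naa"] = naa_h
    modes["naa"] = mode
    apexes["naa"] = windows["naa"].centre_ppm
    flags.extend(naa_flags)

    for name in PEAK_ORDER:
        if name == "naa":
            continue
        h, apex_ppm, peak_flags = measure_peak_height(
            spectrum, windows[name], mode, base_level=base, windows=windows)
        heights[name] = h
        modes[name] = mode
        apexes[name] = apex_ppm
        flags.extend(peak_flags)

    return PeakHeightSet(
        heights=heights,
        baseline_mode=modes,
        noise_sd=noise_sd,
        naa_mode=naa_mode,
        baseline_level=base,
        apex_ppm=apexes,
        flags=tuple(flags),
    )


def window_jitter(spectrum: Spectrum,
                  windows: dict[str, PeakWindow] = DEFAULT_WINDOWS,
                  shift_ppm: float = 0.02) -> dict[str, float]:
    """Robustness surrogate for repeated manual measurement: the relative
    spread of each height under +-``shift_ppm`` window perturbation."""
    base = measure_all(spectrum, windows)
    spreads: dict[str, list[float]] = {p: [base.heights[p]] for p in PEAK_ORDER}
    for delta in (-shift_ppm, shift_ppm):
        shifted = {
            name: PeakWindow(name, w.centre_ppm + delta,
                             w.lo_ppm + delta, w.hi_ppm + delta)
            for name, w in windows.items()
        }
        peaks = measure_all(spectrum, shifted)
        for p in PEAK_ORDER:
            spreads[p].append(peaks.heights[p])
    out = {}
    for p, values in spreads.items():
        centre = values[0]
        span = max(values) - min(values)
        out[p] = span / centre if centre > 0 else float("inf")
    return out
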