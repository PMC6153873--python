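"""Synthetic cohorts and synthetic 1.5-T short-TE spectra.

The generator works at the processed-spectrum level (no FID, eddy-current
or water-suppression modelling).  A case is six latent peak heights drawn
from class-conditional log-normal distributions; the nine diagnostic
ratios are derived from those heights, so every generated ratio vector is
internally consistent by construction (e.g. mIns/NAA equals
(mIns/tCho)/(NAA/tCho) exactly).  A full spectrum is then Lorentzian
metabolite lines plus broad Gaussian lipid/macromolecule humps, an
optional slowly varying baseline with a water-suppression residue near
4.7 ppm, and white Gaussian noise.

The shipped class levels emulate the metabolite profiles of the three
main childhood cerebellar tumour types at 1.5 T: pilocytic astrocytoma
with low creatine and low myo-inositol (high NAA/Cr, low mIns/NAA),
medulloblastoma with high total choline (low mIns/tCho), and ependymoma
with high myo-inositol (high mIns/tCho).  They are calibrated so the
class-conditional distributions sit consistently around the published
decision cutoffs (geometric crossing points near NAA/Cr 2.2, mIns/NAA
0.65 and mIns/tCho 0.85); per-class ratio statistics of the source
cohorts are unpublished, so these are modelling choices, not measured
values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .rules import RATIO_NAMES, compute_ratios_from_heights
from .spectra import Spectrum

PEAK_NAMES: tuple[str, ...] = ("naa", "cr", "tcho", "mins", "lmm09", "lmm13")

# Line positions (ppm).  myo-inositol is not pinned by convention in the
# same way as the singlets; 3.56 ppm is the standard literature position
# and is configurable below.
DEFAULT_PEAK_PPM: dict[str, float] = {
    "naa": 2.02, "cr": 3.03, "tcho": 3.20,
    "mins": 3.56, "lmm09": 0.90, "lmm13": 1.30,
}


class SimulationConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class LogNormalLevel:
    """Median and log-scale sd of one latent peak height (a.u.)."""

    median: float
    sigma: float

    def validate(self, label: str) -> None:
        if self.median <= 0:
            raise SimulationConfigError(f"{label}: median must be > 0")
        if self.sigma <= 0:
            raise SimulationConfigError(f"{label}: sigma must be > 0")


# Class-conditional latent height levels (median a.u. relative units,
# log-sd).  tCho carries a deliberately large spread for pilocytic
# astrocytoma: overall intensity scaling and choline variability blur
# every x/tCho ratio while the height ratios between metabolites (NAA/Cr,
# mIns/NAA) stay tight -- the pattern that makes those two ratios the
# discriminators of choice.
DEFAULT_CLASS_LEVELS: dict[str, dict[str, LogNormalLevel]] = {
    "PA": {
        "naa": LogNormalLevel(0.82, 0.16),
        "cr": LogNormalLevel(0.25, 0.16),
        "mins": LogNormalLevel(0.38, 0.18),
        "tcho": LogNormalLevel(1.00, 0.50),
        "lmm09": LogNormalLevel(0.35, 0.40),
        "lmm13": LogNormalLevel(0.45, 0.40),
    },
    "MB": {
        "naa": LogNormalLevel(0.80, 0.16),
        "cr": LogNormalLevel(0.50, 0.16),
        "mins": LogNormalLevel(0.73, 0.22),
        "tcho": LogNormalLevel(1.45, 0.22),
        "lmm09": LogNormalLevel(0.85, 0.40),
        "lmm13": LogNormalLevel(1.25, 0.40),
    },
    "EP": {
        "naa": LogNormalLevel(0.85, 0.16),
        "cr": LogNormalLevel(0.51, 0.16),
        "mins": LogNormalLevel(1.35, 0.22),
        "tcho": LogNormalLevel(0.95, 0.22),
        "lmm09": LogNormalLevel(0.45, 0.40),
        "lmm13": LogNormalLevel(0.55, 0.40),
    },
}

# Prospective-cohort class sizes (13 pilocytic astrocytomas,
# 4 ependymomas, 14 medulloblastomas).
PROSPECTIVE_CLASS_COUNTS = {"PA": 13, "EP": 4, "MB": 14}


@dataclass
class SimulationConfig:
    """Everything needed to draw a cohort and render its spectra.

    Spectral parameters: ``linewidth_ppm`` is the Lorentzian full width
    at half maximum of the metabolite lines; ``lmm_width_ppm`` the
    Gaussian FWHM of the lipid/macromolecule humps.  ``intensity_scale``
    multiplies all latent heights into scanner-like arbitrary units.
    The axis spans ``ppm_min``..``ppm_max`` with a grid step that places
    the default line centres exactly on grid points, so a noise-free
    apex equals the requested height to machine precision.
    """

    class_counts: dict = field(
        default_factory=lambda: dict(PROSPECTIVE_CLASS_COUNTS))
    class_levels: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CLASS_LEVELS))
    peak_ppm: dict = field(default_factory=lambda: dict(DEFAULT_PEAK_PPM))
    linewidth_ppm: float = 0.03
    lmm_width_ppm: float = 0.19
    ppm_min: float = 0.0
    ppm_max: float = 4.5
    n_points: int = 901
    intensity_scale: float = 10.0
    noise_sd: float = 0.10
    baseline_amplitude: float = 0.0
    baseline_hump_center_ppm: float = 2.5
    baseline_hump_width_ppm: float = 1.2
    water_residual_amplitude: float = 0.0
    water_residual_ppm: float = 4.7
    water_residual_width_ppm: float = 0.5
    seed: int = 0
    source_id: str = "sim"

    def validate(self) -> None:
        for cls, count in self.class_counts.items():
            if count < 0:
                raise SimulationConfigError(f"class count for {cls} must be >= 0")
            if cls not in self.class_levels:
                raise SimulationConfigError(f"no levels configured for class {cls}")
        for cls, levels in self.class_levels.items():
            for peak in PEAK_NAMES:
                if peak not in levels:
                    raise SimulationConfigError(f"{cls}: missing level for {peak}")
                levels[peak].validate(f"{cls}/{peak}")
        if self.linewidth_ppm <= 0 or self.lmm_width_ppm <= 0:
            raise SimulationConfigError("linewidths must be > 0")
        if self.noise_sd < 0:
            raise SimulationConfigError("noise_sd must be >= 0")
        if self.n_points < 64:
            raise SimulationConfigError("n_points must be >= 64")
        if self.ppm_max <= self.ppm_min:
            raise SimulationConfigError("ppm_max must exceed ppm_min")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["class_levels"] = {
            cls: {peak: [lvl.median, lvl.sigma] for peak, lvl in levels.items()}
            for cls, levels in self.class_levels.items()
        }
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        payload = dict(payload)
        if "class_levels" in payload:
            payload["class_levels"] = {
                c: {p: LogNormalLevel(*pair) for p, pair in levels.items()}
                for c, levels in payload["class_levels"].items()
            }
        config = cls(**payload)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    def axis(self) -> np.ndarray:
        """Descending ppm axis."""
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def sample_heights(config: SimulationConfig, true_class: str,
                   rng: np.random.Generator) -> dict[str, float]:
    """One case's six latent peak heights (a.u., already intensity-scaled)."""
    levels = config.class_levels[true_class]
    heights = {}
    for peak in PEAK_NAMES:
        lvl = levels[peak]
        heights[peak] = (config.intensity_scale * lvl.median
                         * float(np.exp(lvl.sigma * rng.standard_normal())))
    return heights


def sample_ratio_profiles(config: SimulationConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Draw a class-labelled cohort table of consistent ratio vectors.

    Returns a DataFrame with ``case_id``, ``true_class``, the nine ratio
    columns and ``source_id``.  Identical config and seed give an
    identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    case = 0
    for true_class in sorted(config.class_counts):
        for _ in range(config.class_counts[true_class]):
            case += 1
            heights = sample_heights(config, true_class, rng)
            row = {"case_id": f"{config.source_id}-{case:04d}",
                   "true_class": true_class}
            row.update(compute_ratios_from_heights(heights))
            row["source_id"] = config.source_id
            rows.append(row)
    columns = ["case_id", "true_class", *RATIO_NAMES, "source_id"]
    return pd.DataFrame(rows, columns=columns)


def sample_cohort_with_heights(config: SimulationConfig,
                               seed: int | None = None):
    """Like :func:`sample_ratio_profiles` but also returns the latent
    heights per case (list of dicts, aligned with the table rows)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, heights_list = [], []
    case = 0
    for true_class in sorted(config.class_counts):
        for _ in range(config.class_counts[true_class]):
            case += 1
            heights = sample_heights(config, true_class, rng)
            heights_list.append(heights)
            row = {"case_id": f"{config.source_id}-{case:04d}",
                   "true_class": true_class}
            row.update(compute_ratios_from_heights(heights))
            row["source_id"] = config.source_id
            rows.append(row)
    columns = ["case_id", "true_class", *RATIO_NAMES, "source_id"]
    return pd.DataFrame(rows, columns=columns), heights_list


# ---------------------------------------------------------------------------
# Spectrum synthesis
# ---------------------------------------------------------------------------

def _lorentzian(ppm: np.ndarray, center: float, height: float,
                fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0  # half width at half maximum
    return height * gamma**2 / ((ppm - center) ** 2 + gamma**2)


def _gaussian(ppm: np.ndarray, center: float, height: float,
              fwhm: float) -> np.ndarray:
    sd = fwhm / 2.3548200450309493  # FWHM -> sd
    return height * np.exp(-0.5 * ((ppm - center) / sd) ** 2)


def synthesize_spectrum(heights, config: SimulationConfig | None = None,
                        seed: int | None = None, *,
                        source_id: str | None = None) -> Spectrum:
    """Render a spectrum with the requested apex heights above baseline.

    Metabolite singlets (NAA, Cr, tCho, mIns) are Lorentzian; the lipid/
    macromolecule resonances at 0.9 and 1.3 ppm are broad Gaussians.
    Missing peaks may simply be omitted from ``heights``.  Noise and the
    baseline come from ``config``; ``seed`` overrides the config seed for
    the noise draw.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    for peak, h in heights.items():
        if h < 0:
            raise ValueError(f"negative height for {peak!r}")
        if peak not in config.peak_ppm:
            raise ValueError(f"unknown peak {peak!r}")
    ppm = config.axis()
    intensity = np.zeros_like(ppm)
    for peak, h in heights.items():
        if h == 0:
            continue
        center = config.peak_ppm[peak]
        if peak in ("lmm09", "lmm13"):
            intensity += _gaussian(ppm, center, h, config.lmm_width_ppm)
        else:
            intensity += _lorentzian(ppm, center, h, config.linewidth_ppm)
    if config.baseline_amplitude:
        intensity += _gaussian(ppm, config.baseline_hump_center_ppm,
                               config.baseline_amplitude,
                               config.baseline_hump_width_ppm)
    if config.water_residual_amplitude:
        intensity += _gaussian(ppm, config.water_residual_ppm,
                               config.water_residual_amplitude,
                               config.water_residual_width_ppm)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        intensity = intensity + config.noise_sd * rng.standard_normal(len(ppm))
    return Spectrum(
        ppm=ppm,
        intensity=intensity,
        echo_time_ms=30.0,
        field_strength_T=1.5,
        source_id=config.source_id if source_id is None else source_id,
        meta={"synthetic": True, "seed": int(config.seed if seed is None else seed)},
    )


def make_fixture_cohort(seed: int = 20050216) -> pd.DataFrame:
    """A packaged worked-example cohort.

    The four rare-tumour mean profiles (exact reported values) plus a
    simulated prospective-sized cohort of the three main types
    (13 pilocytic astrocytomas, 4 ependymomas, 14 medulloblastomas)
    drawn from the shipped class levels with a fixed seed.
    """
    from .reference import rare_tumour_profiles

    config = SimulationConfig(class_counts=dict(PROSPECTIVE_CLASS_COUNTS),
                              seed=seed, source_id="fixture")
    simulated = sample_ratio_profiles(config)
    return pd.concat([rare_tumour_profiles(), simulated], ignore_index=True)


def write_spectrum_csv_for_case(heights: dict, config: SimulationConfig,
                                path, case_seed: int) -> None:
    """Render and write one case's spectrum as a two-column CSV."""
    from .spectra import write_spectrum_csv

    spectrum = synthesize_spectrum(heights, config, seed=case_seed)
    write_spectrum_csv(spectrum, path)


# ---------------------------------------------------------------------------
# Cohort CSV round trip
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["case_id", "true_class", *RATIO_NAMES, "source_id"]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, columns=[c for c in COHORT_COLUMNS
                                              if c in cohort.columns])


def read_cohort_csv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = [c for c in ("case_id", "true_class", *RATIO_NAMES)
               if c not in cohort.columns]
    if missing:
        raise ValueError(f"{path}: missing cohort columns {missing}")
    if cohort["case_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate case_id values")
    values = cohort[list(RATIO_NAMES)].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite ratio values")
    return cohort
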