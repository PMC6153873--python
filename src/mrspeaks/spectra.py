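"""Processed single-voxel MR spectra and their on-disk representation.

A spectrum here is the trace a scanner's own post-processing produces: an
axis of chemical shifts in parts per million (ppm) and one intensity value
per point, in arbitrary units (a.u.).  By display convention the ppm axis
runs from high to low; readers normalise to that orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file or array pair is not a valid spectrum."""


@dataclass
class Spectrum:
    """A one-dimensional processed MR spectrum.

    Parameters
    ----------
    ppm : ndarray
        Chemical-shift axis in ppm, strictly monotone.  Stored descending
        (high to low ppm, the usual display orientation).
    intensity : ndarray
        Intensities in arbitrary units, same length as ``ppm``.
    echo_time_ms : float
        Echo time of the acquisition; short-TE PRESS is 28-35 ms.
    field_strength_T : float
        Static field strength in tesla.
    source_id : str
        Free-text centre/scanner tag carried through to outputs.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    echo_time_ms: float = 30.0
    field_strength_T: float = 1.5
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumFormatError("ppm and intensity must be 1-D arrays")
        if len(self.ppm) != len(self.intensity):
            raise SpectrumFormatError(
                f"axis length {len(self.ppm)} != intensity length {len(self.intensity)}"
            )
        if len(self.ppm) < 2:
            raise SpectrumFormatError("spectrum needs at least two points")
        diffs = np.diff(self.ppm)
        if np.all(diffs > 0):
            # ascending input: normalise to descending display order
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(diffs < 0):
            raise SpectrumFormatError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumFormatError("intensities must be finite")
        if not np.all(np.isfinite(self.ppm)):
            raise SpectrumFormatError("ppm values must be finite")
        if self.ppm_min > 0.5 or self.ppm_max < 4.0:
            raise SpectrumFormatError(
                "ppm axis must cover at least [0.5, 4.0] "
                f"(got [{self.ppm_min:.3f}, {self.ppm_max:.3f}])"
            )

    # -- convenience -------------------------------------------------------

    @property
    def ppm_min(self) -> float:
        return float(self.ppm[-1])

    @property
    def ppm_max(self) -> float:
        return float(self.ppm[0])

    def __len__(self) -> int:
        return len(self.ppm)

    def slice_indices(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        """Indices of points with lo_ppm <= ppm <= hi_ppm."""
        mask = (self.ppm >= lo_ppm) & (self.ppm <= hi_ppm)
        return np.nonzero(mask)[0]

    def value_at(self, ppm: float) -> float:
        """Intensity at the axis point nearest to ``ppm``."""
        idx = int(np.argmin(np.abs(self.ppm - ppm)))
        return float(self.intensity[idx])

    def scaled(self, k: float) -> "Spectrum":
        return replace(self, intensity=self.intensity * k)

    def plot(self, ax=None, **kwargs):
        """Plot intensity against ppm with the axis reversed, MRS-style."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ppm, self.intensity, **kwargs)
        if not ax.xaxis_inverted():
            ax.invert_xaxis()
        ax.set_xlabel("chemical shift (ppm)")
        ax.set_ylabel("intensity (a.u.)")
        return ax


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a two-column ``ppm,intensity`` CSV (scanner-export surrogate)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ppm,intensity\n")
        for p, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{p:.6f},{y:.8g}\n")


def read_spectrum_csv(path, *, echo_time_ms: float = 30.0,
                      field_strength_T: float = 1.5,
                      source_id: str = "") -> Spectrum:
    """Read a two-column ``ppm,intensity`` CSV into a :class:`Spectrum`.

    The file must have a header row and at least 64 numeric data rows.
    Ascending axes are normalised to descending.  Malformed rows are
    reported with their 1-based line number.
    """
    ppm: list[float] = []
    intensity: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() == "":
            raise SpectrumFormatError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: expected two comma-separated values"
                )
            try:
                p, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from exc
            ppm.append(p)
            intensity.append(y)
    if len(ppm) < 64:
        raise SpectrumFormatError(
            f"{path}: only {len(ppm)} data points; at least 64 required"
        )
    arr = np.asarray(ppm)
    if len(np.unique(arr)) != len(arr):
        raise SpectrumFormatError(f"{path}: duplicate ppm values")
    return Spectrum(
        ppm=arr,
        intensity=np.asarray(intensity),
        echo_time_ms=echo_time_ms,
        field_strength_T=field_strength_T,
        source_id=source_id,
    )


def write_spectrum_json(spectrum: Spectrum, path) -> None:
    """Write a spectrum as JSON with a metadata block."""
    payload = {
        "meta": {
            "echo_time_ms": spectrum.echo_time_ms,
            "field_strength_T": spectrum.field_strength_T,
            "source_id": spectrum.source_id,
            **spectrum.meta,
        },
        "ppm": spectrum.ppm.tolist(),
        "intensity": spectrum.intensity.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_spectrum_json(path) -> Spectrum:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    meta = dict(payload.get("meta", {}))
    return Spectrum(
        ppm=np.asarray(payload["ppm"], dtype=float),
        intensity=np.asarray(payload["intensity"], dtype=float),
        echo_time_ms=float(meta.pop("echo_time_ms", 30.0)),
        field_strength_T=float(meta.pop("field_strength_T", 1.5)),
        source_id=str(meta.pop("source_id", "")),
        meta=meta,
    )
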