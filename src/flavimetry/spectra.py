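"""Emission spectra and the two spectral statistics of autofluorescence redox imaging.

The optical redox ratio RR = FAD / (NAD(P)H + FAD) is computed from band
integrals of a single-excitation emission spectrum (NAD(P)H band 430-475 nm,
FAD band 520-600 nm).  R_flavin = I495 / I530 is the ratio of the emission
intensities at the protein-bound FMN main peak (495 nm) and the FAD main peak
/ FMN side peak (530 nm), a proxy for the relative amount of protein-bound
FMN versus FAD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "BandDefinition",
    "band_integrate",
    "redox_ratio",
    "r_flavin",
    "peak_intensity",
    "average_group_spectra",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
]


@dataclass(frozen=True)
class Spectrum:
    """Fluorescence intensity sampled on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValueError("wavelengths and intensities must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(it))):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    @property
    def coverage(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def scaled(self, c: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.intensities * c)


@dataclass(frozen=True)
class BandDefinition:
    """Integration bands and peak read-out positions (all nm).

    ``peak_window`` is the half-width of the averaging window used when
    reading a peak intensity; 0 reproduces a nearest-sample read.
    """

    nadh_band: tuple[float, float] = (430.0, 475.0)
    fad_band: tuple[float, float] = (520.0, 600.0)
    peak_fmn: float = 495.0
    peak_fad: float = 530.0
    peak_window: float = 2.0

    def __post_init__(self) -> None:
        for lo, hi in (self.nadh_band, self.fad_band):
            if not lo < hi:
                raise ValueError("band limits must satisfy lo < hi")
        if self.peak_window < 0:
            raise ValueError("peak_window must be >= 0")


def band_integrate(spectrum: Spectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the spectrum over a closed wavelength band.

    Band endpoints are included; if they do not fall on the grid the spectrum
    is linearly interpolated there.
    """
    lo, hi = float(band[0]), float(band[1])
    if not lo < hi:
        raise ValueError("band limits must satisfy lo < hi")
    wmin, wmax = spectrum.coverage
    if lo < wmin or hi > wmax:
        raise ValueError(
            f"band [{lo}, {hi}] nm outside spectral coverage [{wmin}, {wmax}] nm"
        )
    wl, it = spectrum.wavelengths, spectrum.intensities
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, wl, it)], it[inside], [np.interp(hi, wl, it)]))
    return float(np.trapezoid(ys, xs))


def redox_ratio(spectrum: Spectrum, bands: BandDefinition = BandDefinition()) -> float:
    """Optical redox ratio RR = FAD / (NAD(P)H + FAD) from band integrals."""
    nadh = band_integrate(spectrum, bands.nadh_band)
    fad = band_integrate(spectrum, bands.fad_band)
    total = nadh + fad
    if total <= 0:
        raise ValueError("redox ratio undefined: NAD(P)H + FAD integral is zero")
    return float(fad / total)


def peak_intensity(spectrum: Spectrum, center: float, window: float = 2.0) -> float:
    """Intensity at a peak: mean over samples within +/- window nm of ``center``.

    With ``window == 0`` the nearest grid sample is returned; if no sample
    falls inside the window the spectrum is interpolated at ``center``.
    """
    wl, it = spectrum.wavelengths, spectrum.intensities
    lo, hi = spectrum.coverage
    if center < lo or center > hi:
        raise ValueError(f"peak position {center} nm outside coverage [{lo}, {hi}] nm")
    if window == 0:
        return float(it[np.argmin(np.abs(wl - center))])
    sel = np.abs(wl - center) <= window
    if not np.any(sel):
        return float(np.interp(center, wl, it))
    return float(np.mean(it[sel]))


def r_flavin(spectrum: Spectrum, bands: BandDefinition = BandDefinition()) -> float:
    """R_flavin = I495 / I530, protein-bound FMN relative to FAD."""
    i495 = peak_intensity(spectrum, bands.peak_fmn, bands.peak_window)
    i530 = peak_intensity(spectrum, bands.peak_fad, bands.peak_window)
    if i530 <= 0:
        raise ValueError("R_flavin undefined: intensity at 530 nm is zero")
    return float(i495 / i530)


def average_group_spectra(
    spectra_by_group: dict[str, list[Spectrum]],
) -> dict[str, Spectrum]:
    """Per-group mean spectra, jointly normalized to the global maximum.

    All groups are divided by the single maximum across the group means, so
    the brightest group attains 1.0 at its peak ("relative spectral
    intensity").  All spectra must share one wavelength grid.
    """
    if not spectra_by_group:
        raise ValueError("no groups given")
    grid = None
    means: dict[str, np.ndarray] = {}
    for group, spectra in spectra_by_group.items():
        if not spectra:
            raise ValueError(f"group {group!r} has no spectra")
        for sp in spectra:
            if grid is None:
                grid = sp.wavelengths
            elif sp.wavelengths.shape != grid.shape or not np.allclose(
                sp.wavelengths, grid
            ):
                raise ValueError("all spectra must share a common wavelength grid")
        means[group] = np.mean([sp.intensities for sp in spectra], axis=0)
    global_max = max(float(m.max()) for m in means.values())
    if global_max <= 0:
        raise ValueError("all group spectra are zero; cannot normalize")
    return {g: Spectrum(grid, m / global_max) for g, m in means.items()}


def write_spectrum_tsv(spectrum: Spectrum, path: str | Path) -> None:
    header = "wavelength_nm\tintensity"
    data = np.column_stack([spectrum.wavelengths, spectrum.intensities])
    np.savetxt(path, data, delimiter="\t", header=header, comments="", fmt="%.6g")


def read_spectrum_tsv(path: str | Path) -> Spectrum:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return Spectrum(data[:, 0], data[:, 1])
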