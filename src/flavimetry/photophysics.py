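"""Forward photophysics: fluorophore emission mixtures and flavin-band lifetimes.

The endogenous fluorophores modeled are free NAD(P)H (emission peak 462 nm),
protein-bound FMN (main peak 495 nm with a side peak at 530 nm, ~10x the
quantum yield of FAD, long lifetime ~4.7 ns) and FAD (main peak 530 nm,
dominated by a short ~0.3 ns protein-bound component with a 2-3 ns free-FAD
component).  A scalar glycolytic index g in [0, 1] drives fluorophore
abundances affinely: free NAD(P)H and protein-bound FMN accumulate with
glycolysis while FAD fluorescence declines, which jointly pushes the optical
redox ratio down and R_flavin and the flavin-band lifetime up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flim import DEFAULT_F_MOD, forward_response, phase_lifetime
from .spectra import Spectrum

__all__ = [
    "FLUOROPHORES",
    "FLAVIN_SPECIES",
    "DEFAULT_GRID",
    "FluorophoreComponent",
    "AbundanceModel",
    "MetabolicState",
    "default_components",
    "gaussian_peak",
    "emission_spectrum",
    "abundance_map",
    "flavin_lifetime_of_state",
]

FLUOROPHORES = ("NADH_free", "NADH_bound", "FMN_bound", "FAD")

#: Species whose emission falls in the flavin detection band and whose decay
#: components constitute the measured flavin lifetime.
FLAVIN_SPECIES = ("FMN_bound", "FAD")

#: Native wavelength grid of the spectrometer model (430-740 nm, 1 nm).
DEFAULT_GRID = np.arange(430.0, 741.0, 1.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class FluorophoreComponent:
    """Emission shape, relative quantum yield and decay components of one species.

    ``subpeaks`` holds (center_nm, fwhm_nm, relative_amplitude) triples;
    ``lifetime_components`` holds (tau_ns, intensity_fraction) pairs whose
    fractions sum to one.
    """

    name: str
    subpeaks: tuple[tuple[float, float, float], ...]
    quantum_yield_rel: float
    lifetime_components: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.name not in FLUOROPHORES:
            raise ValueError(f"unknown fluorophore {self.name!r}")
        if self.quantum_yield_rel <= 0:
            raise ValueError("quantum_yield_rel must be positive")
        if not self.subpeaks:
            raise ValueError("at least one emission sub-peak required")
        for center, fwhm, amp in self.subpeaks:
            if fwhm <= 0 or amp < 0:
                raise ValueError("sub-peak fwhm must be > 0 and amplitude >= 0")
        fracs = [f for _, f in self.lifetime_components]
        if not self.lifetime_components or any(
            t <= 0 or not 0 <= f <= 1 for t, f in self.lifetime_components
        ):
            raise ValueError("lifetime components need tau > 0 and fractions in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("lifetime fractions must sum to 1")

    def shape(self, grid: np.ndarray) -> np.ndarray:
        """Unit-amplitude emission shape (before quantum yield) on the grid."""
        out = np.zeros_like(grid, dtype=float)
        for center, fwhm, amp in self.subpeaks:
            sigma = fwhm * _FWHM_TO_SIGMA
            out += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        return out


def default_components() -> dict[str, FluorophoreComponent]:
    """The default fluorophore library.

    FMN_bound carries 10x the quantum yield of FAD and a mono-exponential
    4.7 ns decay; FAD mixes a dominant 0.3 ns protein-bound component with a
    2.5 ns free-FAD component.  Peak widths are model parameters (the peak
    positions are the physically anchored quantities).
    """
    return {
        "NADH_free": FluorophoreComponent(
            name="NADH_free",
            subpeaks=((462.0, 60.0, 1.0),),
            quantum_yield_rel=1.0,
            lifetime_components=((0.4, 1.0),),
        ),
        "NADH_bound": FluorophoreComponent(
            name="NADH_bound",
            subpeaks=((445.0, 60.0, 1.0),),
            quantum_yield_rel=1.0,
            lifetime_components=((2.5, 1.0),),
        ),
        "FMN_bound": FluorophoreComponent(
            name="FMN_bound",
            subpeaks=((495.0, 40.0, 1.0), (530.0, 45.0, 0.55)),
            quantum_yield_rel=10.0,
            lifetime_components=((4.7, 1.0),),
        ),
        "FAD": FluorophoreComponent(
            name="FAD",
            subpeaks=((530.0, 45.0, 1.0),),
            quantum_yield_rel=1.0,
            lifetime_components=((0.3, 0.75), (2.5, 0.25)),
        ),
    }


def gaussian_peak(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Gaussian parameterized by FWHM (helper for tests/configs)."""
    sigma = fwhm * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((np.asarray(grid, float) - center) / sigma) ** 2)


def emission_spectrum(
    components: dict[str, FluorophoreComponent],
    abundances: dict[str, float],
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Linear emission mixture: sum of abundance x quantum yield x shape."""
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if grid[0] < 430.0 - 1e-9 or grid[-1] > 740.0 + 1e-9:
        raise ValueError("grid must lie within [430, 740] nm")
    if not abundances:
        raise ValueError("empty abundance map")
    intensity = np.zeros_like(grid)
    for name, a in abundances.items():
        if name not in components:
            raise ValueError(f"no component definition for {name!r}")
        if a < 0:
            raise ValueError(f"negative abundance for {name!r}")
        if a == 0:
            continue
        comp = components[name]
        intensity += a * comp.quantum_yield_rel * comp.shape(grid)
    return Spectrum(grid, intensity)


@dataclass(frozen=True)
class AbundanceModel:
    """Affine map from glycolytic index g to fluorophore abundances.

    abundance_f(g) = max(intercept_f + slope_f * g, 0).  Free NAD(P)H and
    protein-bound FMN must not decrease with g; FAD must not increase.
    """

    coefficients: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (_, slope) in self.coefficients.items():
            if name not in FLUOROPHORES:
                raise ValueError(f"unknown fluorophore {name!r}")
            if name in ("NADH_free", "FMN_bound") and slope < 0:
                raise ValueError(f"{name} abundance must be non-decreasing in g")
            if name == "FAD" and slope > 0:
                raise ValueError("FAD abundance must be non-increasing in g")

    def __call__(self, g: float) -> dict[str, float]:
        if not 0 <= g <= 1:
            raise ValueError(f"glycolytic index g={g} outside [0, 1]")
        return {
            name: max(intercept + slope * g, 0.0)
            for name, (intercept, slope) in self.coefficients.items()
        }


@dataclass(frozen=True)
class MetabolicState:
    """Latent state of one measurement: glycolytic index and abundances."""

    g: float
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 <= self.g <= 1:
            raise ValueError("glycolytic index must lie in [0, 1]")
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be nonnegative")


def abundance_map(g: float, model: AbundanceModel | None = None) -> dict[str, float]:
    """Fluorophore abundances at glycolytic index g.

    Without an explicit model the calibrated default (fitted to the
    group-average spectral anchors) is used.
    """
    if model is None:
        from .calibration import default_abundance_model

        model = default_abundance_model()
    return model(g)


def flavin_lifetime_of_state(
    abundances: dict[str, float],
    components: dict[str, FluorophoreComponent] | None = None,
    band: tuple[float, float] = (500.0, 580.0),
    f_mod: float = DEFAULT_F_MOD,
) -> float:
    """Apparent flavin-band lifetime of a metabolic state, in ns.

    Each decay component of each flavin species enters the phasor sum with
    weight (band-integrated emission of the species) x (component intensity
    fraction); the returned value is the phase lifetime at ``f_mod``.
    """
    if components is None:
        components = default_components()
    lo, hi = band
    grid = np.linspace(lo, hi, 161)
    mixture: list[tuple[float, float]] = []
    for name in FLAVIN_SPECIES:
        a = abundances.get(name, 0.0)
        if a < 0:
            raise ValueError(f"negative abundance for {name!r}")
        if a == 0 or name not in components:
            continue
        comp = components[name]
        band_emission = a * comp.quantum_yield_rel * np.trapezoid(comp.shape(grid), grid)
        for tau, frac in comp.lifetime_components:
            if frac > 0:
                mixture.append((tau, band_emission * frac))
    if not mixture or sum(w for _, w in mixture) <= 0:
        raise ValueError("zero total flavin intensity in the detection band")
    return phase_lifetime(forward_response(mixture, f_mod=f_mod))
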