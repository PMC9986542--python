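"""Synthetic cohort generation for the five-group brain-tumor study design.

The emulated cohort comprises 361 data points: 16 non-tumorous controls
(CTL), 71 low-grade gliomas (LGG), 117 high-grade gliomas (HGG), 64
meningiomas (MNG) and 93 metastases (MET).  Each data point carries the
three measured metrics: flavin fluorescence lifetime (500-580 nm band, ns),
optical redox ratio, and R_flavin.

Two generation modes are provided:

``metric_space``
    The quantitative mode.  Per group and metric, values are drawn from a
    two-piece-normal marginal whose quartiles match the calibration targets
    exactly, coupled across metrics through a shared latent glycolytic score
    (Gaussian copula): the redox ratio loads negatively on the latent,
    R_flavin and the lifetime positively.  Lifetimes are realized through
    the FD-FLIM phase estimator (modulated response -> phase lifetime).

``photophysics``
    The mechanistic mode.  A glycolytic index g is drawn per sample, mapped
    to fluorophore abundances, an emission spectrum and a flavin-band phasor
    lifetime by the forward model; metrics are then computed by the spectral
    pipeline.  Structurally faithful, quantitatively approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import spectra as sp
from .flim import DEFAULT_F_MOD, FLIMImage, phase_lifetime, response_from_lifetime
from .photophysics import (
    AbundanceModel,
    MetabolicState,
    default_components,
    emission_spectrum,
    flavin_lifetime_of_state,
)

__all__ = [
    "GROUPS",
    "GROUP_COUNTS",
    "METRICS",
    "METRIC_SIGNS",
    "HISTO_SUBLABELS",
    "TwoPieceNormal",
    "GroupPreset",
    "SampleRecord",
    "Cohort",
    "HotspotSpec",
    "sample_metabolic_state",
    "sample_group_metrics",
    "generate_cohort",
    "generate_flim_image",
    "write_cohort_csv",
    "read_cohort_csv",
]

GROUPS = ("CTL", "LGG", "HGG", "MNG", "MET")

#: Data points per group in the emulated study design.
GROUP_COUNTS = {"CTL": 16, "LGG": 71, "HGG": 117, "MNG": 64, "MET": 93}

METRICS = ("tau_ns", "redox_ratio", "r_flavin")

#: Loading sign of each metric on the shared latent glycolytic score.
METRIC_SIGNS = {"tau_ns": 1.0, "redox_ratio": -1.0, "r_flavin": 1.0}

HISTO_SUBLABELS = ("TUM", "INF", "NEC", "REA", "none")

#: Per-group histopathology sub-label proportions (plotting parity only).
_HISTO_PROPS: dict[str, dict[str, float]] = {
    "CTL": {"none": 1.0},
    "LGG": {"TUM": 0.6, "INF": 0.3, "REA": 0.1},
    "HGG": {"TUM": 0.5, "INF": 0.25, "NEC": 0.15, "REA": 0.1},
    "MNG": {"TUM": 0.85, "REA": 0.15},
    "MET": {"TUM": 0.55, "INF": 0.2, "NEC": 0.15, "REA": 0.1},
}

_Z75 = 0.6744897501960817  # upper quartile of the standard normal


@dataclass(frozen=True)
class TwoPieceNormal:
    """Two-piece normal defined by its quartiles.

    The quantile function is piecewise linear in the standard-normal score z:
    Q(z) = median + (q75 - median) z / z75 for z >= 0 and
    Q(z) = median + (median - q25) (-z) / (-z75) for z < 0, so the three
    quartiles are matched exactly for any ordered triple, including the
    strongly asymmetric ones.
    """

    median: float
    s_minus: float
    s_plus: float

    def __post_init__(self) -> None:
        if self.s_minus < 0 or self.s_plus < 0:
            raise ValueError("quartile half-spreads must be nonnegative")

    @classmethod
    def from_quartiles(cls, q25: float, median: float, q75: float) -> "TwoPieceNormal":
        if not q25 <= median <= q75:
            raise ValueError(f"quartiles must be ordered, got ({q25}, {median}, {q75})")
        return cls(median=median, s_minus=median - q25, s_plus=q75 - median)

    @property
    def quartiles(self) -> tuple[float, float, float]:
        return self.median - self.s_minus, self.median, self.median + self.s_plus

    def transform(self, z: np.ndarray | float) -> np.ndarray | float:
        """Map standard-normal scores to values (monotone, quartile-exact)."""
        z = np.asarray(z, dtype=float)
        scale = np.where(z >= 0, self.s_plus, self.s_minus)
        return self.median + scale * z / _Z75


@dataclass(frozen=True)
class GroupPreset:
    """Everything needed to generate one group's data points.

    ``g_center``/``g_scale`` parameterize the glycolytic-index distribution
    for the photophysics mode; ``marginals`` hold the metric-space
    two-piece-normal marginals; ``coupling`` is the copula loading rho in
    [0, 1] of each metric on the shared latent score (noise weight is
    sqrt(1 - rho^2)); ``anchor_495`` is the group's relative spectral
    intensity at 495 nm used by the spectral calibration.
    """

    name: str
    n_points: int
    g_center: float
    g_scale: float
    marginals: dict[str, TwoPieceNormal]
    coupling: float
    anchor_495: float
    histo_props: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in GROUPS:
            raise ValueError(f"unknown group {self.name!r}")
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if not 0 <= self.g_center <= 1 or self.g_scale < 0:
            raise ValueError("g_center must be in [0, 1] and g_scale >= 0")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [0, 1]")
        missing = set(METRICS) - set(self.marginals)
        if missing:
            raise ValueError(f"missing marginals for {sorted(missing)}")


@dataclass(frozen=True)
class SampleRecord:
    """One data point of the cohort."""

    sample_id: str
    group: str
    histo_sublabel: str
    tau_ns: float
    redox_ratio: float
    r_flavin: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.histo_sublabel not in HISTO_SUBLABELS:
            raise ValueError(f"unknown histo sublabel {self.histo_sublabel!r}")
        if not (
            math.isfinite(self.tau_ns)
            and math.isfinite(self.redox_ratio)
            and math.isfinite(self.r_flavin)
        ):
            raise ValueError("metric values must be finite")
        if self.tau_ns <= 0:
            raise ValueError("lifetime must be positive")
        if not 0 <= self.redox_ratio <= 1:
            raise ValueError("redox ratio must lie in [0, 1]")
        if self.r_flavin <= 0:
            raise ValueError("R_flavin must be positive")


@dataclass(frozen=True)
class Cohort:
    """A generated cohort plus its provenance (seed, mode)."""

    records: tuple[SampleRecord, ...]
    seed: int
    mode: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "group": [r.group for r in self.records],
                "histo_sublabel": [r.histo_sublabel for r in self.records],
                "tau_ns": [r.tau_ns for r in self.records],
                "redox_ratio": [r.redox_ratio for r in self.records],
                "r_flavin": [r.r_flavin for r in self.records],
            }
        )

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.group] = counts.get(r.group, 0) + 1
        return counts


def sample_metabolic_state(
    preset: GroupPreset,
    rng: np.random.Generator,
    model: AbundanceModel | None = None,
) -> MetabolicState:
    """Draw one glycolytic index from the preset and map it to abundances."""
    g = float(np.clip(rng.normal(preset.g_center, preset.g_scale), 0.0, 1.0))
    from .photophysics import abundance_map

    return MetabolicState(g=g, abundances=abundance_map(g, model))


def sample_group_metrics(
    preset: GroupPreset,
    n: int,
    rng: np.random.Generator,
    f_mod: float = DEFAULT_F_MOD,
) -> pd.DataFrame:
    """Draw ``n`` metric triples from the calibrated group preset.

    A shared latent score z couples the metrics (Gaussian copula with
    loading ``preset.coupling``); each marginal is the quartile-exact
    two-piece normal.  Lifetimes are realized through the FD-FLIM phase
    estimator: the sampled apparent lifetime defines the sample's modulated
    response, from which the recorded lifetime is re-estimated.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rho = preset.coupling
    noise = math.sqrt(1.0 - rho**2)
    z = rng.standard_normal(n)
    out: dict[str, np.ndarray] = {}
    for metric in METRICS:
        eps = rng.standard_normal(n)
        score = METRIC_SIGNS[metric] * (rho * z + noise * eps)
        values = np.asarray(preset.marginals[metric].transform(score), dtype=float)
        if metric == "redox_ratio":
            values = np.clip(values, 1e-6, 1.0)
        elif metric == "tau_ns":
            values = np.clip(values, 0.05, None)
            values = np.array(
                [phase_lifetime(response_from_lifetime(t, f_mod=f_mod)) for t in values]
            )
        else:
            values = np.clip(values, 1e-6, None)
        out[metric] = values
    return pd.DataFrame(out)


def _draw_histo(group: str, props: dict[str, float], n: int, rng: np.random.Generator):
    if not props:
        props = _HISTO_PROPS[group]
    labels = list(props)
    p = np.array([props[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def _photophysics_metrics(
    preset: GroupPreset,
    n: int,
    rng: np.random.Generator,
    f_mod: float,
    abundance_jitter: float = 0.05,
) -> pd.DataFrame:
    components = default_components()
    bands = sp.BandDefinition()
    rows = []
    for _ in range(n):
        state = sample_metabolic_state(preset, rng)
        ab = {
            k: v * rng.lognormal(0.0, abundance_jitter)
            for k, v in state.abundances.items()
        }
        spectrum = emission_spectrum(components, ab)
        rows.append(
            {
                "tau_ns": flavin_lifetime_of_state(ab, components, f_mod=f_mod),
                "redox_ratio": sp.redox_ratio(spectrum, bands),
                "r_flavin": sp.r_flavin(spectrum, bands),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    presets: dict[str, GroupPreset],
    seed: int,
    mode: str = "metric_space",
    n_per_group: dict[str, int] | int | None = None,
    f_mod: float = DEFAULT_F_MOD,
) -> Cohort:
    """Generate a cohort with the preset group sizes (or an override).

    ``n_per_group`` may be an int (applied to every group) or a mapping; by
    default each group's preset count is used, yielding the 361-point
    16/71/117/64/93 design.
    """
    missing = set(GROUPS) - set(presets)
    if missing:
        raise ValueError(f"missing presets for groups {sorted(missing)}")
    if mode not in ("metric_space", "photophysics"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    for group in GROUPS:
        preset = presets[group]
        if n_per_group is None:
            n = preset.n_points
        elif isinstance(n_per_group, int):
            n = n_per_group
        else:
            n = n_per_group.get(group, preset.n_points)
        if mode == "metric_space":
            metrics = sample_group_metrics(preset, n, rng, f_mod=f_mod)
        else:
            metrics = _photophysics_metrics(preset, n, rng, f_mod=f_mod)
        histo = _draw_histo(group, preset.histo_props, n, rng)
        for i in range(n):
            records.append(
                SampleRecord(
                    sample_id=f"{group}-{i + 1:04d}",
                    group=group,
                    histo_sublabel=str(histo[i]),
                    tau_ns=float(metrics["tau_ns"].iloc[i]),
                    redox_ratio=float(metrics["redox_ratio"].iloc[i]),
                    r_flavin=float(metrics["r_flavin"].iloc[i]),
                )
            )
    return Cohort(records=tuple(records), seed=seed, mode=mode)


@dataclass(frozen=True)
class HotspotSpec:
    """Circular focal region of elevated lifetime within a FLIM image.

    ``fraction`` is the hotspot's share of the field-of-view area in [0, 1);
    ``center_mm`` defaults to a random position fully containing the circle.
    """

    fraction: float
    tau_ns: float
    center_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fraction < 1:
            raise ValueError("hotspot fraction must lie in [0, 1)")
        if self.tau_ns <= 0:
            raise ValueError("hotspot lifetime must be positive")


def generate_flim_image(
    tau_ns: float,
    rng: np.random.Generator,
    width_mm: float = 6.5,
    n_pixels: int = 64,
    hotspot: HotspotSpec | None = None,
    background_cv: float = 0.03,
    mean_intensity: float = 40.0,
) -> FLIMImage:
    """Synthesize a square FLIM image around a sample's flavin lifetime.

    Background pixels scatter around ``tau_ns`` with coefficient of
    variation ``background_cv``; an optional circular hotspot is set to its
    own elevated lifetime.  The paired intensity map is lognormal around
    ``mean_intensity`` (mV_RMS).
    """
    if n_pixels < 4:
        raise ValueError("n_pixels must be at least 4")
    if tau_ns <= 0:
        raise ValueError("background lifetime must be positive")
    pixel_size = width_mm / n_pixels
    lifetime = rng.normal(tau_ns, background_cv * tau_ns, size=(n_pixels, n_pixels))
    if hotspot is not None and hotspot.fraction > 0:
        radius = width_mm * math.sqrt(hotspot.fraction / math.pi)
        if 2 * radius > width_mm:
            raise ValueError("hotspot larger than the field of view")
        if hotspot.center_mm is None:
            cx = rng.uniform(radius, width_mm - radius)
            cy = rng.uniform(radius, width_mm - radius)
        else:
            cx, cy = hotspot.center_mm
            if cx - radius < 0 or cy - radius < 0 or cx + radius > width_mm or cy + radius > width_mm:
                raise ValueError("hotspot extends outside the field of view")
        px = (np.arange(n_pixels) + 0.5) * pixel_size
        dist2 = (px[None, :] - cx) ** 2 + (px[:, None] - cy) ** 2
        mask = dist2 <= radius**2
        lifetime[mask] = rng.normal(
            hotspot.tau_ns, background_cv * hotspot.tau_ns, size=int(mask.sum())
        )
    lifetime = np.clip(lifetime, 0.05, None)
    intensity = rng.lognormal(math.log(mean_intensity), 0.2, size=(n_pixels, n_pixels))
    return FLIMImage(lifetime_map=lifetime, intensity_map=intensity, pixel_size_mm=pixel_size)


_CSV_COLUMNS = ["sample_id", "group", "histo_sublabel", "tau_ns", "redox_ratio", "r_flavin"]


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.to_dataframe().to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and schema-validate a cohort table."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns {missing}")
    for col in ("tau_ns", "redox_ratio", "r_flavin"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            raise ValueError(f"non-numeric value in column {col!r} at row {int(bad[0])}")
        df[col] = values
    unknown = set(df["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels {sorted(unknown)} in cohort CSV")
    return df
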