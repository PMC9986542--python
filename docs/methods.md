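# Methods

This note documents the models, calibration procedures, numerical choices
and limitations behind `flavimetry`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Study design emulated

Five groups of ex-vivo measurements on brain tissue — non-tumorous control
(CTL), low-grade glioma (LGG), high-grade glioma (HGG), meningioma (MNG)
and metastasis (MET) — with 16 / 71 / 117 / 64 / 93 data points
respectively (361 total).  Each data point is one co-registered
measurement: an emission spectrum on a 430–740 nm grid (1 nm native step in
the simulator), a flavin-band (500–580 nm) frequency-domain lifetime, and
the three derived metrics (lifetime τ, optical redox ratio RR, R_flavin).
Imaging geometry: 6.5 × 6.5 mm² field of view, 0.6 × 0.6 mm² square regions
of interest.

## Spectral metrics

- `RR = FAD / (NAD(P)H + FAD)` with band integrals over 430–475 nm and
  520–600 nm.  Quadrature is the trapezoid rule on the native grid with
  band endpoints included by linear interpolation (the choice of quadrature
  is not physically constrained; trapezoid on a 1 nm grid is accurate to
  ≪0.1% against a dense Riemann oracle, which the suite asserts).
- `R_flavin = I495 / I530`.  Peak intensities are means over a ±2 nm window
  by default (robust to grid noise); a window of 0 reads the nearest grid
  sample.  Window width is a config knob because the spectrometer
  resolution underlying the printed peak values is not known.
- Group-average spectra are pointwise means on a common grid, all groups
  divided by the single global maximum across groups, so the brightest
  group reads 1.0 at its peak ("relative spectral intensity").
- Both metrics are invariant to a global intensity scale; the grid is
  validated but never resampled.

## Frequency-domain lifetime model

Mixtures of exponential decays sum linearly in phasor space:
`G = Σ wᵢ/(1+(ωτᵢ)²)`, `S = Σ wᵢωτᵢ/(1+(ωτᵢ)²)` with normalized intensity
weights and ω = 2πf.  The two standard single-frequency estimators are
`τ_φ = tan(atan2(S,G))/ω` and `τ_m = sqrt(1/(G²+S²) − 1)/ω`; they agree
exactly for mono-exponential decays and otherwise satisfy τ_φ ≤ τ_m (both
asserted).  The **phase lifetime is the reported flavin lifetime**
throughout; the modulation lifetime is diagnostic output.  The default
modulation frequency is 10 MHz (config-exposed): the instrument's actual
frequency and estimator are not public, and at 10 MHz every lifetime in the
calibrated range (≈1.3–6 ns) maps to a phase safely inside (0, π/2).

ROI statistics are intensity-weighted means of the lifetime map over the
pixels whose centers fall in the ROI square (half-open on the max edges;
origin top-left, x rightward, y downward, mm units).

## Fluorophore component library

| species | peaks (nm, FWHM nm, rel. amp.) | rel. quantum yield | lifetime components (ns, fraction) |
|---|---|---|---|
| free NAD(P)H | 462 / 60 / 1.0 | 1 | 0.4 (1.0) |
| bound NAD(P)H | 445 / 60 / 1.0 | 1 | 2.5 (1.0) |
| protein-bound FMN | 495 / 40 / 1.0 and 530 / 45 / 0.55 | 10 | 4.7 (1.0) |
| FAD | 530 / 45 / 1.0 | 1 | 0.3 (0.75), 2.5 (0.25) |

Emission shapes are Gaussians parameterized by FWHM.  Physically anchored
quantities: the three peak positions, the 10× FMN-to-FAD quantum-yield
ratio, FMN's long ~4.7 ns lifetime, FAD's dominant short ~0.3 ns component
and a free-FAD component inside the reported 2–3 ns range (2.5 ns chosen).
Peak widths, the 0.55 side-peak amplitude, and the 0.75/0.25 FAD fraction
split are model parameters without published values; they are exposed in
the component dataclasses.  Bound NAD(P)H is included for completeness of
the library but carries zero weight in the default abundance model, which
only needs the three species that drive the metrics.  Note a consequence of
overlapping Gaussians: the pure-FMN mixture mode sits 3–4 nm above 495 nm
because of the side peak's tail; the suite asserts the mode in [495, 500] nm.

A scalar glycolytic index g ∈ [0, 1] drives abundances affinely (floored at
zero): free NAD(P)H and bound FMN increase with g, FAD decreases.  On the
noiseless chain this makes RR strictly decreasing and R_flavin and τ
strictly increasing in g (asserted over a 101-point grid) — the qualitative
signature the whole analysis rests on.

## Calibration

Three deterministic fits, run once per process and cached:

1.  **Marginals.**  Each group × metric quartile triple (q25, median, q75)
    defines a *two-piece normal*: the quantile function is piecewise linear
    in the standard-normal score, `Q(z) = median + (q75−median)·z/z₀.₇₅` for
    z ≥ 0 and analogously below, matching any ordered triple exactly.  A
    skew-normal family was considered and rejected: its quartile-asymmetry
    ratio is bounded near 1.34 (half-normal limit), while the control
    group's R_flavin targets (0.85, 0.86, 0.97) require a ratio of 11.
2.  **Spectral anchors.**  Group centers g_k are placed affinely in the
    495 nm anchor values over [0.15, 0.85] (forward intensity at any
    wavelength is affine in g, so this placement is self-consistent), then
    the five free abundance coefficients are fit by bounded least squares so
    that noiseless forward spectra at the g_k, normalized to their global
    maximum, reproduce the 462/495/530 nm anchors (495 nm weighted 3×, as
    those are the quantitative targets; residuals at 495 nm are < 0.01,
    and the fit errors out if they exceed 0.02).
3.  **Latent coupling.**  In metric-space generation each sample draws a
    latent score z ~ N(0,1); metric m receives the score
    `sign_m·(ρz + √(1−ρ²)ε_m)` (RR loads negatively, R_flavin and τ
    positively) pushed through its marginal — a Gaussian copula that leaves
    the quartile match exact for every ρ.  The single loading ρ is tuned by
    Brent root finding on a large fixed-seed simulation (300× the cohort
    size) so the pooled Pearson correlation of R_flavin vs RR equals −0.87;
    the fitted ρ ≈ 0.89.  If the target fell outside the attainable range
    (ρ ∈ [0, 1]) calibration raises with the range in the error.

Sampled lifetimes are realized through the FD-FLIM estimator: the sampled
apparent lifetime defines the sample's modulated response, and the recorded
value is the phase lifetime re-estimated from that response (an exact round
trip, so the marginal calibration is preserved).  Redox ratios are clipped
to [0, 1] and lifetimes floored at 0.05 ns; at the calibrated scales the
clipping probability is negligible and quartiles are unaffected.

### Two generation modes

`metric_space` (default) is the quantitative mode used for all cohort-level
statistics.  `photophysics` draws g per sample (normal around the group
center, scale converted from the group's RR interquartile range through the
local dRR/dg slope, clipped to [0, 1], with 5% lognormal abundance jitter)
and runs the full forward chain: abundances → spectrum → band metrics →
phasor lifetime.  It is structurally faithful — correct monotone couplings,
correct spectral shapes, exact anchor reproduction at group centers — but
its absolute metric levels are only approximate, for a structural reason:
a single latent g orders the groups CTL < MET < HGG < LGG < MNG (the 495 nm
anchor order), which is consistent with the RR and R_flavin medians but not
with the lifetime medians of MET (2.41 ns) vs HGG (2.31 ns).  No
one-dimensional noiseless chain can reproduce all fifteen group medians
simultaneously; the per-metric marginal calibration in metric space is the
package's resolution.

### Within-group heterogeneity

One latent dimension per sample is an assumption; the within-group joint
structure beyond the pooled correlation is not constrained by published
values.  Histopathology sub-labels (TUM/INF/NEC/REA) are attached with
fixed per-group proportions purely for plotting parity and have no
generative meaning.  The 16 control points in the real design came from
3 specimens of 2 patients; within-patient correlation is not modeled.

## FLIM images

Synthetic per-specimen images (default 64 × 64 pixels over 6.5 mm, pixel
size = width/n exactly) scatter background lifetimes around the sample's τ
(3% coefficient of variation) with an optional circular hotspot of elevated
lifetime (e.g. a 3.61 ns focal region in a 1.33 ns control background,
recovered by ROI means in the suite); intensity maps are lognormal around
40 mV_RMS.  Files are two-page 32-bit float TIFFs (lifetime ns, intensity
mV_RMS) with the pixel size in the image description.

## Statistics

- Group summaries: median and quartiles by linear interpolation between
  order statistics (numpy default, type-7 style).  The quartile convention
  matters when comparing against printed tables; it is applied consistently
  in calibration and summaries.
- Tumor-vs-control inference: one-sided Mann-Whitney-U per metric
  (alternatives: lifetime greater, RR lower, R_flavin greater), exact null
  distribution for n₁+n₂ ≤ 12 without ties, otherwise normal approximation
  with tie and continuity correction.  Significance at p < 0.05; display
  stars at p < 0.005 (*) and p < 1e-5 (**).  No multiple-testing
  correction is applied, matching the emulated protocol.
- Subgroup shape check: two-sample Kolmogorov-Smirnov on per-subgroup
  z-scored values ("normalization" is not further specified in the source
  protocol; per-subgroup standardization is this package's reading, which
  makes the test a pure shape comparison).
- Regression: ordinary least squares of R_flavin on RR plus Pearson r.
- Type-I behavior of the one-sided battery is verified empirically over
  2,000 null simulations (empirical rate within a 3σ binomial band of
  α = 0.05).

## Classification protocol

Features: (τ, RR, R_flavin).  For each of 50 repeats, a fresh stratified
5-fold partition (80/20); within each of the 250 validations the training
fold is z-scored with its own statistics, minority classes are SMOTE-
oversampled to the majority size *in the scaled space*, the model is fit
and the untouched validation fold predicted.  SMOTE synthesizes
`x + u·(x_nn − x)` with u ~ U(0,1) and x_nn one of k = 5 (capped at class
size − 1) within-class nearest neighbors; it is implemented in-package and
synthetic rows never leave their training fold (leak checks by index
tracking are part of the suite).  Model zoo: LDA, logistic regression,
k-NN, support-vector classifier (RBF, C = 1, gamma = 'scale' — the
reporting default), gradient boosting, random forest, extra trees; ranked
by macro-averaged F-score over pooled predictions (macro to respect
minority classes).  Confusion counts are aggregated over all validations
(50 × 361 = 18,050 predictions) with one-vs-rest sensitivity and
specificity per class in percent; class display order CTL, LGG, HGG, MNG,
MET.  One master seed drives per-repeat fold and SMOTE sub-seeds, making
the whole protocol deterministic.

The protocol cross-validates over data points, not patients or specimens,
mirroring the emulated study; a per-specimen grouping is a known stricter
alternative but the synthetic generator does not model specimen identity.

## Problem sizes and numerical choices

Oversized calibration-verification draws use n = 10,000 per group; the
coupling fit simulates 300 cohort replicates; seed-replicate averages use
10 cohorts.  The classification protocol always runs at full size (250
fits, seconds for the SVC); the zoo ranking is run at reduced repeat counts
in tests since its purpose there is interface and determinism checking.
Ties in the marginal transform cannot occur (continuous scores); ties in
rank tests are handled by the tie-corrected asymptotic path.  Degenerate
inputs (empty groups, zero-variance subgroups, zero band intensity,
non-physical phases, singleton SMOTE classes) raise `ValueError` with a
specific message rather than propagating NaNs.

## What passing tests do and do not show

The generator reproduces the *published summary structure* — group sizes,
quartiles, spectral anchors, pooled correlation — and the analysis stack
recovers these from its own output.  That validates the pipeline's
internal consistency and the direction/magnitude of group separations, not
the real tissue data: real spectra contain hemoglobin absorption,
scattering, photobleaching and ex-vivo drift (all out of scope here), real
within-group distributions need not be two-piece normal, and real
classification difficulty may exceed the synthetic one if within-specimen
correlation inflates effective separability.  Classification results on
the synthetic cohort should therefore be read as "at least as separable as
the published quartile spreads imply", which is also how the acceptance
bound on the control-class sensitivity is framed.
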