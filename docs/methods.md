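# Methods

This note documents the models, numerical choices and limitations of
`bgmrsi`. The package implements the full analysis chain of a single-slab
proton MRSI study of the basal ganglia in older adults — acquisition
geometry 24 × 24 phase encodes over a 240 mm field of view (10 mm in-plane
voxels), a 10 mm slab, 512 complex points at 1 ms dwell, TR/TE =
1000/145 ms at 1.5 T — together with a synthetic cohort generator that
replaces scanner data with phantoms of known ground truth.

## Frequency and lineshape conventions

FIDs are stored in the transmitter frame with the carrier on water
(4.70 ppm); a resonance at chemical shift `p` appears at
`f = (4.70 − p) · f0` Hz with `f0 = 63.87` MHz (γB0 at 1.5 T). Lineshapes
are Gaussian in the time domain, `exp(−β t²)`, with
`β = (π · FWHM)² / (4 ln 2)`; the conversion is verified by a round-trip
test. Nominal shifts are Cho 3.20, Cre 3.03, NAA 2.02 ppm and a lactate
doublet centred at 1.31 ppm with a 7.3 Hz splitting, inverted (phase π) at
TE = 145 ms ≈ 1/J.

## Synthetic cohort generator

Each subject is an elderly-brain-like axial slab built at 1 mm in-plane
resolution on three contiguous slices (3.33 mm each, honouring the
three-slice tissue overlay): an elliptical brain with subject-randomised
axes/rotation/centre, a thin sulcal-CSF rim (atrophy), a cortical GM
ribbon, central CSF ventricles, paired deep-GM nuclei, WM elsewhere.
Crisp labels are smoothed in-plane (σ = 2 mm) into probability maps; the
smoothing preserves the partition of unity, so GM+WM+CSF+BGND sums to one
everywhere.

Per-voxel metabolite amplitudes follow
`a = c_voxel · n_protons · exp(−TE/T2) · (1 − exp(−TR/T1))` with
`c_voxel = f_gm·C_GM + f_wm·C_WM` (CSF and background carry no metabolite
signal), so downstream relaxation correction and proton normalisation
exactly invert the simulation. The shipped `LBC1936` concentration preset
encodes the pure-tissue levels of the study population: NAA 70/76,
Cho 10/13, Cre 57/44 IU (GM/WM); lactate defaults to a near-zero 0.5 IU
while the model retains its inverted doublet. The T1/T2 preset
(`basal_ganglia_elderly_1p5T`: NAA 1450/390, Cho 1150/330, Cre 1550/210,
Lac 1550/240 ms) is the single source of truth for both simulation and
quantification; the study it emulates used literature values that were
not printed, so the preset is user-overridable.

Realism terms, all defaults chosen once as study conditions:

- **Residual water**: a Gaussian line at 4.70 ppm + local B0 offset,
  amplitude `0.05 × 70000 ×` voxel water volume — i.e. unsuppressed water
  ≈ 1000× the NAA amplitude and a ~50× residual after CHESS-like
  suppression, in line with in vivo suppression factors.
- **Eddy currents / phase**: 1–2 exponentially decaying phase terms
  (0.2–0.8 rad, τ = 30–120 ms) plus a random zero-order phase, applied
  multiplicatively to water and metabolites alike — exactly the assumption
  under which water-referenced (Klose-style) correction is valid.
- **B0 and linewidth maps**: smooth Gaussian random fields, B0 σ ≈ 1.5 Hz
  plus a subject offset; linewidths 4.5 Hz baseline plus subject and
  spatial terms (typically 4–9 Hz, occasionally beyond the 10 Hz QC
  bound). Both carry a scale knob used by the yield-vs-shim experiment.
- **Noise**: complex white noise, SD 1.5 per time point, giving ~2–5 %
  amplitude CV on fitted peaks — a deliberately benign long-TE 1.5 T
  condition.
- **Subject effects**: one additive concentration shift per metabolite per
  subject (SD 3 % of the mean level), shifting GM and WM alike — the
  random intercept of the downstream mixed model. Effects are drawn with a
  fixed correlation structure (Cho–Cre +0.55, Cre–NAA −0.32), and the
  covariate table couples fluid intelligence to creatine (ρ = 0.33),
  memory to NAA (0.27) and WM-lesion score to choline (0.24). At ten
  subjects the realised sample correlations scatter widely; they are
  reported, not asserted.

What the phantom does **not** emulate: scalp lipid rings, chemical-shift
displacement of the PRESS box, coil sensitivities, macromolecule baseline,
frequency drift, and motion. Passing tests therefore demonstrate
correctness of the analysis chain under its own forward model, not
robustness to every artefact of real spectra.

## Reconstruction

k-space is apodised with the separable cosine window
`w(k) = cos(πk / (2(N/2+1)))`, `k = index − N/2` (DC at index 12): centre
weight exactly 1, outermost weight > 0 on an even grid. Reconstruction is
a centred orthonormal inverse 2D FFT per time point; the phantom applies
the exact inverse, so the no-apodisation round trip is exact to floating
point and energy is conserved. The PRESS excitation box is a configured
voxel-index rectangle; its one-voxel boundary ring ("edge") is excluded
from analysis, and the attrition denominator counts only fully interior
voxels (the count including the ring is reported alongside, since either
convention appears in practice).

## Water referencing and removal

The residual water line is located within ±0.4 ppm of 4.70 ppm (parabolic
peak interpolation), isolated by a Gaussian band-pass (σ = 12.5 Hz,
"±25 Hz"; choline, ≈96 Hz away at 1.5 T, is attenuated by e⁻²⁰), and its
instantaneous phase is unwrapped and frozen once the envelope falls below
2 % of its maximum. One refinement pass (demodulate, re-filter) removes
most of the convolution edge bias near t = 0. The correction
`s·exp(−i·track)·exp(−2πi·δf·t)` is magnitude-preserving; afterwards the
first corrected sample should be real-positive, and its residual angle is
rotated away as a final zero-order touch-up. If no water line exceeds 3×
the median spectral magnitude, the voxel falls back to zero-order phasing
by the angle of the first FID sample (exact at t = 0 for in-phase
models), with a 0.01 rad dead-band so that already-phased data are left
untouched — this makes the full preprocess idempotent.

HLSVD: Hankel matrix of the full FID (256 × 257), truncated SVD (rank 16
by default, fixed Lanczos start vector for bitwise reproducibility),
poles from the shift invariance of the left singular subspace, amplitudes
by envelope-weighted linear least squares (the weighting keeps the model
accurate at the earliest samples, whose mismatch would otherwise leak a
broad baseline). Components within ±30 Hz of water are subtracted, with
dampings clipped at ≥ 0 so Lorentzian approximants of the Gaussian line
cannot diverge. Water-region suppression is quantified on the absorption
(real-part) area over 4.4–5.0 ppm: a magnitude integral is dominated by
the causal-FID dispersion baseline of the metabolites themselves and
would understate the removal.

## Spectral fitting

Constrained nonlinear least squares in the time domain (stacked
real/imaginary residuals), the AMARES formulation: amplitudes ≥ 0,
phases fixed by prior knowledge (0 or π), frequencies within ±0.15 ppm of
nominal, linewidths free in 0.5–15 Hz (deliberately wider than the 1–10 Hz
QC window, so rejection is the QC stage's job, not the optimiser's). The
lactate doublet shares one amplitude (split equally), centre and
linewidth. Each peak's linewidth is free — no inter-peak coupling — a
deliberate choice documented here. No baseline term: at TE = 145 ms the
macromolecule background is largely decayed, and the phantom contains
none; this is the model's main simplification against short-TE data.

Initialisation is deterministic: non-negative linear least squares for
amplitudes at nominal positions, multistart over frequency offsets
{0, ±0.05 ppm}, analytic Jacobian, early exit once a start reaches the
noise-floor cost estimated from the FID tail. A brute-force (frequency ×
linewidth) grid search with closed-form amplitudes serves as an
independent oracle in the tests.

## Quality control

Stages in fixed order, each voxel charged to its first failure:
BGND (brain < 95 %), CSF (> 20 %), NAA (fit failed: non-convergence,
FWHM outside [1, 10] Hz, or |offset| > 0.1 ppm), Vis, ChoCre (same
spectral rules for choline/creatine). All comparisons are strict in the
rejecting direction, so boundary values (CSF = 20.0 %, FWHM = 1.0 or
10.0 Hz, offset = 0.1 ppm) are retained. `n_valid_naa` counts voxels
surviving the NAA stage; Vis and ChoCre then reduce it to `n_valid_all`.
Subjects with fewer than five all-valid voxels are excluded from
subject-level analyses.

The human visual check is replaced by a deterministic proxy (disable-able
in config): reject if the median real *residual* spectrum (data minus
fitted model) over 1–4 ppm exceeds 3× the noise SD estimated from the
signal-free 6–10 ppm region (elevated baseline), or if any residual
excursion outside ±0.15 ppm of the fitted peaks exceeds 0.5× the tallest
fitted peak (spurious resonance). Using the residual rather than the raw
spectrum matters: every causal FID carries a constant spectral offset
that the peak model itself reproduces and that must not be penalised.

## Quantification

`IU = scale · area / (F · n_protons)` with
`F = exp(−TE/T2)(1 − exp(−TR/T1))`, n = 3 (NAA, Cre), 9 (Cho); the global
scale (default 1) is arbitrary, which is what "institutional" means.
Relaxation values are applied per metabolite (a tissue-global switch would
be a one-line preset change). Absolute water-referenced quantification is
intentionally not implemented — the emulated protocol had no unsuppressed
reference acquisition and relied on self-referencing. Both IU-based and
raw-area metabolite ratios are computed per voxel; their algebraic
consistency identity (area ratio × relaxation factors × proton counts) is
property-tested.

## Tissue overlay and the partial-volume regression

Tissue fractions average the probability maps over each voxel footprint
across the three slices. Two footprints are available: the nominal 10 mm
cube, and (default) the apodisation point-spread-weighted footprint,
computed by circularly convolving the fraction grids with the real,
unit-sum PSF of the cosine window — circular convolution is the exact
forward operator for phase-encoded MRSI. The PSF-weighted variant keeps
the regressor consistent with what the reconstructed signal actually
measures; with the nominal cube the regression slope acquires a
metabolite-dependent bias (attenuation of the contrast field ≈ 0.8 plus
an omitted-variable term from PSF-induced signal deficit) large enough to
shift the extrapolated GM creatine by ~9 %.

The tissue contrast is `x = (%WM − %GM)/(%WM + %GM)` so that pure tissue
sits at x = ±1 regardless of CSF partial volume; the raw difference
(%WM − %GM) is also emitted for sensitivity analyses. For the same
reason the model response is the parenchyma-referred level
`IU / ((f_gm+f_wm)/100)` — CSF and background contribute no metabolite
signal, and without this normalisation the extrapolation inherits a
CSF-dilution bias. Raw IU levels are kept in the long table. Per-voxel
ratios are unaffected (the volume factor cancels).

## Cohort model

`y_ij = β0 + β1 x_ij + u_i + ε_ij` with a subject random intercept,
fitted by REML (statsmodels MixedLM); Wald p-value on β1; pure-tissue
estimates `β0 ± β1`. Degenerate cases are handled explicitly: a perfect
linear fit (noiseless fixtures) returns the exact OLS solution with zero
variances, and a REML boundary solution with zero subject variance (rare
with few groups, where the profiled intercept can be lost) falls back to
pooled OLS, which is then the maximum-likelihood answer. A fixed-effects
ANOVA variant (subject as a sum-coded factor) is available via
`stats_method="anova"`. Ratios are modelled per voxel exactly like
levels; because a quotient is convex in x, ratio extrapolations need not
equal quotients of level extrapolations, and both are reported. No
multiple-testing correction is applied, matching the emulated analysis.
Pearson correlations across subjects use the t-transform with n−2 degrees
of freedom.

## Problem sizes and determinism

The packaged study runs 10 subjects × ~120 PRESS-interior voxels
(~1200 fits) in under a minute on one CPU; unit tests use single voxels
or single subjects. Everything is deterministic given the cohort seed:
per-voxel noise streams are derived from (subject seed, voxel index),
fitting has no randomness, and the Lanczos start vector is fixed, so
reprocessing a cohort is byte-identical.

## Known limitations

- Gaussian-only lineshapes; no Voigt/Lorentzian mixing, no B0-induced
  asymmetry within a voxel.
- No macromolecule/lipid components and no baseline term in the fit.
- The visual-QC proxy is a two-rule heuristic, not a model of human
  judgement; its thresholds are config values.
- Mixed-model extrapolation to x = ±1 is a linear idealisation; for
  ratios it is a genuinely different estimand than the ratio of level
  estimates (documented above, deliberately).
- The eddy-phase track is frozen once the water envelope decays, leaving
  a small late-time phase error (sub-1 % effect on fitted amplitudes at
  default conditions).
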