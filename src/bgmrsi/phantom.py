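"""Synthetic single-slab MRSI brain phantoms with known ground truth.

Each phantom subject is an elderly-brain-like axial slab at the level of
the deep grey nuclei: an elliptical brain with a thin rim of sulcal CSF
(atrophy), a cortical GM ribbon, central CSF ventricles, paired deep-GM
nuclei, and WM elsewhere.  Tissue probability maps are built at 1 mm
in-plane resolution on three contiguous slices spanning the 10 mm slab.

The forward signal model per spectroscopic voxel is a sum of
Gaussian-damped resonances

    s(t) = exp(i(phi0 + phi_e(t))) *
           [ sum_k a_k exp(i phi_k) exp(2 pi i f_k t - beta_k t^2)
             + water(t) ] + noise(t)

with metabolite amplitudes

    a_k = c_voxel(k) * n_protons(k) * exp(-TE/T2_k) * (1 - exp(-TR/T1_k))

so that relaxation correction and proton normalisation downstream exactly
invert the simulation.  ``c_voxel`` is the GM/WM-weighted concentration of
the voxel (CSF and background contribute no metabolite signal).  Lactate
appears as an inverted doublet (phase pi) with equal component amplitudes.
The eddy-current phase ``phi_e`` and the zero-order phase ``phi0`` multiply
water and metabolites alike, which is precisely the assumption under which
water-referenced phase correction is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .lineshape import gaussian_peak
from .params import AcquisitionParams
from .presets import (
    LACTATE_DOUBLET_HZ,
    NOMINAL_PPM,
    N_PROTONS,
    RelaxationParams,
    get_concentrations,
    get_relaxation,
)
from .tissue import TissueFractions, voxel_fractions

#: correlation structure of per-subject (NAA, Cho, Cre) concentration
#: effects: choline-creatine strongly positive, creatine-NAA weakly negative
SUBJECT_EFFECT_CORR = np.array(
    [
        [1.00, 0.00, -0.32],
        [0.00, 1.00, 0.55],
        [-0.32, 0.55, 1.00],
    ]
)
SUBJECT_EFFECT_ORDER = ("NAA", "Cho", "Cre")

#: covariate couplings to subject metabolite effects (covariate, metabolite, r)
COVARIATE_COUPLINGS = (
    ("fluid_g", "Cre", 0.33),
    ("memory_g", "NAA", 0.27),
    ("wml_score", "Cho", 0.24),
    ("atrophy_score", None, 0.0),
    ("iron_score", None, 0.0),
)


@dataclass
class PhantomSpec:
    """Ground truth for one synthetic subject."""

    subject_id: str
    gm: np.ndarray          # (fov, fov, 3) probability at 1 mm
    wm: np.ndarray
    csf: np.ndarray
    mask: np.ndarray        # boolean brain mask, same shape
    concentrations: dict[str, tuple[float, float]]  # metabolite -> (GM, WM) IU
    relaxation: dict[str, RelaxationParams]
    b0_map: np.ndarray      # (nx, ny) Hz
    linewidth_map: np.ndarray  # (nx, ny) Gaussian FWHM, Hz
    eddy_terms: Sequence[tuple[float, float]] = ()  # (amplitude rad, tau s)
    zero_phase: float = 0.0
    water_residual_scale: float = 0.05
    #: unsuppressed water amplitude per unit brain volume; ~1000x the NAA
    #: time-domain amplitude, so the 5 % residual is ~50x the metabolites,
    #: as typical for CHESS-suppressed in vivo spectra
    water_amp0: float = 70000.0
    noise_sd: float = 1.5
    seed: int = 0
    subject_effects: dict[str, float] = field(default_factory=dict)
    hr_res_mm: float = 1.0
    _fractions: TissueFractions | None = field(default=None, repr=False)

    def fractions(self, params: AcquisitionParams) -> TissueFractions:
        """Tissue fractions of this subject on the MRSI grid (cached)."""
        if self._fractions is None:
            self._fractions = voxel_fractions(
                self.gm, self.wm, self.csf, params, self.hr_res_mm
            )
        return self._fractions

    def eddy_phase(self, t: np.ndarray) -> np.ndarray:
        """Time-varying eddy-current phase (radians)."""
        phi = np.zeros_like(t)
        for amp, tau in self.eddy_terms:
            phi += amp * np.exp(-t / tau)
        return phi


@dataclass
class MRSIAcquisition:
    """k-space spectroscopic acquisition plus its parameters."""

    params: AcquisitionParams
    kspace: np.ndarray  # complex, (kx, ky, t)
    truth: PhantomSpec | None = None

    def __post_init__(self) -> None:
        want = (self.params.n_phase_x, self.params.n_phase_y, self.params.n_points)
        if self.kspace.shape != want:
            raise ValueError(f"kspace shape {self.kspace.shape} != {want}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipse_r(x, y, cx, cy, ax, ay, theta):
    xr = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    yr = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    return np.sqrt((xr / ax) ** 2 + (yr / ay) ** 2)


def _subject_geometry(rng: np.random.Generator, fov_mm: float, hr_res_mm: float):
    """Crisp label volumes -> smoothed probability maps for one subject."""
    n = int(round(fov_mm / hr_res_mm))
    coords = (np.arange(n) + 0.5) * hr_res_mm - fov_mm / 2.0
    x, y = np.meshgrid(coords, coords, indexing="ij")

    a = 95.0 * (1 + 0.04 * rng.uniform(-1, 1))
    b = 85.0 * (1 + 0.04 * rng.uniform(-1, 1))
    theta = rng.uniform(-0.12, 0.12)
    cx, cy = rng.uniform(-3, 3, size=2)

    vent_dx = 17.0 * (1 + 0.1 * rng.uniform(-1, 1))
    vent_ax = 9.0 * (1 + 0.15 * rng.uniform(-1, 1))
    vent_ay = 24.0 * (1 + 0.15 * rng.uniform(-1, 1))
    nuc_dx = 33.0 * (1 + 0.08 * rng.uniform(-1, 1))
    nuc_ax = 13.0 * (1 + 0.1 * rng.uniform(-1, 1))
    nuc_ay = 19.0 * (1 + 0.1 * rng.uniform(-1, 1))

    gm = np.zeros((n, n, 3))
    wm = np.zeros((n, n, 3))
    csf = np.zeros((n, n, 3))

    for s in range(3):
        shrink = 1.0 - 0.02 * abs(s - 1)  # mild through-slab curvature
        r = _ellipse_r(x, y, cx, cy, a * shrink, b * shrink, theta)
        brain = r <= 1.0
        rim_csf = brain & (r > 0.95)
        cortex = brain & (r > 0.80) & ~rim_csf
        interior = brain & (r <= 0.80)

        vent = np.zeros_like(brain)
        nuc = np.zeros_like(brain)
        for sign in (-1.0, 1.0):
            vent |= (
                _ellipse_r(x, y, cx + sign * vent_dx, cy + 6.0, vent_ax, vent_ay,
                           sign * 0.2) <= 1.0
            )
            nuc |= (
                _ellipse_r(x, y, cx + sign * nuc_dx, cy - 2.0, nuc_ax, nuc_ay,
                           sign * 0.1) <= 1.0
            )

        lab_csf = rim_csf | (vent & interior)
        lab_gm = (cortex | (nuc & interior)) & ~lab_csf
        lab_wm = brain & ~lab_csf & ~lab_gm
        gm[:, :, s] = lab_gm
        wm[:, :, s] = lab_wm
        csf[:, :, s] = lab_csf

    # partial volume: in-plane smoothing preserves the partition of unity
    sigma = 2.0 / hr_res_mm
    gm, wm, csf = (gaussian_filter(m, (sigma, sigma, 0)) for m in (gm, wm, csf))
    brain_p = gm + wm + csf
    mask = brain_p > 0.5
    gm, wm, csf = (np.where(mask, m, 0.0) for m in (gm, wm, csf))
    return gm, wm, csf, mask


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape, sigma_vox=2.0):
    f = gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def make_default_phantom(
    seed: int,
    n_subjects: int,
    params: AcquisitionParams | None = None,
    concentration_preset: str = "LBC1936",
    relaxation_preset: str = "basal_ganglia_elderly_1p5T",
    noise_sd: float = 1.5,
    water_residual_scale: float = 0.05,
    b0_scale: float = 1.0,
    lw_scale: float = 1.0,
    subject_sd_frac: float = 0.03,
) -> list[PhantomSpec]:
    """Generate a cohort of phantom subjects with known ground truth.

    ``subject_sd_frac`` sets the SD of the per-subject additive
    concentration effect as a fraction of each metabolite's mean level;
    the same effect shifts GM and WM alike, so it acts as the subject
    random intercept of the downstream mixed model.  Deterministic given
    ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params or AcquisitionParams()
    base_conc = get_concentrations(concentration_preset)
    relax = get_relaxation(relaxation_preset)
    chol = np.linalg.cholesky(SUBJECT_EFFECT_CORR)

    grid_shape = (params.n_phase_x, params.n_phase_y)
    specs = []
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        gm, wm, csf, mask = _subject_geometry(rng, params.fov_mm, 1.0)

        z = chol @ rng.standard_normal(3)
        conc = {m: tuple(v) for m, v in base_conc.items()}
        effects = {}
        for m, zi in zip(SUBJECT_EFFECT_ORDER, z):
            g, w = base_conc[m]
            sd = subject_sd_frac * 0.5 * (g + w)
            effects[m] = float(zi)
            conc[m] = (max(g + sd * zi, 0.0), max(w + sd * zi, 0.0))

        b0 = b0_scale * (
            1.5 * _smooth_field(rng, grid_shape) + rng.normal(0.0, 0.8)
        )
        lw = lw_scale * np.clip(
            4.5
            + rng.normal(0.0, 0.8)
            + 2.2 * np.abs(_smooth_field(rng, grid_shape)),
            2.0,
            None,
        )

        n_eddy = rng.integers(1, 3)
        eddy = tuple(
            (float(rng.uniform(0.2, 0.8)), float(rng.uniform(0.03, 0.12)))
            for _ in range(n_eddy)
        )

        specs.append(
            PhantomSpec(
                subject_id=f"sub{i:02d}",
                gm=gm, wm=wm, csf=csf, mask=mask,
                concentrations=conc,
                relaxation=relax,
                b0_map=b0,
                linewidth_map=lw,
                eddy_terms=eddy,
                zero_phase=float(rng.uniform(-np.pi, np.pi)),
                water_residual_scale=water_residual_scale,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_effects=effects,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def relaxation_weight(relax: RelaxationParams, params: AcquisitionParams) -> float:
    """Signal attenuation exp(-TE/T2) * (1 - exp(-TR/T1))."""
    return float(
        np.exp(-params.te_ms / relax.t2_ms)
        * (1.0 - np.exp(-params.tr_ms / relax.t1_ms))
    )


def metabolite_components(
    spec: PhantomSpec, params: AcquisitionParams, voxel: tuple[int, int]
):
    """(amplitude, freq Hz, fwhm Hz, phase) of every resonance in a voxel."""
    ix, iy = voxel
    fr = spec.fractions(params)
    f_gm = fr.f_gm[ix, iy] / 100.0
    f_wm = fr.f_wm[ix, iy] / 100.0
    b0 = spec.b0_map[ix, iy]
    fwhm = spec.linewidth_map[ix, iy]

    comps = []
    for m, (c_gm, c_wm) in spec.concentrations.items():
        c_vox = f_gm * c_gm + f_wm * c_wm
        amp = c_vox * N_PROTONS[m] * relaxation_weight(spec.relaxation[m], params)
        f_hz = params.hz_of_ppm(NOMINAL_PPM[m]) + b0
        if m == "Lac":
            for df in (-LACTATE_DOUBLET_HZ / 2, LACTATE_DOUBLET_HZ / 2):
                comps.append((amp / 2.0, f_hz + df, fwhm, np.pi))
        else:
            comps.append((amp, f_hz, fwhm, 0.0))
    return comps


def water_component(
    spec: PhantomSpec, params: AcquisitionParams, voxel: tuple[int, int]
):
    """(amplitude, freq Hz, fwhm Hz, phase) of the residual water line."""
    ix, iy = voxel
    fr = spec.fractions(params)
    vol = (fr.f_gm[ix, iy] + fr.f_wm[ix, iy] + fr.f_csf[ix, iy]) / 100.0
    amp = spec.water_amp0 * spec.water_residual_scale * vol
    return (amp, spec.b0_map[ix, iy], spec.linewidth_map[ix, iy] * 1.15, 0.0)


def simulate_voxel_fid(
    spec: PhantomSpec,
    params: AcquisitionParams,
    voxel: tuple[int, int],
    include_noise: bool = True,
) -> np.ndarray:
    """Forward-model the complex FID of one spectroscopic voxel."""
    ix, iy = voxel
    if not (0 <= ix < params.n_phase_x and 0 <= iy < params.n_phase_y):
        raise IndexError(f"voxel {voxel} outside the phase-encode grid")
    t = params.time_axis()
    s = np.zeros(params.n_points, dtype=complex)
    for amp, f_hz, fwhm, phase in metabolite_components(spec, params, voxel):
        s += gaussian_peak(t, amp, f_hz, fwhm, phase)
    w_amp, w_f, w_fwhm, w_ph = water_component(spec, params, voxel)
    s += gaussian_peak(t, w_amp, w_f, w_fwhm, w_ph)
    s *= np.exp(1j * (spec.zero_phase + spec.eddy_phase(t)))
    if include_noise and spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 101, ix, iy])
        s += spec.noise_sd * (
            rng.standard_normal(params.n_points)
            + 1j * rng.standard_normal(params.n_points)
        )
    return s


def simulate_acquisition(
    spec: PhantomSpec,
    params: AcquisitionParams | None = None,
    include_noise: bool = True,
) -> MRSIAcquisition:
    """Simulate the full k-space acquisition of one subject.

    The voxel-space signal grid is transformed to k-space with the inverse
    of the reconstruction operator (orthonormal centred 2D FFT), so that
    reconstructing without apodisation recovers the voxel FIDs to floating
    point accuracy.
    """
    params = params or AcquisitionParams()
    grid = np.zeros(
        (params.n_phase_x, params.n_phase_y, params.n_points), dtype=complex
    )
    for ix in range(params.n_phase_x):
        for iy in range(params.n_phase_y):
            grid[ix, iy] = simulate_voxel_fid(spec, params, (ix, iy), include_noise)
    k = np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(grid, axes=(0, 1)), axes=(0, 1), norm="ortho"),
        axes=(0, 1),
    )
    return MRSIAcquisition(params=params, kspace=k, truth=spec)


# ---------------------------------------------------------------------------
# cohort covariates
# ---------------------------------------------------------------------------

def make_covariates(specs: list[PhantomSpec], seed: int):
    """Subject covariate table with configured couplings to ground truth.

    Cognitive scores are standardised; radiological scores are small
    non-negative integers.  Couplings are population correlations; at
    cohort sizes of tens the realised sample correlations scatter widely.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 202])
    rows = []
    for spec in specs:
        row = {"subject_id": spec.subject_id}
        for cov, met, r in COVARIATE_COUPLINGS:
            z = spec.subject_effects.get(met, 0.0) if met else 0.0
            val = r * z + np.sqrt(max(1 - r**2, 0.0)) * rng.standard_normal()
            if cov.endswith("_score"):
                val = int(np.clip(np.round(1.5 + val), 0, 4))
            row[cov] = val
        rows.append(row)
    return pd.DataFrame(rows)
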