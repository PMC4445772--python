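"""Tissue-fraction overlay of segmentation maps on the MRSI grid.

High-resolution GM/WM/CSF probability maps (three contiguous slices
spanning the 10 mm slab) are averaged over each 10 mm spectroscopic-voxel
footprint.  Samples outside the brain mask carry zero tissue probability
and therefore accumulate into the background (BGND) fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AcquisitionParams


@dataclass
class TissueFractions:
    """Per-spectroscopy-voxel tissue percentages on the phase-encode grid.

    Each field is an ``(n_phase_x, n_phase_y)`` array in percent; the four
    fields sum to 100 at every voxel.
    """

    f_gm: np.ndarray
    f_wm: np.ndarray
    f_csf: np.ndarray
    f_bgnd: np.ndarray

    def __post_init__(self) -> None:
        total = self.f_gm + self.f_wm + self.f_csf + self.f_bgnd
        if not np.allclose(total, 100.0, atol=1e-6):
            raise ValueError("tissue fractions must sum to 100 % per voxel")


def voxel_fractions(
    gm: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    params: AcquisitionParams,
    hr_res_mm: float = 1.0,
) -> TissueFractions:
    """Average high-resolution probability maps over voxel footprints.

    Parameters
    ----------
    gm, wm, csf
        ``(fov/hr_res, fov/hr_res, n_slices)`` probability volumes,
        co-registered to the MRSI grid (index 0 at the grid corner),
        zero outside the brain mask.
    params
        Acquisition geometry; the voxel footprint is the nominal
        ``voxel_mm`` square through all slices of the slab.
    """
    maps = [np.asarray(m, dtype=float) for m in (gm, wm, csf)]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("tissue maps must share one shape")
    block = int(round(params.voxel_mm / hr_res_mm))
    want = (params.n_phase_x * block, params.n_phase_y * block)
    if shape[:2] != want:
        raise ValueError(
            f"tissue map in-plane shape {shape[:2]} does not cover the "
            f"{params.n_phase_x} x {params.n_phase_y} grid at "
            f"{hr_res_mm} mm (expected {want})"
        )

    def pool(m: np.ndarray) -> np.ndarray:
        m3 = m.reshape(params.n_phase_x, block, params.n_phase_y, block, -1)
        return m3.mean(axis=(1, 3, 4))

    f_gm, f_wm, f_csf = (100.0 * pool(m) for m in maps)
    f_bgnd = 100.0 - (f_gm + f_wm + f_csf)
    return TissueFractions(f_gm, f_wm, f_csf, f_bgnd)


def psf_weight_fractions(
    fr: TissueFractions, params: AcquisitionParams
) -> TissueFractions:
    """Tissue fractions of the *effective* (apodised) voxel profile.

    The reconstructed signal of a phase-encoded voxel is the circular
    convolution of the true voxel-space signal with the apodisation
    point-spread function, so a metabolite amplitude measures the
    PSF-weighted tissue composition, not the nominal 10 mm cube.  This
    applies the same (real, unit-sum) PSF to the fraction grids, keeping
    regressor and signal consistent for the partial-volume regression.
    Tiny negative values from PSF side-lobes are clipped and the voxel
    renormalised to 100 %.
    """
    from .recon import cosine_window  # local import to avoid a cycle

    wx = cosine_window(params.n_phase_x)
    wy = cosine_window(params.n_phase_y)
    W = wx[:, None] * wy[None, :]

    def smear(img: np.ndarray) -> np.ndarray:
        k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
        return np.real(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k * W))))

    gm, wm, csf = (np.clip(smear(m), 0.0, None)
                   for m in (fr.f_gm, fr.f_wm, fr.f_csf))
    bgnd = np.clip(smear(fr.f_bgnd), 0.0, None)
    total = gm + wm + csf + bgnd
    scale = np.where(total > 0, 100.0 / total, 0.0)
    return TissueFractions(gm * scale, wm * scale, csf * scale, bgnd * scale)


def tissue_contrast(fr: TissueFractions) -> np.ndarray:
    """Normalised WM-GM contrast x = (%WM - %GM) / (%WM + %GM).

    +1 is pure white matter, -1 pure grey matter; normalising by the brain
    parenchyma fraction makes the pure-tissue extrapolation land at x = +/-1
    regardless of CSF partial volume.  Voxels with no GM or WM content give
    NaN (they are rejected upstream by the BGND/CSF rules).
    """
    denom = fr.f_wm + fr.f_gm
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (fr.f_wm - fr.f_gm) / denom, np.nan)


def tissue_difference(fr: TissueFractions) -> np.ndarray:
    """Raw unnormalised (%WM - %GM) in percentage points (sensitivity variant)."""
    return fr.f_wm - fr.f_gm
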