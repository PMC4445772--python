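"""Spatial reconstruction of voxel FIDs from k-space.

The 24 x 24 phase-encode grid is transformed per time point with a centred
orthonormal inverse 2D FFT, optionally after cosine-weighted apodisation of
k-space.  DC sits at index N/2 (12 on the default grid).

Apodisation window
------------------
w(k) = cos(pi * k / (2 * (N/2 + 1))) with k = index - N/2.  The DC sample
has weight exactly 1 and the outermost samples keep a strictly positive
weight; the window is symmetric, w(k) = w(-k), wherever both indices
exist.  The window trades spatial side-lobes (inter-voxel bleed) for a
broadened main lobe, as usual for MRSI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AcquisitionParams
from .phantom import MRSIAcquisition


@dataclass
class VoxelGrid:
    """Reconstructed voxel-space FIDs plus PRESS-box masks."""

    fids: np.ndarray        # complex (x, y, t)
    params: AcquisitionParams
    press_mask: np.ndarray  # True for voxels inside the PRESS box
    edge_mask: np.ndarray   # True for the 1-voxel boundary ring of the box

    def __post_init__(self) -> None:
        if self.edge_mask[~self.press_mask].any():
            raise ValueError("edge_mask must be a subset of press_mask")

    @property
    def interior_mask(self) -> np.ndarray:
        """Voxels fully inside the PRESS box (edge ring removed)."""
        return self.press_mask & ~self.edge_mask

    def voxels(self, interior_only: bool = True):
        """Iterate (ix, iy) indices over the analysable grid."""
        mask = self.interior_mask if interior_only else self.press_mask
        return [tuple(v) for v in np.argwhere(mask)]


def cosine_window(n: int) -> np.ndarray:
    """1D cosine apodisation weights for an n-sample phase-encode axis."""
    k = np.arange(n) - n // 2
    return np.cos(np.pi * k / (2.0 * (n // 2 + 1)))


def apodise_kspace(kspace: np.ndarray, params: AcquisitionParams) -> np.ndarray:
    """Multiply k-space by the separable cosine window w(kx) * w(ky)."""
    if kspace.shape[:2] != (params.n_phase_x, params.n_phase_y):
        raise ValueError(
            f"kspace grid {kspace.shape[:2]} does not match params "
            f"({params.n_phase_x}, {params.n_phase_y})"
        )
    wx = cosine_window(params.n_phase_x)
    wy = cosine_window(params.n_phase_y)
    return kspace * wx[:, None, None] * wy[None, :, None]


def press_masks(params: AcquisitionParams) -> tuple[np.ndarray, np.ndarray]:
    """(press_mask, edge_mask) boolean grids from the configured PRESS box."""
    x0, x1, y0, y1 = params.press_box
    press = np.zeros((params.n_phase_x, params.n_phase_y), dtype=bool)
    press[x0:x1, y0:y1] = True
    interior = np.zeros_like(press)
    interior[x0 + 1:x1 - 1, y0 + 1:y1 - 1] = True
    return press, press & ~interior


def reconstruct(acq: MRSIAcquisition, apodise: bool = True) -> VoxelGrid:
    """Inverse 2D spatial FT of the acquisition, per time point."""
    k = acq.kspace
    if not np.all(np.isfinite(k)):
        bad = tuple(int(i) for i in np.argwhere(~np.isfinite(k))[0])
        raise ValueError(f"non-finite k-space sample at index {bad}")
    if apodise:
        k = apodise_kspace(k, acq.params)
    fids = np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=(0, 1)), axes=(0, 1), norm="ortho"),
        axes=(0, 1),
    )
    press, edge = press_masks(acq.params)
    return VoxelGrid(fids=fids, params=acq.params, press_mask=press, edge_mask=edge)
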