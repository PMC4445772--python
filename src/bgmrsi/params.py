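"""Acquisition geometry, timing and pipeline configuration.

The default :class:`AcquisitionParams` describe a 1.5 T single-slab PRESS
MRSI protocol: a 24 x 24 phase-encode grid over a 240 mm field of view
(10 mm in-plane voxels), a 10 mm slab, 512 complex points per FID at a
1 ms dwell (1000 Hz spectral width), TR/TE = 1000/145 ms.

Frequency convention
--------------------
FIDs are stored in the rotating frame of the transmitter, which is placed
on water (4.70 ppm).  An off-water resonance at chemical shift ``p`` ppm
appears at ``f = (water_ppm - p) * f0_mhz`` Hz, so the ppm axis is
``ppm = water_ppm - f / f0_mhz``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml


@dataclass(frozen=True)
class AcquisitionParams:
    """Spectroscopic-imaging acquisition parameters."""

    n_phase_x: int = 24
    n_phase_y: int = 24
    n_points: int = 512
    dwell_s: float = 1.0e-3
    tr_ms: float = 1000.0
    te_ms: float = 145.0
    fov_mm: float = 240.0
    slab_mm: float = 10.0
    field_t: float = 1.5
    f0_mhz: float = 63.87
    water_ppm: float = 4.70
    #: half-open (x0, x1, y0, y1) voxel-index rectangle of the PRESS box
    press_box: tuple[int, int, int, int] = (5, 19, 6, 18)

    def __post_init__(self) -> None:
        x0, x1, y0, y1 = self.press_box
        if not (0 < x0 < x1 < self.n_phase_x and 0 < y0 < y1 < self.n_phase_y):
            raise ValueError(
                f"press_box {self.press_box} must lie strictly inside the "
                f"{self.n_phase_x} x {self.n_phase_y} grid"
            )

    @property
    def spectral_width_hz(self) -> float:
        return 1.0 / self.dwell_s

    @property
    def voxel_mm(self) -> float:
        return self.fov_mm / self.n_phase_x

    @property
    def readout_s(self) -> float:
        return self.n_points * self.dwell_s

    def time_axis(self) -> np.ndarray:
        """Sample times in seconds, starting at t = 0."""
        return np.arange(self.n_points) * self.dwell_s

    def hz_of_ppm(self, ppm: float | np.ndarray) -> float | np.ndarray:
        """Offset frequency (Hz, transmitter on water) of a chemical shift."""
        return (self.water_ppm - np.asarray(ppm, dtype=float)) * self.f0_mhz

    def ppm_of_hz(self, hz: float | np.ndarray) -> float | np.ndarray:
        return self.water_ppm - np.asarray(hz, dtype=float) / self.f0_mhz

    def fft_freqs_hz(self) -> np.ndarray:
        """Frequency axis of ``np.fft.fft(fid)`` (natural FFT ordering)."""
        return np.fft.fftfreq(self.n_points, self.dwell_s)


@dataclass
class QCThresholds:
    """Voxel rejection thresholds of the quality-control cascade.

    All comparisons are strict in the rejecting direction, so values that
    sit exactly on a bound are retained.
    """

    csf_max_pct: float = 20.0    # reject if CSF fraction exceeds this
    brain_min_pct: float = 95.0  # reject if brain (non-BGND) fraction is below
    lw_min_hz: float = 1.0       # reject fitted FWHM strictly below
    lw_max_hz: float = 10.0      # reject fitted FWHM strictly above
    ppm_offset_max: float = 0.1  # reject |fitted - nominal| strictly above
    min_voxels_per_subject: int = 5


@dataclass
class VisualProxyConfig:
    """Automated stand-in for human visual spectrum review."""

    enabled: bool = True
    baseline_z: float = 3.0       # |median real spectrum| vs noise SD
    spurious_frac: float = 0.5    # residual peak vs tallest fitted peak
    ppm_lo: float = 1.0
    ppm_hi: float = 4.0
    exclude_ppm: float = 0.15     # half-width masked around each fitted peak
    noise_ppm: tuple[float, float] = (6.0, 10.0)


@dataclass
class PipelineConfig:
    """Everything the three pipeline commands need, in one serialisable bag."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    visual: VisualProxyConfig = field(default_factory=VisualProxyConfig)
    relaxation_preset: str = "basal_ganglia_elderly_1p5T"
    concentration_preset: str = "LBC1936"
    hlsvd_rank: int = 16
    water_window_hz: float = 30.0
    water_lowpass_hz: float = 25.0
    iu_scale: float = 1.0
    #: compute tissue fractions of the apodised (PSF-weighted) voxel
    #: profile rather than the nominal 10 mm cube, keeping the
    #: partial-volume regressor consistent with what the signal measures
    psf_weighted_fractions: bool = True
    n_subjects: int = 10
    seed: int = 0
    downweight_first_points: int = 0
    stats_method: str = "mixed"  # "mixed" (random intercept) or "anova"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "acquisition" in d:
            acq = dict(d["acquisition"])
            if "press_box" in acq:
                acq["press_box"] = tuple(acq["press_box"])
            d["acquisition"] = AcquisitionParams(**acq)
        if "qc" in d:
            d["qc"] = QCThresholds(**d["qc"])
        if "visual" in d:
            vis = dict(d["visual"])
            if "noise_ppm" in vis:
                vis["noise_ppm"] = tuple(vis["noise_ppm"])
            d["visual"] = VisualProxyConfig(**vis)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
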