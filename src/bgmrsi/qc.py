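"""Ordered voxel-rejection cascade and attrition accounting.

Stages are applied in a fixed order, and a voxel is charged to the first
stage it fails:

    BGND   brain (non-background) below 95 % of the voxel volume
    CSF    CSF above 20 %
    NAA    NAA fit failed the spectral rules (convergence, linewidth,
           chemical-shift offset)
    Vis    automated proxy for the visual quality check
    ChoCre choline and/or creatine failed the spectral rules

All threshold comparisons are strict in the rejecting direction, so a
voxel sitting exactly on a bound (CSF = 20.0 %, FWHM = 1.0 or 10.0 Hz,
offset = 0.1 ppm) is retained.  Only voxels fully inside the PRESS box
(edge ring excluded) enter the denominator; the count including the edge
ring is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import PipelineConfig, QCThresholds, VisualProxyConfig
from .spectral_fit import FitResult
from .tissue import TissueFractions

STAGES = ("BGND", "CSF", "NAA", "Vis", "ChoCre")


@dataclass
class QCRecord:
    voxel: tuple[int, int]
    stage_failed: str  # one of STAGES or "none"
    details: dict[str, float] = field(default_factory=dict)


@dataclass
class AttritionTable:
    """Voxel bookkeeping.

    ``n_valid_naa`` counts voxels surviving the NAA spectral test (the
    tissue and NAA stages), of which the Vis and ChoCre stages then remove
    further voxels, leaving ``n_valid_all``:

        n_total     = BGND + CSF + NAA + n_valid_naa
        n_valid_all = n_valid_naa - Vis - ChoCre
    """

    counts: dict[str, int]
    n_total: int
    n_valid_naa: int
    n_valid_all: int
    n_inbox_with_edges: int = 0

    def __post_init__(self) -> None:
        c = self.counts
        if self.n_total != c["BGND"] + c["CSF"] + c["NAA"] + self.n_valid_naa:
            raise ValueError("attrition counts inconsistent with n_total")
        if self.n_valid_all != self.n_valid_naa - c["Vis"] - c["ChoCre"]:
            raise ValueError("Vis/ChoCre counts inconsistent with valid totals")

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_total": self.n_total,
            "n_valid_naa": self.n_valid_naa,
            "n_valid_all": self.n_valid_all,
            "n_inbox_with_edges": self.n_inbox_with_edges,
        }


def spectral_valid(
    fit: FitResult, peak: str, qc: QCThresholds | None = None
) -> tuple[bool, str]:
    """Spectral rules for one fitted peak: (valid, reason).

    Valid iff the fit converged, the linewidth lies in [lw_min, lw_max]
    and the fitted centre is within ppm_offset_max of nominal.
    """
    qc = qc or QCThresholds()
    if not fit.converged:
        return False, "convergence"
    pk = fit.peaks[peak]
    if pk.fwhm_hz < qc.lw_min_hz or pk.fwhm_hz > qc.lw_max_hz:
        return False, "linewidth"
    if abs(pk.offset_ppm) > qc.ppm_offset_max:
        return False, "offset"
    return True, ""


def visual_proxy(
    spectrum_fid: np.ndarray,
    fit: FitResult,
    params,
    cfg: VisualProxyConfig | None = None,
) -> bool:
    """Automated stand-in for human visual review of one spectrum.

    Rejects on (a) an elevated baseline: the median of the real residual
    spectrum (data minus fitted model) over the metabolite region exceeds
    ``baseline_z`` times the noise SD estimated from a signal-free region
    -- a baseline the peak model itself carries (the constant offset of
    any causal FID) is thereby not penalised; or (b) a spurious peak: the
    residual spectrum outside the fitted-peak windows exceeds
    ``spurious_frac`` times the tallest fitted peak.  Returns True when
    the spectrum passes.
    """
    cfg = cfg or VisualProxyConfig()
    if not cfg.enabled:
        return True
    spec = np.fft.fft(spectrum_fid)
    freqs = np.fft.fftfreq(len(spectrum_fid), params.dwell_s)
    ppm = params.ppm_of_hz(freqs)

    noise_sel = (ppm >= cfg.noise_ppm[0]) & (ppm <= cfg.noise_ppm[1])
    noise_sd = float(np.std(spec[noise_sel].real)) if noise_sel.any() else 0.0
    met_sel = (ppm >= cfg.ppm_lo) & (ppm <= cfg.ppm_hi)

    model_spec = np.fft.fft(fit.model) if fit.model is not None else 0.0
    baseline = abs(float(np.median((spec - model_spec)[met_sel].real)))
    if noise_sd > 0 and baseline > cfg.baseline_z * noise_sd:
        return False

    if fit.model is not None:
        resid = np.abs((spec - model_spec).real)
        outside = met_sel.copy()
        for pk in fit.peaks.values():
            outside &= np.abs(ppm - pk.centre_ppm) > cfg.exclude_ppm
        if outside.any():
            tallest = float(np.max(np.abs(model_spec.real))) if np.any(fit.model) else 0.0
            floor = max(cfg.baseline_z * noise_sd, 0.0)
            if tallest > 0 and float(resid[outside].max()) > max(
                cfg.spurious_frac * tallest, floor
            ):
                return False
    return True


def run_cascade(
    fits: dict[tuple[int, int], FitResult],
    fractions: TissueFractions,
    press_mask: np.ndarray,
    edge_mask: np.ndarray,
    config: PipelineConfig | None = None,
    spectra: dict[tuple[int, int], np.ndarray] | None = None,
    params=None,
) -> tuple[list[QCRecord], AttritionTable]:
    """Apply the rejection cascade over the PRESS-interior grid.

    ``fits`` may omit voxels that already fail the tissue stages; a voxel
    past the tissue stages with no fit available is charged to NAA (fit
    failure).  ``spectra`` supplies corrected FIDs for the visual proxy;
    when absent the Vis stage passes everything.
    """
    config = config or PipelineConfig()
    qc = config.qc
    if fractions.f_gm.shape != press_mask.shape:
        raise ValueError(
            f"fraction grid {fractions.f_gm.shape} does not match press mask "
            f"{press_mask.shape}"
        )
    interior = press_mask & ~edge_mask

    records: list[QCRecord] = []
    counts = {s: 0 for s in STAGES}
    n_valid_naa = 0
    n_valid_all = 0
    for ix, iy in map(tuple, np.argwhere(interior)):
        v = (ix, iy)
        brain_pct = 100.0 - fractions.f_bgnd[ix, iy]
        csf_pct = fractions.f_csf[ix, iy]
        details = {"brain_pct": brain_pct, "csf_pct": csf_pct}

        if brain_pct < qc.brain_min_pct:
            stage = "BGND"
        elif csf_pct > qc.csf_max_pct:
            stage = "CSF"
        else:
            fit = fits.get(v)
            naa_ok = False
            if fit is not None:
                naa_ok, reason = spectral_valid(fit, "NAA", qc)
                details["naa_fwhm_hz"] = fit.peaks["NAA"].fwhm_hz
                details["naa_offset_ppm"] = fit.peaks["NAA"].offset_ppm
                if not naa_ok:
                    details["naa_reason"] = reason
            if not naa_ok:
                stage = "NAA"
            else:
                n_valid_naa += 1
                vis_ok = True
                if spectra is not None and v in spectra:
                    vis_ok = visual_proxy(spectra[v], fit, params, config.visual)
                if not vis_ok:
                    stage = "Vis"
                else:
                    cho_ok, cho_r = spectral_valid(fit, "Cho", qc)
                    cre_ok, cre_r = spectral_valid(fit, "Cre", qc)
                    if not (cho_ok and cre_ok):
                        stage = "ChoCre"
                        details["chocre_reason"] = cho_r or cre_r
                    else:
                        stage = "none"
                        n_valid_all += 1
        if stage in counts:
            counts[stage] += 1
        records.append(QCRecord(voxel=v, stage_failed=stage, details=details))

    table = AttritionTable(
        counts=counts,
        n_total=int(interior.sum()),
        n_valid_naa=n_valid_naa,
        n_valid_all=n_valid_all,
        n_inbox_with_edges=int(press_mask.sum()),
    )
    return records, table


def subject_inclusion(n_valid_voxels: int, min_voxels: int = 5) -> bool:
    """Subjects with fewer than ``min_voxels`` valid voxels are excluded."""
    return n_valid_voxels >= min_voxels
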