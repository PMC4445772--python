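"""QC cascade: rule boundaries, ordered attrition accounting, visual proxy
and subject inclusion."""

import numpy as np
import pytest

from bgmrsi.lineshape import gaussian_peak
from bgmrsi.params import PipelineConfig, QCThresholds
from bgmrsi.presets import NOMINAL_PPM
from bgmrsi.qc import (
    AttritionTable,
    run_cascade,
    spectral_valid,
    subject_inclusion,
    visual_proxy,
)
from bgmrsi.spectral_fit import FitResult, PeakFit, fit_voxel
from bgmrsi.tissue import TissueFractions


def make_fit(fwhm=5.0, offset_ppm=0.0, converged=True, amplitude=50.0):
    peaks = {}
    for m in ("NAA", "Cho", "Cre", "Lac"):
        peaks[m] = PeakFit(
            amplitude=amplitude,
            centre_ppm=NOMINAL_PPM[m] + offset_ppm,
            offset_ppm=offset_ppm,
            fwhm_hz=fwhm,
            phase=0.0,
        )
    return FitResult(peaks=peaks, residual_rms=1.0, converged=converged)


class TestSpectralValid:
    @pytest.mark.parametrize(
        "fwhm, offset, expect, reason",
        [
            (1.0, 0.0, True, ""),        # boundary linewidth retained
            (10.0, 0.0, True, ""),       # boundary linewidth retained
            (0.9, 0.0, False, "linewidth"),
            (10.5, 0.0, False, "linewidth"),
            (5.0, 0.1, True, ""),        # boundary offset retained
            (5.0, 0.11, False, "offset"),
            (5.0, -0.11, False, "offset"),
        ],
    )
    def test_rule_boundaries(self, fwhm, offset, expect, reason):
        ok, why = spectral_valid(make_fit(fwhm=fwhm, offset_ppm=offset), "NAA")
        assert ok is expect
        assert why == reason

    def test_non_converged_fit_invalid(self):
        ok, why = spectral_valid(make_fit(converged=False), "NAA")
        assert not ok and why == "convergence"


class TestVisualProxy:
    def _fitted_phantom_fid(self, params, noise_sd=1.0, seed=2):
        rng = np.random.default_rng(seed)
        t = params.time_axis()
        fid = np.zeros(params.n_points, dtype=complex)
        for m, a in (("Cho", 40.0), ("Cre", 30.0), ("NAA", 70.0)):
            fid += gaussian_peak(t, a, params.hz_of_ppm(NOMINAL_PPM[m]), 5.0)
        fid += noise_sd * (rng.standard_normal(len(t))
                           + 1j * rng.standard_normal(len(t)))
        return fid, fit_voxel(fid, params=params)

    def test_clean_spectrum_passes(self, params):
        fid, fit = self._fitted_phantom_fid(params)
        assert visual_proxy(fid, fit, params)

    def test_elevated_baseline_fails(self, params):
        """A constant spectral offset of 5x the noise SD is rejected."""
        fid, fit = self._fitted_phantom_fid(params)
        spec = np.fft.fft(fid)
        ppm = params.ppm_of_hz(params.fft_freqs_hz())
        noise_sd = np.std(spec[(ppm >= 6) & (ppm <= 10)].real)
        doctored = np.fft.ifft(spec + 5.0 * noise_sd)
        assert not visual_proxy(doctored, fit, params)

    def test_spurious_peak_fails(self, params):
        """A rogue resonance at 3.6 ppm twice the NAA height is rejected."""
        fid, fit = self._fitted_phantom_fid(params)
        t = params.time_axis()
        rogue = gaussian_peak(t, 140.0, params.hz_of_ppm(3.6), 5.0)
        assert not visual_proxy(fid + rogue, fit, params)

    def test_disabled_proxy_passes_everything(self, params):
        from bgmrsi.params import VisualProxyConfig

        fid, fit = self._fitted_phantom_fid(params)
        spec = np.fft.fft(fid)
        doctored = np.fft.ifft(spec + 1e4)
        cfg = VisualProxyConfig(enabled=False)
        assert visual_proxy(doctored, fit, params, cfg)


def ten_voxel_fixture(params):
    """10-voxel PRESS-interior grid exercising every cascade stage.

    Stage plan: 2 BGND, 2 CSF, 2 NAA-fail, 1 Vis, 1 ChoCre, 2 pass.
    """
    import dataclasses

    p = dataclasses.replace(params, press_box=(1, 8, 1, 5))
    nx, ny = p.n_phase_x, p.n_phase_y
    f_gm = np.full((nx, ny), 30.0)
    f_wm = np.full((nx, ny), 70.0)
    f_csf = np.zeros((nx, ny))
    f_bgnd = np.zeros((nx, ny))
    from bgmrsi.recon import press_masks

    press, edge = press_masks(p)
    interior = [tuple(v) for v in np.argwhere(press & ~edge)]
    assert len(interior) == 10

    def set_fr(v, gm, wm, csf, bgnd):
        f_gm[v], f_wm[v], f_csf[v], f_bgnd[v] = gm, wm, csf, bgnd

    fits, vis_fail = {}, set()
    # 2 BGND (brain < 95 %)
    set_fr(interior[0], 20, 70, 0, 10)
    set_fr(interior[1], 30, 60, 4, 6)
    # 2 CSF (> 20 %)
    set_fr(interior[2], 30, 45, 25, 0)
    set_fr(interior[3], 30, 49, 21, 0)
    # 2 NAA failures (bad linewidth / no convergence)
    fits[interior[4]] = make_fit(fwhm=12.0)
    fits[interior[5]] = make_fit(converged=False)
    # 1 visual failure (flagged externally)
    fits[interior[6]] = make_fit()
    vis_fail.add(interior[6])
    # 1 ChoCre failure: NAA fine, Cho offset too large
    bad_cho = make_fit()
    bad_cho.peaks["Cho"] = PeakFit(50.0, NOMINAL_PPM["Cho"] + 0.2, 0.2, 5.0, 0.0)
    fits[interior[7]] = bad_cho
    # 2 clean passes, one sitting exactly on the CSF boundary
    fits[interior[8]] = make_fit()
    set_fr(interior[8], 30, 50, 20.0, 0)  # CSF == 20.0 % retained
    fits[interior[9]] = make_fit(fwhm=1.0)  # FWHM == 1.0 Hz retained

    fr = TissueFractions(f_gm, f_wm, f_csf, 100.0 - f_gm - f_wm - f_csf)
    return p, fits, fr, press, edge, vis_fail, interior


class TestCascade:
    def test_ten_voxel_fixture_counts(self, params):
        p, fits, fr, press, edge, vis_fail, interior = ten_voxel_fixture(params)
        cfg = PipelineConfig(acquisition=p)

        # emulate the visual stage with a doctored spectrum for one voxel
        spectra = {}
        t = p.time_axis()
        rng = np.random.default_rng(8)
        model = gaussian_peak(t, 50.0, p.hz_of_ppm(NOMINAL_PPM["NAA"]), 5.0)
        clean = model + 1.0 * (rng.standard_normal(len(t))
                               + 1j * rng.standard_normal(len(t)))
        for v in fits:
            spectra[v] = clean
        bad = np.fft.ifft(np.fft.fft(clean) + 200.0)
        for v in vis_fail:
            spectra[v] = bad
        # attach matching models so the proxy sees residuals, not peaks
        for v, f in fits.items():
            f.model = model

        records, table = run_cascade(fits, fr, press, edge, cfg,
                                     spectra=spectra, params=p)
        assert table.counts == {"BGND": 2, "CSF": 2, "NAA": 2, "Vis": 1,
                                "ChoCre": 1}
        assert table.n_total == 10
        assert table.n_valid_naa == 4
        assert table.n_valid_all == 2
        stages = {r.voxel: r.stage_failed for r in records}
        assert stages[interior[8]] == "none"   # CSF 20.0 % retained
        assert stages[interior[9]] == "none"   # FWHM 1.0 Hz retained

    def test_all_pass_grid(self, params):
        p, fits, fr, press, edge, _, interior = ten_voxel_fixture(params)
        for v in interior:
            fits[v] = make_fit()
            fr.f_gm[v], fr.f_wm[v], fr.f_csf[v], fr.f_bgnd[v] = 30, 70, 0, 0
        cfg = PipelineConfig(acquisition=p)
        _, table = run_cascade(fits, fr, press, edge, cfg)
        assert table.counts == {s: 0 for s in table.counts}
        assert table.n_valid_all == table.n_total == 10

    def test_mismatched_grid_raises(self, params):
        p, fits, fr, press, edge, _, _ = ten_voxel_fixture(params)
        small = TissueFractions(*(np.full((4, 4), 25.0) for _ in range(4)))
        with pytest.raises(ValueError, match="does not match"):
            run_cascade(fits, small, press, edge, PipelineConfig(acquisition=p))

    def test_relaxing_linewidth_threshold_never_reduces_yield(self, params):
        p, fits, fr, press, edge, _, _ = ten_voxel_fixture(params)
        yields = []
        for lw_max in (8.0, 10.0, 13.0):
            cfg = PipelineConfig(acquisition=p)
            cfg.qc = QCThresholds(lw_max_hz=lw_max)
            _, table = run_cascade(fits, fr, press, edge, cfg)
            yields.append(table.n_valid_all)
        assert yields == sorted(yields)


class TestAttritionTable:
    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            AttritionTable(
                counts={"BGND": 1, "CSF": 0, "NAA": 0, "Vis": 0, "ChoCre": 0},
                n_total=5, n_valid_naa=3, n_valid_all=3,
            )


@pytest.mark.parametrize("n, included", [(4, False), (5, True), (0, False)])
def test_subject_inclusion_boundary(n, included):
    assert subject_inclusion(n) is included
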