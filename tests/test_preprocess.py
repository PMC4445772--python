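"""Water referencing, phase/eddy correction and HLSVD water removal."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgmrsi.lineshape import gaussian_peak
from bgmrsi.params import AcquisitionParams
from bgmrsi.phantom import simulate_voxel_fid
from bgmrsi.preprocess import (
    WaterReference,
    correct_fid,
    estimate_water,
    hlsvd_fit,
    preprocess_fid,
    remove_water,
)

from conftest import uniform_spec


def water_fid(params, offset_hz=0.0, fwhm=4.0, amp=1000.0, phase=0.0):
    return gaussian_peak(params.time_axis(), amp, offset_hz, fwhm, phase)


def real_area(fid, params, lo_ppm=4.4, hi_ppm=5.0):
    """Absorption-mode area of the water region."""
    s = np.fft.fft(fid)
    ppm = params.ppm_of_hz(params.fft_freqs_hz())
    sel = (ppm >= lo_ppm) & (ppm <= hi_ppm)
    return np.abs(s[sel].real).sum()


class TestEstimateWater:
    def test_on_resonance_water_gives_zero_offset_and_flat_phase(self, params):
        ref = estimate_water(water_fid(params), params)
        assert ref.found
        assert ref.freq_offset_hz == pytest.approx(0.0, abs=0.05)
        assert np.abs(ref.phase_track[:200]).max() < 0.01

    def test_shifted_water_offset_in_hz(self, params):
        """+0.05 ppm at 63.87 MHz is +3.19 Hz (water below 4.70 moves -f)."""
        shift_hz = -0.05 * params.f0_mhz  # +0.05 ppm shift of the line
        ref = estimate_water(water_fid(params, offset_hz=-shift_hz), params)
        assert ref.freq_offset_hz == pytest.approx(3.19, abs=0.3)

    def test_eddy_phase_recovered(self, params):
        """Injected phase 0.5*exp(-t/0.1 s) is recovered within 0.02 rad."""
        t = params.time_axis()
        phi = 0.5 * np.exp(-t / 0.1)
        fid = water_fid(params) * np.exp(1j * phi)
        ref = estimate_water(fid, params)
        total = ref.phase_track + 2 * np.pi * ref.freq_offset_hz * t
        sel = t <= 0.2
        assert np.abs(total[sel] - phi[sel]).max() < 0.02

    def test_no_water_falls_back_to_metabolite_phasing(self, params):
        spec = uniform_spec("wm", params)
        fid = simulate_voxel_fid(spec, params, (12, 12), include_noise=False)
        fid = fid * np.exp(1j * 0.7)
        ref = estimate_water(fid, params)
        assert not ref.found
        assert ref.phase_track[0] == pytest.approx(0.7, abs=1e-9)
        corr = correct_fid(fid, ref, params)
        # the zero-order rotation is undone: in-phase again at t = 0
        assert np.angle(corr[0]) == pytest.approx(0.0, abs=1e-9)


class TestCorrectFid:
    def test_identity_for_trivial_reference(self, params):
        fid = water_fid(params, offset_hz=3.0)
        ref = WaterReference(np.zeros(len(fid)), 0.0, 1.0)
        assert np.array_equal(correct_fid(fid, ref, params), fid)

    def test_pure_zero_order_phase_rotation(self, params):
        """A 30 degree zero-order error is undone exactly."""
        fid0 = water_fid(params)
        fid = fid0 * np.exp(1j * np.deg2rad(30))
        ref = WaterReference(np.full(len(fid), np.deg2rad(30)), 0.0, 1.0)
        corr = correct_fid(fid, ref, params)
        s = np.fft.fft(corr)
        assert s.real.max() == pytest.approx(np.abs(s).max(), rel=1e-9)
        assert np.allclose(corr, fid0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_magnitudes_unchanged(self, seed):
        params = AcquisitionParams()
        rng = np.random.default_rng(seed)
        fid = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        ref = WaterReference(rng.standard_normal(64), rng.normal(0, 5), 1.0)
        corr = correct_fid(fid, ref, params)
        assert np.allclose(np.abs(corr), np.abs(fid), rtol=1e-12)

    def test_phantom_eddy_on_off_agree_after_correction(self, params):
        spec = uniform_spec("wm", params, water_residual_scale=0.05,
                            eddy_terms=((0.5, 0.08),), zero_phase=0.9)
        still = dataclasses.replace(spec, eddy_terms=(), zero_phase=0.0,
                                    _fractions=None)
        v = (12, 12)
        corr_on = correct_fid(simulate_voxel_fid(spec, params, v),
                              estimate_water(simulate_voxel_fid(spec, params, v), params),
                              params)
        corr_off = correct_fid(simulate_voxel_fid(still, params, v),
                               estimate_water(simulate_voxel_fid(still, params, v), params),
                               params)
        s_on, s_off = np.fft.fft(corr_on), np.fft.fft(corr_off)
        rms = np.sqrt(np.mean(np.abs(s_on - s_off) ** 2))
        assert rms / np.sqrt(np.mean(np.abs(s_off) ** 2)) < 0.01


class TestHLSVD:
    def test_single_damped_sinusoid_recovered(self, params):
        t = params.time_axis()
        fid = 2.0 * np.exp((2j * np.pi * 37.0 - 6.0) * t + 1j * 0.4)
        model = hlsvd_fit(fid, 1, params)
        f, d, a, p = model.components[0]
        assert f == pytest.approx(37.0, rel=1e-4)
        assert d == pytest.approx(6.0, rel=1e-4)
        assert a == pytest.approx(2.0, rel=1e-4)

    def test_zero_fid_gives_no_components(self, params):
        model = hlsvd_fit(np.zeros(512, dtype=complex), 4, params)
        assert model.components.size == 0

    def test_three_exponentials_rank_eight(self, params):
        t = params.time_axis()
        truth = [(3.0, -60.0, 4.0), (1.5, 10.0, 8.0), (0.8, 150.0, 3.0)]
        fid = sum(a * np.exp((2j * np.pi * f - d) * t) for a, f, d in truth)
        model = hlsvd_fit(fid, 8, params)
        amps = sorted(model.components[:3, 2], reverse=True)
        for est, (a, _, _) in zip(amps, truth):
            assert est == pytest.approx(a, rel=1e-3)
        assert np.all(model.components[3:, 2] < 1e-6 * truth[0][0])

    def test_rank_validation(self, params):
        with pytest.raises(ValueError):
            hlsvd_fit(np.ones(512, dtype=complex), 0, params)
        with pytest.raises(ValueError):
            hlsvd_fit(np.ones(512, dtype=complex), 256, params)

    def test_noiseless_reconstruction_high_fidelity(self, params):
        """Rank >= K reconstructs a K-component signal to < 1e-6 relative."""
        t = params.time_axis()
        fid = (1.0 * np.exp((2j * np.pi * 5 - 8.0) * t)
               + 0.5 * np.exp((2j * np.pi * -12 - 15.0) * t))
        model = hlsvd_fit(fid, 4, params)
        rec = model.reconstruct(t, np.ones(len(model.components), dtype=bool))
        assert np.abs(rec - fid).max() / np.abs(fid).max() < 1e-6


class TestRemoveWater:
    def test_no_component_in_window_is_identity(self, params):
        t = params.time_axis()
        fid = np.exp((2j * np.pi * 170.0 - 10.0) * t)
        model = hlsvd_fit(fid, 2, params)
        out = remove_water(fid, model, params, window_hz=30.0)
        assert np.array_equal(out, fid)

    def test_water_only_fid_reduced_to_noise_floor(self, params):
        rng = np.random.default_rng(5)
        noise = 0.5 * (rng.standard_normal(512) + 1j * rng.standard_normal(512))
        fid = water_fid(params, offset_hz=2.0, amp=3000.0) + noise
        model = hlsvd_fit(fid, 16, params)
        out = remove_water(fid, model, params, window_hz=30.0)
        # residual power comparable to the injected noise power
        assert np.mean(np.abs(out) ** 2) < 3.0 * np.mean(np.abs(noise) ** 2)

    def test_phantom_water_area_reduced_99_percent(self, params):
        spec = uniform_spec("wm", params, water_residual_scale=0.05,
                            noise_sd=1.5, seed=7,
                            eddy_terms=((0.4, 0.06),), zero_phase=0.5)
        fid = simulate_voxel_fid(spec, params, (12, 12))
        ref = estimate_water(fid, params)
        corr = correct_fid(fid, ref, params)
        model = hlsvd_fit(corr, 16, params)
        out = remove_water(corr, model, params, window_hz=30.0)
        assert 1 - real_area(out, params) / real_area(corr, params) >= 0.99


def test_preprocess_is_idempotent(params):
    """A second pass changes the spectrum by less than 0.1 %."""
    spec = uniform_spec("wm", params, water_residual_scale=0.05,
                        eddy_terms=((0.5, 0.08),), zero_phase=0.8)
    fid = simulate_voxel_fid(spec, params, (12, 12), include_noise=False)
    once, _ = preprocess_fid(fid, params)
    twice, _ = preprocess_fid(once, params)
    s1, s2 = np.fft.fft(once), np.fft.fft(twice)
    assert (np.sqrt(np.mean(np.abs(s2 - s1) ** 2))
            / np.sqrt(np.mean(np.abs(s1) ** 2))) < 1e-3
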