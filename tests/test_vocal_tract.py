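"""Vocal-tract filter: tube model, mouth opening, envelopes, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import welch

from voxgen.contours import ContourSpec, sample_contour
from voxgen.source import GlottalSourceParams, compute_f0_track, synthesize_voiced
from voxgen.stft import N_BINS, bin_frequencies
from voxgen.vocal_tract import (
    NASAL_F1_BANDWIDTH,
    SPEED_OF_SOUND,
    Formant,
    FormantTable,
    SpectralEnvelope,
    VocalTractParams,
    adjust_for_mouth,
    apply_filter,
    compute_spectral_envelope,
    estimate_bandwidth,
    estimate_vtl,
    extend_formants,
    formant_frequencies_from_vtl,
)
from voxgen.waveform import Waveform

from conftest import SR, flat_f0


def mouth_contour(value, n_frames=4):
    spec = ContourSpec.from_pairs(float(value), parameter_id="mouth")
    return sample_contour(spec, 1.0, n_frames)


class TestTubeModel:
    def test_vtl_from_schwa_formants(self):
        assert estimate_vtl([500, 1500, 2500]) == pytest.approx(17.7, rel=1e-12)

    def test_vtl_from_single_formant(self):
        assert estimate_vtl([500]) == pytest.approx(35400 / (4 * 500), rel=1e-12)

    def test_vtl_scaling_symmetry(self):
        assert estimate_vtl([1000, 3000, 5000]) == pytest.approx(8.85, rel=1e-12)

    def test_schwa_series(self):
        assert np.allclose(formant_frequencies_from_vtl(17.7, 3), [500, 1500, 2500])

    def test_equidistant_spacing(self):
        f = formant_frequencies_from_vtl(17.7, 6)
        assert np.allclose(np.diff(f), SPEED_OF_SOUND / (2 * 17.7))

    def test_first_formant_quarter_wavelength(self):
        vtl = 12.0
        assert formant_frequencies_from_vtl(vtl, 1)[0] == pytest.approx(
            SPEED_OF_SOUND / (4 * vtl)
        )

    @settings(deadline=None, max_examples=60)
    @given(st.floats(5.0, 100.0))
    def test_round_trip_vtl(self, vtl):
        freqs = formant_frequencies_from_vtl(vtl, 4)
        assert estimate_vtl(freqs) == pytest.approx(vtl, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_vtl([])
        with pytest.raises(ValueError):
            estimate_vtl([-100.0])
        with pytest.raises(ValueError):
            formant_frequencies_from_vtl(-5.0, 3)


class TestExtendFormants:
    def test_appends_tube_series_above_user_formants(self):
        user = FormantTable([Formant.at(500.0), Formant.at(1500.0)])
        out = extend_formants(user, 17.7, nyquist=11025.0)
        freqs = out.frequencies_at(0.0)
        assert np.allclose(freqs, [500, 1500, 2500, 3500, 4500, 5500, 6500, 7500, 8500, 9500, 10500])

    def test_user_formants_never_altered(self):
        user = FormantTable([Formant.at(640.0), Formant.at(1900.0)])
        out = extend_formants(user, 15.0, nyquist=11025.0)
        assert out.formants[0].frequency.anchors[0].value == 640.0
        assert out.formants[1].frequency.anchors[0].value == 1900.0

    def test_empty_table_yields_full_schwa(self):
        out = extend_formants(FormantTable(), 17.7, nyquist=11025.0)
        freqs = out.frequencies_at(0.0)
        assert freqs[0] == pytest.approx(500.0)
        assert np.allclose(np.diff(freqs), 1000.0)

    def test_saturated_table_unchanged(self):
        user = FormantTable([Formant.at(f) for f in formant_frequencies_from_vtl(17.7, 11)])
        out = extend_formants(user, 17.7, nyquist=11025.0)
        assert len(out.formants) == 11

    def test_temperature_zero_disables_extension(self):
        user = FormantTable([Formant.at(500.0)])
        out = extend_formants(user, 17.7, nyquist=11025.0, temperature=0.0)
        assert len(out.formants) == 1


class TestMouthOpening:
    def test_neutral_position_no_shift(self):
        table = FormantTable([Formant.at(500.0), Formant.at(1500.0)])
        frames = adjust_for_mouth(table, mouth_contour(0.5), 17.7)
        for ft in frames:
            assert np.allclose(ft.frequencies_at(0.0), [500, 1500])

    def test_fully_open_shift(self):
        table = FormantTable([Formant.at(500.0), Formant.at(1500.0)])
        frames = adjust_for_mouth(table, mouth_contour(1.0), 17.7)
        assert np.allclose(frames[0].frequencies_at(0.0), [750, 1750])

    def test_fully_closed_shift_and_nasalization(self):
        table = FormantTable([Formant.at(500.0), Formant.at(1500.0)])
        frames = adjust_for_mouth(table, mouth_contour(0.0), 17.7)
        poles = [f for f in frames[0].formants if not f.is_zero]
        zeros = [f for f in frames[0].formants if f.is_zero]
        f1 = min(poles, key=lambda f: f.frequency.anchors[0].value)
        assert f1.frequency.anchors[0].value == pytest.approx(250.0)
        assert f1.bandwidth_hz == NASAL_F1_BANDWIDTH
        assert len(zeros) == 1  # one zero-pole pair near F1
        assert len(poles) == 3

    def test_shift_linear_in_mouth_and_equal_across_formants(self):
        table = FormantTable([Formant.at(500.0), Formant.at(1500.0), Formant.at(2500.0)])
        slope = SPEED_OF_SOUND / (4 * 17.7)
        for m in (0.1, 0.35, 0.8):
            frames = adjust_for_mouth(table, mouth_contour(m), 17.7)
            shifts = frames[0].frequencies_at(0.0) - np.array([500, 1500, 2500])
            assert np.allclose(shifts, (m - 0.5) * slope)

    def test_out_of_range_mouth_rejected(self):
        table = FormantTable([Formant.at(500.0)])
        bad = mouth_contour(0.5)
        bad.values[:] = 1.5
        with pytest.raises(ValueError):
            adjust_for_mouth(table, bad, 17.7)


class TestBandwidth:
    def test_positive_everywhere(self):
        f = np.geomspace(30, 10000, 100)
        assert np.all(estimate_bandwidth(f) > 0)

    def test_low_frequency_correction_widens(self):
        assert estimate_bandwidth(200.0) > estimate_bandwidth(500.0)
        grid = np.linspace(60, 499, 200)
        assert np.all(np.diff(estimate_bandwidth(grid)) < 0)

    def test_continuous_at_500(self):
        assert estimate_bandwidth(499.999) == pytest.approx(
            estimate_bandwidth(500.001), rel=1e-3
        )

    def test_user_bandwidth_overrides_estimator(self):
        table = FormantTable([Formant.at(500.0, bandwidth_hz=90.0)])
        env = compute_spectral_envelope(table, SR, radiation=None)
        # envelope peak sharper than the estimator's default would give:
        table2 = FormantTable([Formant.at(500.0)])
        env2 = compute_spectral_envelope(table2, SR, radiation=None)
        assert not np.allclose(env.gains, env2.gains)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            estimate_bandwidth(0.0)


class TestSpectralEnvelope:
    def test_empty_table_unity(self):
        env = compute_spectral_envelope(FormantTable(), SR, radiation=None)
        assert np.allclose(env.gains, 1.0)

    def test_single_formant_argmax(self):
        env = compute_spectral_envelope(
            FormantTable([Formant.at(500.0, bandwidth_hz=50.0)]), SR, radiation=None
        )
        freqs = bin_frequencies(SR)
        peak_bin = np.argmax(env.gains[:, 0])
        assert abs(freqs[peak_bin] - 500.0) <= SR / 1024

    def test_pole_zero_cancellation(self):
        table = FormantTable(
            [
                Formant.at(1000.0, bandwidth_hz=80.0),
                Formant.at(1000.0, bandwidth_hz=80.0, is_zero=True),
            ]
        )
        env = compute_spectral_envelope(table, SR, radiation=None)
        db = 20 * np.log10(env.gains[:, 0])
        assert np.all(np.abs(db) < 0.1)

    def test_formant_amp_db_moves_peak_level(self):
        base = compute_spectral_envelope(
            FormantTable([Formant.at(800.0, bandwidth_hz=80.0)]), SR, radiation=None
        )
        boosted = compute_spectral_envelope(
            FormantTable([Formant.at(800.0, bandwidth_hz=80.0, amp_db=6.0)]), SR, radiation=None
        )
        gain_db = 20 * (np.log10(boosted.gains.max()) - np.log10(base.gains.max()))
        assert gain_db == pytest.approx(6.0, abs=0.5)

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            compute_spectral_envelope(
                FormantTable([Formant.at(500.0, bandwidth_hz=0.0)]), SR, radiation=None
            )

    def test_lip_radiation_tilts_spectrum(self):
        tract = VocalTractParams(lip_radiation=6.0)
        env = compute_spectral_envelope(FormantTable(), SR, radiation=tract)
        freqs = bin_frequencies(SR)
        db = 20 * np.log10(env.gains[:, 0])
        i1, i2 = np.argmin(np.abs(freqs - 1000)), np.argmin(np.abs(freqs - 2000))
        assert db[i2] - db[i1] == pytest.approx(6.0, abs=0.5)


class TestApplyFilter:
    def make_tone(self, seconds=0.4):
        p = GlottalSourceParams(f0_contour=flat_f0(150.0), rolloff=3.0)
        track = compute_f0_track(p, seconds, SR)
        return synthesize_voiced(track, p, SR)

    def test_unity_envelope_reconstruction(self):
        x = self.make_tone()
        env = SpectralEnvelope(np.ones((N_BINS, 4)), SR / 1024, 256 / SR)
        y = apply_filter(x, env)
        err = np.sqrt(np.mean((y.samples - x.samples) ** 2) / np.mean(x.samples**2))
        assert err < 1e-3

    def test_zero_envelope_silence(self):
        x = self.make_tone()
        env = SpectralEnvelope(np.zeros((N_BINS, 4)), SR / 1024, 256 / SR)
        assert np.allclose(apply_filter(x, env).samples, 0.0)

    def test_noise_through_formant_peaks_at_its_frequency(self):
        rng = np.random.default_rng(2)
        x = Waveform(rng.standard_normal(int(SR)), SR)
        env = compute_spectral_envelope(
            FormantTable([Formant.at(2000.0, bandwidth_hz=100.0)]), SR, radiation=None
        )
        y = apply_filter(x, env)
        f, psd = welch(y.samples, fs=SR, nperseg=1024)
        assert abs(f[np.argmax(psd)] - 2000.0) <= SR / 1024

    def test_linearity(self):
        x = self.make_tone()
        rng = np.random.default_rng(3)
        y = Waveform(rng.standard_normal(len(x.samples)), SR)
        env = compute_spectral_envelope(
            FormantTable([Formant.at(900.0, bandwidth_hz=120.0)]), SR, radiation=None
        )
        lhs = apply_filter(Waveform(2.0 * x.samples + 0.5 * y.samples, SR), env)
        rhs = 2.0 * apply_filter(x, env).samples + 0.5 * apply_filter(y, env).samples
        assert np.allclose(lhs.samples, rhs, atol=1e-9)

    def test_geometry_mismatch_rejected(self):
        x = self.make_tone()
        env = SpectralEnvelope(np.ones((64, 4)), SR / 126, 256 / SR)
        with pytest.raises(ValueError):
            apply_filter(x, env)

    def test_formant_fidelity_end_to_end(self):
        # flat 100-Hz pitch so harmonics fall exactly on the target formants
        p = GlottalSourceParams(f0_contour=flat_f0(100.0), rolloff=2.0)
        track = compute_f0_track(p, 1.0, SR)
        raw = synthesize_voiced(track, p, SR)
        env = compute_spectral_envelope(
            FormantTable(
                [Formant.at(700.0, bandwidth_hz=80.0),
                 Formant.at(1200.0, bandwidth_hz=90.0),
                 Formant.at(2600.0, bandwidth_hz=120.0)]
            ),
            SR,
            radiation=None,
        )
        out = apply_filter(raw, env)
        f, psd = welch(out.samples, fs=SR, nperseg=4096)
        db = 10 * np.log10(np.maximum(psd, 1e-30))
        for target in (700.0, 1200.0, 2600.0):
            band = (f > target - 300) & (f < target + 300)
            peak = f[band][np.argmax(db[band])]
            assert abs(peak - target) <= 50.0
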