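import numpy as np
import pytest

from hetsim import (
    LocalOscillator,
    PhaseSet,
    SampleImage,
    acquire,
    bitmap_stack,
    effective_otf,
    heterodyne_reconstruct,
    ism_reassign,
    multifocal_stack,
    oscillator_sinusoid,
    oscillator_whiten,
    raster_offsets,
    sinusoidal_stack,
    wiener_deconvolve,
    widefield,
)
from hetsim.phantoms import measure_fwhm, spectral_extension_db

GRID = (128, 128)
PX = 20.0


def peak_magnitudes(frame, n):
    F = np.abs(np.fft.fft2(frame))
    return np.sort(F.ravel())[::-1][:n]


class TestOscillatorSinusoid:
    def test_two_beam_three_equal_peaks(self, three_phases, pattern_freq):
        osc = oscillator_sinusoid(pattern_freq, 0.3, three_phases, GRID, PX)
        peaks = peak_magnitudes(osc.frames[0], 4)
        assert peaks[0] == pytest.approx(peaks[1], rel=1e-9)
        assert peaks[1] == pytest.approx(peaks[2], rel=1e-9)
        assert peaks[3] < 1e-9 * peaks[0]

    def test_three_beam_five_equal_peaks(self, five_phases, pattern_freq):
        osc = oscillator_sinusoid(pattern_freq, 0.3, five_phases, GRID, PX,
                                  n_beams=3)
        peaks = peak_magnitudes(osc.frames[0], 6)
        assert peaks[0] == pytest.approx(peaks[4], rel=1e-9)
        assert peaks[5] < 1e-9 * peaks[0]

    def test_dc_is_one(self, three_phases, pattern_freq):
        osc = oscillator_sinusoid(pattern_freq, 0.3, three_phases, GRID, PX)
        for m in osc.frames:
            assert m.mean() == pytest.approx(1.0, abs=1e-12)

    def test_bad_phases_rejected_with_order(self, pattern_freq):
        with pytest.raises(ValueError, match="order 2"):
            oscillator_sinusoid(pattern_freq, 0.0, PhaseSet([0.0, np.pi]),
                                GRID, PX)

    def test_three_beam_needs_orders_up_to_four(self, pattern_freq):
        with pytest.raises(ValueError, match="order"):
            oscillator_sinusoid(pattern_freq, 0.0, PhaseSet.equal_steps(3),
                                GRID, PX, n_beams=3)


class TestOscillatorWhiten:
    def test_sinusoid_whitens_to_analytic(self, three_phases, pattern_freq):
        ill = sinusoidal_stack(pattern_freq, 0.3, three_phases, GRID, PX)
        osc_w = oscillator_whiten(ill.frames)
        osc_a = oscillator_sinusoid(pattern_freq, 0.3, three_phases, GRID, PX)
        for w, a in zip(osc_w.frames, osc_a.frames):
            assert np.abs(w - a).max() < 1e-9

    def test_uniform_pattern_gives_dc_only(self):
        osc = oscillator_whiten(np.full(GRID, 2.0))
        assert np.allclose(osc.frames[0], 1.0, atol=1e-12)

    def test_lattice_phases_preserved(self, exc_tf):
        offsets = raster_offsets(640.0, 4)
        ill = multifocal_stack(640.0, offsets, exc_tf, GRID, PX)
        osc = oscillator_whiten(ill.frames)
        F_in = np.fft.fft2(ill.frames[3])
        F_out = np.fft.fft2(osc.frames[3])
        strong = np.abs(F_in) > 0.05 * np.abs(F_in).max()
        # retained peaks keep their phases and are equalized in magnitude
        assert np.allclose(np.angle(F_in[strong]), np.angle(F_out[strong]),
                           atol=1e-6)
        mags = np.abs(F_out[strong])
        assert mags.max() == pytest.approx(mags.min(), rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            oscillator_whiten(np.zeros(GRID))


class TestHeterodyne:
    def test_point_source_spectrum_is_weighted_otf_sum(
        self, det_tf, point_sample, three_phases, pattern_freq
    ):
        ill = sinusoidal_stack(pattern_freq, 0.3, three_phases, GRID, PX)
        stack = acquire(point_sample, ill, det_tf)
        osc = oscillator_sinusoid(pattern_freq, 0.3, three_phases, GRID, PX)
        res = heterodyne_reconstruct(stack, osc, det_tf)
        got = np.fft.fft2(res.image)
        assert np.abs(got - res.effective_otf).max() < 1e-6 * np.abs(
            res.effective_otf
        ).max()

    def test_frame_count_mismatch_rejected(self, det_tf, point_sample,
                                           three_phases, pattern_freq):
        ill = sinusoidal_stack(pattern_freq, 0.3, three_phases, GRID, PX)
        stack = acquire(point_sample, ill, det_tf)
        osc = oscillator_sinusoid(pattern_freq, 0.3, PhaseSet.equal_steps(4),
                                  GRID, PX)
        with pytest.raises(ValueError, match="mismatch"):
            heterodyne_reconstruct(stack, osc)

    def test_two_phase_cross_terms_survive(self, det_tf, periodic_sample,
                                           pattern_freq):
        # with only two phases the first-order sum cancels but the
        # second-order sum equals 2, leaving S(k+-2p)H(k+-p) terms
        from hetsim.patterns import snap_frequency, spatial_grids

        pv = snap_frequency(
            (pattern_freq * np.sin(0.4), pattern_freq * np.cos(0.4)), GRID, PX
        )
        Y, X = spatial_grids(GRID, PX)
        u0 = 2 * np.pi * (pv[0] * Y + pv[1] * X)

        def recon(phases):
            ps = PhaseSet(phases, orders_required=[1])
            ill = sinusoidal_stack(pattern_freq, 0.4, ps, GRID, PX)
            stack = acquire(periodic_sample, ill, det_tf)
            osc = LocalOscillator(
                frames=[1 + 2 * np.cos(u0 + phi) for phi in ps.phases],
                provenance="analytic_sinusoid", p=pv, phases=list(ps.phases),
                n_beams=2, pixel_nm=PX,
            )
            m = len(phases)
            ideal = np.fft.fft2(periodic_sample.density) * effective_otf(
                det_tf, pv, 2, m
            )
            got = np.fft.fft2(heterodyne_reconstruct(stack, osc).image)
            return np.abs(got - ideal).max() / np.abs(ideal).max()

        assert recon([0, np.pi]) > 1e-3
        assert recon(list(PhaseSet.equal_steps(3).phases)) < 1e-8

    def test_spectral_extension_beyond_cutoff(self, det_tf, periodic_sample,
                                              three_phases, pattern_freq):
        ill = sinusoidal_stack(pattern_freq, 0.4, three_phases, GRID, PX)
        stack = acquire(periodic_sample, ill, det_tf)
        osc = oscillator_sinusoid(pattern_freq, 0.4, three_phases, GRID, PX)
        rec = heterodyne_reconstruct(stack, osc).image
        raw = np.sum(stack.frames, axis=0)
        db = spectral_extension_db(
            rec, raw, PX, det_tf.k_cutoff * 1.05,
            det_tf.k_cutoff + 0.95 * pattern_freq, direction=ill.p,
        )
        assert db >= 20.0


class TestEffectiveOtf:
    def test_support_extends_by_pattern_frequency(self, det_tf, three_phases,
                                                  pattern_freq):
        pv = (0.0, pattern_freq)
        eff = effective_otf(det_tf, pv, 2, 3)
        k = np.fft.fftfreq(GRID[1], PX)
        line = np.abs(eff[0])
        assert line[np.abs(k) > det_tf.k_cutoff + pattern_freq + 2 / (
            GRID[1] * PX
        )].max() < 1e-9
        inside = (np.abs(k) > det_tf.k_cutoff) & (
            np.abs(k) < det_tf.k_cutoff + 0.9 * pattern_freq
        )
        assert line[inside].max() > 1e-3

    def test_zero_frequency_degenerate(self, det_tf):
        eff = effective_otf(det_tf, (0.0, 0.0), 2, 3)
        assert np.abs(eff - 2 * 3 * det_tf.otf).max() < 1e-12


@pytest.fixture(scope="module")
def ism_stack(exc_tf, det_tf):
    sample = np.zeros(GRID)
    sample[64, 64] = 1.0
    offsets = raster_offsets(GRID[0] * PX, 16)
    ill = multifocal_stack(GRID[0] * PX, offsets, exc_tf, GRID, PX)
    return acquire(SampleImage(sample, PX), ill, det_tf)


class TestIsmReassign:
    def test_point_source_sharper_than_widefield(self, ism_stack, det_tf):
        out = ism_reassign(ism_stack, beta=510 / 488)
        sample = np.zeros(GRID)
        sample[64, 64] = 1.0
        wf = widefield(SampleImage(sample, PX), det_tf)
        assert measure_fwhm(out, pixel_nm=PX / 2) < 0.8 * measure_fwhm(
            wf, pixel_nm=PX
        )

    def test_uniform_sample_stays_uniform(self, exc_tf, det_tf):
        # 80 nm scan step: Nyquist-fine relative to the 208 nm spot FWHM
        offsets = raster_offsets(GRID[0] * PX, 32)
        ill = multifocal_stack(GRID[0] * PX, offsets, exc_tf, GRID, PX)
        stack = acquire(SampleImage(np.ones(GRID), PX), ill, det_tf)
        out = ism_reassign(stack, beta=1.0)
        assert (out.max() - out.min()) / out.mean() < 0.01

    def test_missing_scan_metadata_rejected(self, det_tf, point_sample,
                                            three_phases, pattern_freq):
        ill = sinusoidal_stack(pattern_freq, 0.0, three_phases, GRID, PX)
        stack = acquire(point_sample, ill, det_tf)
        with pytest.raises(ValueError, match="scan_offsets"):
            ism_reassign(stack)


class TestArbitraryPatternReconstruction:
    def test_scanned_spot_beats_raw_sum(self, exc_tf, det_tf):
        # ISM via the whitened-oscillator route: a delta bitmap scanned
        # over the grid reconstructs a point source sharper than the sum
        bmp = np.zeros(GRID)
        bmp[0, 0] = 1.0
        offsets = raster_offsets(GRID[0] * PX, 16)
        ill = bitmap_stack(bmp, offsets, exc_tf, PX)
        sample = np.zeros(GRID)
        sample[64, 64] = 1.0
        stack = acquire(SampleImage(sample, PX), ill, det_tf)
        osc = oscillator_whiten(ill.frames)
        rec = heterodyne_reconstruct(stack, osc).image
        raw = np.sum(stack.frames, axis=0)
        assert measure_fwhm(rec, pixel_nm=PX) < measure_fwhm(raw, pixel_nm=PX)


class TestWiener:
    def test_in_support_recovery(self, det_tf, periodic_sample):
        img = widefield(periodic_sample, det_tf)
        dec = wiener_deconvolve(img, det_tf.otf, w=1e-6)
        S = np.fft.fft2(periodic_sample.density)
        D = np.fft.fft2(dec)
        k = np.fft.fftfreq(GRID[0], PX)
        KY, KX = np.meshgrid(k, k, indexing="ij")
        core = np.hypot(KY, KX) < 0.5 * det_tf.k_cutoff
        assert (
            np.abs(D[core] - S[core]).max() / np.abs(S[core]).max() < 1e-3
        )

    def test_real_in_real_out(self, det_tf, periodic_sample):
        img = widefield(periodic_sample, det_tf)
        out = wiener_deconvolve(img, det_tf.otf, w=1e-3)
        assert np.isrealobj(out)

    def test_large_regularization_kills_output(self, det_tf, periodic_sample):
        img = widefield(periodic_sample, det_tf)
        out = wiener_deconvolve(img, det_tf.otf, w=1e12)
        assert np.abs(out).max() < 1e-6 * np.abs(img).max()
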