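"""FLASH forward model and the four map estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mpmaging as m
from mpmaging.flash import flash_signal, fit_r2star_loglinear, average_echoes


def rational_forward(protocol, weighting, amplitude, r1, r2star, delta=0.0, f_t=1.0):
    """Per-echo rational-model signals for one weighting (test-side helper)."""
    w = protocol.weightings[weighting]
    return np.stack([
        flash_signal(amplitude, r1, r2star, w.flip_rad * f_t, w.tr_s, te, delta)
        for te in w.te_s
    ], axis=-1)


class TestFlashSignal:
    def test_zero_amplitude_gives_zero_signal(self):
        assert flash_signal(0.0, 1.0, 20.0, 0.1, 0.0237, 0.005) == 0.0

    def test_rational_value_at_protocol_settings(self):
        # A=100, R1=1/s, TE=0, 6 deg / 23.7 ms: S = A*a*TR*R1/(a^2/2 + TR*R1)
        a = math.radians(6.0)
        expected = 100 * a * 0.0237 / (a**2 / 2 + 0.0237)
        s = flash_signal(100.0, 1.0, 0.0, a, 0.0237, 0.0, model="rational")
        assert s == pytest.approx(expected, rel=1e-12)
        assert s == pytest.approx(8.50, abs=0.01)

    def test_rational_close_to_ernst_at_small_angle(self):
        a = math.radians(6.0)
        s_rat = flash_signal(100.0, 1.0, 0.0, a, 0.0237, 0.0, model="rational")
        s_ern = flash_signal(100.0, 1.0, 0.0, a, 0.0237, 0.0, model="ernst")
        assert s_rat == pytest.approx(s_ern, rel=5e-3)

    def test_ernst_angle_maximizes_ernst_signal(self):
        tr, r1 = 0.0237, 1.0
        ernst = math.acos(math.exp(-tr * r1))
        angles = np.linspace(0.01, math.pi / 2, 2000)
        signals = flash_signal(1.0, r1, 0.0, angles, tr, 0.0, model="ernst")
        assert angles[np.argmax(signals)] == pytest.approx(ernst, abs=2e-3)

    @pytest.mark.parametrize("bad", [
        dict(amplitude=1, r1=-1, r2star=0, alpha_rad=0.1, tr_s=0.02, te_s=0.0),
        dict(amplitude=1, r1=1, r2star=0, alpha_rad=-0.1, tr_s=0.02, te_s=0.0),
        dict(amplitude=1, r1=1, r2star=0, alpha_rad=0.1, tr_s=-0.02, te_s=0.0),
        dict(amplitude=1, r1=1, r2star=0, alpha_rad=0.1, tr_s=0.02, te_s=-1e-3),
    ])
    def test_nonphysical_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            flash_signal(**bad)

    def test_ernst_model_rejects_mt_term(self):
        with pytest.raises(ValueError):
            flash_signal(1.0, 1.0, 0.0, 0.1, 0.02, 0.0, mt_sat_pu=2.0, model="ernst")

    @given(a1=st.floats(0.1, 100), a2=st.floats(0.1, 100))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_monotone_in_amplitude(self, a1, a2):
        lo, hi = sorted((a1, a2))
        s_lo = flash_signal(lo, 1.0, 10.0, 0.1, 0.0237, 0.005)
        s_hi = flash_signal(hi, 1.0, 10.0, 0.1, 0.0237, 0.005)
        assert s_lo <= s_hi


class TestR2StarFit:
    def test_constant_signal_gives_zero_rate(self, protocol):
        te = protocol.pdw.te_s
        r2, _, valid = fit_r2star_loglinear(np.full(len(te), 50.0), te)
        assert valid
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_exact_exponential_recovered(self, protocol):
        te = np.array(protocol.pdw.te_s)
        sig = 50.0 * np.exp(-20.0 * te)
        r2, intercept, valid = fit_r2star_loglinear(sig, te)
        assert r2 == pytest.approx(20.0, rel=1e-12)
        assert np.exp(intercept) == pytest.approx(50.0, rel=1e-12)

    def test_amplitude_scale_invariance(self, protocol, rng):
        te = np.array(protocol.pdw.te_s)
        sig = rng.uniform(10, 100, (40, 1)) * np.exp(-15.0 * te)
        r2, _, _ = fit_r2star_loglinear(sig, te)
        assert np.allclose(r2, 15.0, rtol=1e-10)

    def test_nonpositive_echo_masks_voxel(self, protocol):
        te = np.array(protocol.pdw.te_s)
        sig = np.tile(50.0 * np.exp(-20.0 * te), (2, 1))
        sig[1, 3] = -1.0
        r2, _, valid = fit_r2star_loglinear(sig, te)
        assert valid[0] and not valid[1]
        assert np.isnan(r2[1])

    def test_single_echo_rejected(self):
        with pytest.raises(ValueError):
            fit_r2star_loglinear(np.array([5.0]), [0.01])

    def test_monte_carlo_mean_within_two_percent(self, protocol, rng):
        te = np.array(protocol.pdw.te_s)
        clean = 50.0 * np.exp(-20.0 * te)
        noisy = clean + rng.normal(0, 1.0, (10_000, te.size))  # SNR 50 at TE=0
        r2, _, valid = fit_r2star_loglinear(noisy, te)
        assert valid.mean() > 0.99
        assert np.nanmean(r2[valid]) == pytest.approx(20.0, rel=0.02)


class TestAverageEchoes:
    def test_effective_te_of_common_echo_train(self, protocol):
        vol = np.ones((3, len(protocol.pdw.te_s)))
        _, te_eff = average_echoes(vol, protocol.pdw.te_s,
                                   len(protocol.common_echoes_ms()))
        assert te_eff * 1e3 == pytest.approx(8.45, abs=1e-12)

    def test_single_echo_is_identity(self):
        vol = np.arange(6.0).reshape(2, 3, 1)
        avg, te = average_echoes(vol, [0.005])
        assert np.array_equal(avg, vol[..., 0])
        assert te == 0.005

    def test_equal_echo_images_average_to_themselves(self, rng):
        img = rng.uniform(1, 2, (4, 4))
        vol = np.repeat(img[..., None], 5, axis=-1)
        avg, _ = average_echoes(vol, np.linspace(2e-3, 10e-3, 5))
        assert np.allclose(avg, img)


class TestR1Amplitude:
    def test_noiseless_rational_round_trip(self, protocol, rng):
        r1 = rng.uniform(0.3, 1.5, 200)
        amp = rng.uniform(50, 120, 200)
        s_pd = flash_signal(amp, r1, 0.0, protocol.pdw.flip_rad,
                            protocol.pdw.tr_s, 0.0)
        s_t1 = flash_signal(amp, r1, 0.0, protocol.t1w.flip_rad,
                            protocol.t1w.tr_s, 0.0)
        est_r1, est_a, valid = m.estimate_r1_amplitude(s_pd, s_t1, protocol)
        assert valid.all()
        assert np.allclose(est_r1, r1, rtol=1e-10)
        assert np.allclose(est_a, amp, rtol=1e-10)

    def test_b1_corrected_recovery_and_uncorrected_bias(self, protocol):
        f_t, r1_true, amp = 0.85, 1.0, 100.0
        s_pd = flash_signal(amp, r1_true, 0.0, protocol.pdw.flip_rad * f_t,
                            protocol.pdw.tr_s, 0.0)
        s_t1 = flash_signal(amp, r1_true, 0.0, protocol.t1w.flip_rad * f_t,
                            protocol.t1w.tr_s, 0.0)
        r1_corr, a_corr, _ = m.estimate_r1_amplitude(s_pd, s_t1, protocol, f_t=f_t)
        assert float(r1_corr) == pytest.approx(r1_true, rel=1e-10)
        assert float(a_corr) == pytest.approx(amp, rel=1e-10)
        # uncorrected: nominal angles overstate the true flip, inflating R1
        # by 1/f_T^2 in the rational model
        r1_raw, _, _ = m.estimate_r1_amplitude(s_pd, s_t1, protocol, f_t=1.0)
        assert float(r1_raw) > r1_true
        assert float(r1_raw) == pytest.approx(r1_true / f_t**2, rel=1e-10)

    def test_receive_field_scale_cancels_in_r1(self, protocol):
        s_pd = flash_signal(80.0, 0.9, 0.0, protocol.pdw.flip_rad,
                            protocol.pdw.tr_s, 0.0)
        s_t1 = flash_signal(80.0, 0.9, 0.0, protocol.t1w.flip_rad,
                            protocol.t1w.tr_s, 0.0)
        r1_a, _, _ = m.estimate_r1_amplitude(s_pd, s_t1, protocol)
        r1_b, _, _ = m.estimate_r1_amplitude(1.3 * s_pd, 1.3 * s_t1, protocol)
        assert float(r1_a) == pytest.approx(float(r1_b), rel=1e-12)

    def test_ernst_forward_bias_grows_with_flip_angle(self, protocol):
        """Rational-model inversion of exact Ernst signals: small-angle bias
        increases monotonically as the T1w flip angle grows."""
        import dataclasses
        r1_true, biases = 1.0, []
        for alpha in (10.0, 20.0, 40.0):
            t1w = dataclasses.replace(protocol.t1w, flip_deg=alpha)
            prot = m.AcquisitionProtocol(pdw=protocol.pdw, t1w=t1w,
                                         mtw=protocol.mtw)
            s_pd = flash_signal(100.0, r1_true, 0.0, prot.pdw.flip_rad,
                                prot.pdw.tr_s, 0.0, model="ernst")
            s_t1 = flash_signal(100.0, r1_true, 0.0, prot.t1w.flip_rad,
                                prot.t1w.tr_s, 0.0, model="ernst")
            est, _, _ = m.estimate_r1_amplitude(s_pd, s_t1, prot)
            biases.append(abs(float(est) - r1_true) / r1_true)
        assert biases[0] < biases[1] < biases[2]
        assert biases[1] < 0.05  # protocol settings stay in the small-angle regime

    def test_negative_denominator_masked(self, protocol):
        # S_PD/a_PD below S_T1/a_T1 violates the flip-angle ordering -> masked
        _, _, valid = m.estimate_r1_amplitude(1.0, 100.0, protocol)
        assert not valid


class TestMTSat:
    def test_zero_saturation_estimated_as_zero(self, protocol):
        amp, r1 = 90.0, 1.1
        s_mt = flash_signal(amp, r1, 0.0, protocol.mtw.flip_rad,
                            protocol.mtw.tr_s, 0.0, 0.0)
        delta, valid, _ = m.estimate_mt_sat(s_mt, amp, r1, protocol)
        assert valid
        assert float(delta) == pytest.approx(0.0, abs=1e-10)

    def test_round_trip_two_percent_units(self, protocol):
        amp, r1, d_true = 90.0, 1.1, 2.0
        s_mt = flash_signal(amp, r1, 0.0, protocol.mtw.flip_rad,
                            protocol.mtw.tr_s, 0.0, d_true)
        delta, _, _ = m.estimate_mt_sat(s_mt, amp, r1, protocol)
        assert float(delta) == pytest.approx(d_true, rel=1e-10)

    def test_invariant_to_global_receive_scale(self, protocol):
        """MT saturation depends only on signal ratios: a common x1.1 receive
        scale on all three weightings leaves the estimate unchanged."""
        amp, r1, d_true, g = 90.0, 1.1, 1.5, 1.1
        s_pd = flash_signal(amp, r1, 0.0, protocol.pdw.flip_rad,
                            protocol.pdw.tr_s, 0.0)
        s_t1 = flash_signal(amp, r1, 0.0, protocol.t1w.flip_rad,
                            protocol.t1w.tr_s, 0.0)
        s_mt = flash_signal(amp, r1, 0.0, protocol.mtw.flip_rad,
                            protocol.mtw.tr_s, 0.0, d_true)
        out = []
        for scale in (1.0, g):
            r1_est, a_est, _ = m.estimate_r1_amplitude(scale * s_pd, scale * s_t1,
                                                       protocol)
            d_est, _, _ = m.estimate_mt_sat(scale * s_mt, a_est, r1_est, protocol)
            out.append(float(d_est))
        assert out[0] == pytest.approx(out[1], rel=1e-10)

    def test_negative_estimates_clamped_and_counted(self, protocol):
        amp, r1 = 90.0, 1.1
        s_mt = flash_signal(amp, r1, 0.0, protocol.mtw.flip_rad,
                            protocol.mtw.tr_s, 0.0, 0.0)
        delta, _, n_clamped = m.estimate_mt_sat(
            np.array([s_mt * 1.05]), amp, r1, protocol)
        assert n_clamped == 1
        assert delta[0] == 0.0


class TestCalibratePD:
    def test_wm_mean_is_exactly_69(self, rng):
        a = rng.uniform(50, 150, (8, 8, 8))
        wm = np.zeros((8, 8, 8), bool)
        wm[2:6, 2:6, 2:6] = True
        pd, _ = m.calibrate_pd(a, wm)
        assert pd[wm].mean() == pytest.approx(69.0, abs=1e-9)

    def test_uniform_amplitude_scale_is_69_over_c(self):
        a = np.full((6, 6, 6), 42.0)
        wm = np.ones((6, 6, 6), bool)
        _, info = m.calibrate_pd(a, wm, receive_correct=False)
        assert info["scale"] == pytest.approx(69.0 / 42.0, rel=1e-12)

    def test_region_ratios_preserved_under_smooth_field(self):
        """Correcting a log-polynomial receive field restores inter-region
        amplitude ratios (GM/WM contrast) on a noiseless phantom."""
        shape = (16, 16, 16)
        x = np.linspace(-1, 1, 16)
        gx, gy, gz = np.meshgrid(x, x, x, indexing="ij")
        field = np.exp(0.3 * gx + 0.2 * gy * gz - 0.1 * gx**2)
        truth = np.full(shape, 69.0)
        gm_region = np.zeros(shape, bool)
        gm_region[10:14, 10:14, 10:14] = True
        truth[gm_region] = 83.0
        wm = ~gm_region
        wm &= np.ones(shape, bool)
        pd, _ = m.calibrate_pd(truth * field, wm, receive_correct=True)
        ratio = pd[gm_region].mean() / pd[wm].mean()
        assert ratio == pytest.approx(83.0 / 69.0, rel=1e-3)

    def test_empty_wm_mask_rejected(self):
        with pytest.raises(ValueError):
            m.calibrate_pd(np.ones((4, 4, 4)), np.zeros((4, 4, 4), bool))


class TestFullFit:
    def test_zero_noise_round_trip_all_parameters(self, protocol, geometry48,
                                                  zero_noise_aging):
        """Primary oracle: simulate the rational forward model with B1 and
        receive fields at zero noise; fitting recovers R1, R2*, MT saturation
        and the TE=0 amplitude to <= 1e-8 relative error."""
        spec = m.CohortSpec(noise_sd_frac=0.0)
        rng = np.random.default_rng(0)
        sub = m.sample_subject(spec, zero_noise_aging, geometry48, 30.0,
                               "M", 1, rng)
        vols = m.simulate_acquisition(sub, protocol, spec, rng)
        maps = m.fit_parameter_maps(
            vols.volumes["pdw"], vols.volumes["t1w"], vols.volumes["mtw"],
            protocol, f_t=vols.b1, wm_mask=geometry48.label_volume == 3,
            mt_b1_correct=True,
        )
        brain = geometry48.label_volume > 0
        assert maps.valid[brain].all()
        for est, tru in [(maps.r1, sub.maps["r1"]),
                         (maps.r2star, sub.maps["r2star"]),
                         (maps.a0, sub.maps["pd"] * np.asarray(vols.receive))]:
            rel = np.abs(est[brain] - tru[brain]) / np.abs(tru[brain])
            assert np.nanmax(rel) < 1e-8
        mt_err = np.abs(maps.mt_sat[brain] - sub.maps["mt_sat"][brain])
        denom = np.maximum(np.abs(sub.maps["mt_sat"][brain]), 1.0)
        assert np.max(mt_err / denom) < 1e-8
        assert np.nanmean(maps.pd_star[geometry48.label_volume == 3]) == \
            pytest.approx(69.0, abs=1e-6)

    def test_background_voxels_masked_not_crashed(self, protocol, geometry24,
                                                  zero_noise_aging):
        spec = m.CohortSpec(noise_sd_frac=0.02)
        rng = np.random.default_rng(1)
        sub = m.sample_subject(spec, zero_noise_aging, geometry24, 40.0, "F", 2, rng)
        vols = m.simulate_acquisition(sub, protocol, spec, rng)
        maps = m.fit_parameter_maps(vols.volumes["pdw"], vols.volumes["t1w"],
                                    vols.volumes["mtw"], protocol, f_t=vols.b1)
        background = geometry24.label_volume == 0
        assert maps.qc["n_valid"] < maps.qc["n_voxels"]
        assert np.isnan(maps.r1[background]).mean() > 0.4
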