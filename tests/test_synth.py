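import numpy as np
import pytest

from avieit import ForwardSolver, ScenarioConfig, simulate_recording
from avieit.geometry import LABEL_CODE
from avieit.synth import ConductivityMovie, breathing_waveform

FPS = 48.0


class TestScenarioConfig:
    def test_band_separability_enforced(self):
        with pytest.raises(ValueError, match="separable"):
            ScenarioConfig(rr=30.0, hr=100.0)

    def test_cardiac_fraction_bounded(self):
        with pytest.raises(ValueError):
            ScenarioConfig(cardiac_frac=0.5)

    def test_bad_recumbency_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(recumbency="upside_down")


class TestBreathingWaveform:
    def test_cycle_count(self):
        vol, bounds = breathing_waveform(2, 10, 120, FPS, seed=0)
        # 20 cycles started in 2 min at 10/min (+/- the 5% period jitter)
        assert 19 <= len(bounds) + 1 <= 21
        assert len(vol) == int(120 * FPS)

    def test_expiration_endpoints_normalised(self):
        for brp in (1, 2, 3, 4):
            vol, bounds = breathing_waveform(brp, 10, 60, FPS, seed=1)
            for i0, i1, i2 in bounds:
                assert vol[i1] > 0.97  # end-inspiration ~ full
                assert vol[i2] < 0.03  # end-expiration ~ empty
                assert vol[i0] < 0.03

    def test_volume_in_unit_interval(self):
        vol, _ = breathing_waveform(3, 12, 60, FPS, seed=2)
        assert vol.min() >= 0.0 and vol.max() <= 1.0

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            breathing_waveform(1, 10, 2.0, FPS, seed=0)


class TestConductivityMovie:
    def test_zero_shift_gains_symmetric(self, coarse_phantom):
        cfg = ScenarioConfig(shift=0.0)
        m = ConductivityMovie(coarse_phantom, np.array([0.0, 1.0]), cfg)
        assert np.allclose(m.airsac_gain, 1.0)

    def test_cardiac_frac_zero_keeps_cardiac_constant(self, coarse_phantom):
        cfg = ScenarioConfig(cardiac_frac=0.0, duration_s=30.0)
        vol = np.linspace(0, 1, 100)
        m = ConductivityMovie(coarse_phantom, vol, cfg)
        cardiac = coarse_phantom.elements_with_label("cardiac")
        s0, s1 = m[0][cardiac], m[50][cardiac]
        assert np.array_equal(s0, s1)

    def test_zero_volume_movie_constant(self, coarse_phantom):
        cfg = ScenarioConfig(cardiac_frac=0.0)
        m = ConductivityMovie(coarse_phantom, np.zeros(10), cfg)
        assert np.array_equal(m[0], m[9])
        assert np.allclose(m[0], cfg.sigma_base)

    def test_lungs_always_constant(self, coarse_phantom):
        cfg = ScenarioConfig(shift=0.3, recumbency="left_lateral")
        m = ConductivityMovie(coarse_phantom, np.linspace(0, 1, 20), cfg)
        lungs = np.concatenate(
            [coarse_phantom.elements_with_label("lung_r"),
             coarse_phantom.elements_with_label("lung_l")]
        )
        for i in (0, 10, 19):
            assert np.allclose(m[i][lungs], cfg.sigma_base)

    def test_nonphysical_amplitude_rejected(self, coarse_phantom):
        cfg = ScenarioConfig(tiv_scale=0.9, shift=0.5)
        with pytest.raises(ValueError, match="non-physical"):
            ConductivityMovie(coarse_phantom, np.zeros(5), cfg)

    def test_shift_gain_bounds_and_direction(self, coarse_phantom):
        cfg = ScenarioConfig(shift=0.3, recumbency="right_lateral")
        m = ConductivityMovie(coarse_phantom, np.zeros(2), cfg)
        assert m.airsac_gain.min() >= 1 - 0.3 - 1e-12
        assert m.airsac_gain.max() <= 1 + 0.3 + 1e-12
        cent = coarse_phantom.element_centroids()[coarse_phantom.elements_with_label("airsac")]
        # right lateral: non-dependent side is the left (+x); gain grows with x
        assert np.corrcoef(cent[:, 0], m.airsac_gain)[0, 1] > 0.99


class TestSimulateRecording:
    def test_same_seed_bit_identical(self, coarse_phantom):
        cfg = ScenarioConfig(duration_s=15.0, seed=123)
        r1, t1 = simulate_recording(coarse_phantom, cfg)
        r2, t2 = simulate_recording(coarse_phantom, cfg)
        assert np.array_equal(r1.voltages, r2.voltages)
        assert np.array_equal(t1.volume_curve, t2.volume_curve)

    def test_different_seed_differs(self, coarse_phantom):
        cfg1 = ScenarioConfig(duration_s=15.0, seed=1)
        cfg2 = ScenarioConfig(duration_s=15.0, seed=2)
        assert not np.array_equal(
            simulate_recording(coarse_phantom, cfg1)[0].voltages,
            simulate_recording(coarse_phantom, cfg2)[0].voltages,
        )

    def test_noise_does_not_perturb_breath_timing(self, coarse_phantom):
        base = dict(duration_s=15.0, seed=5)
        _, t0 = simulate_recording(coarse_phantom, ScenarioConfig(noise_sd=0.0, **base))
        _, t1 = simulate_recording(coarse_phantom, ScenarioConfig(noise_sd=0.05, **base))
        assert t0.breaths == t1.breaths
        assert np.array_equal(t0.volume_curve, t1.volume_curve)

    def test_interpolated_frames_match_direct_solve(self, coarse_phantom, pattern):
        cfg = ScenarioConfig(duration_s=15.0, noise_sd=0.0, seed=8, shift=0.2,
                             recumbency="dorsal")
        rec, truth = simulate_recording(coarse_phantom, cfg)
        movie = ConductivityMovie(coarse_phantom, truth.volume_curve, cfg)
        solver = ForwardSolver(coarse_phantom, pattern, cfg.current_a)
        for k in (3, 200, 500):
            exact = solver.solve(movie[k])
            err = np.max(np.abs(rec.voltages[k] - exact)) / np.max(np.abs(exact))
            assert err < 1e-9

    def test_reference_frame_is_end_expiration(self, coarse_phantom):
        cfg = ScenarioConfig(duration_s=15.0, seed=3)
        rec, truth = simulate_recording(coarse_phantom, cfg)
        assert rec.ref_frame == truth.breaths[0][0]
        assert truth.volume_curve[rec.ref_frame] < 0.05

    def test_detected_breath_count_matches_rate(self, coarse_sim):
        from avieit import detect_breaths, global_curve, remove_cardiac

        _, _, truth, stream = coarse_sim
        breaths = detect_breaths(remove_cardiac(global_curve(stream)))
        # 60 s at 10/min: 9-10 complete cycles, edge cycles may be dropped
        assert 8 <= len(breaths) <= 10
        rr = len(breaths) / (stream.n_frames / stream.fps) * 60
        assert abs(rr - 10) <= 2.0

    def test_doubling_amplitude_doubles_tiv(self, coarse_phantom, coarse_model):
        from avieit import detect_breaths, global_curve, reconstruct, remove_cardiac

        tivs = {}
        for a in (0.05, 0.1):
            cfg = ScenarioConfig(duration_s=30.0, noise_sd=0.0, tiv_scale=a, seed=6)
            rec, _ = simulate_recording(coarse_phantom, cfg)
            stream = reconstruct(
                coarse_model, rec.voltages[rec.ref_frame], rec.voltages, fps=rec.fps
            )
            breaths = detect_breaths(remove_cardiac(global_curve(stream)))
            tivs[a] = np.mean([b.tiv for b in breaths])
        assert tivs[0.1] / tivs[0.05] == pytest.approx(2.0, abs=0.1)
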