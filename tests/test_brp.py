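import numpy as np
import pytest

from avieit import (
    BrPLabel,
    GlobalCurve,
    classify_breath,
    classify_recording,
    detect_pause,
    extract_expiration,
)
from avieit.breaths import BreathSegment
from avieit.brp import ExpiratoryCurve
from avieit.synth import breathing_waveform

FPS = 48.0


def curve_from(z, duration_s=3.0):
    tau = np.linspace(0.0, 1.0, len(z))
    return ExpiratoryCurve(z_norm=np.asarray(z, float), tau=tau, duration_s=duration_s)


def plateau_curve(level=0.6, pause_s=0.5, total_s=3.5, fps=FPS):
    """Linear decay to ``level``, hold for ``pause_s``, linear decay to 0."""
    n_pause = int(round(pause_s * fps))
    n_rest = int(round((total_s - pause_s) * fps))
    n1 = int(round(n_rest * (1 - level)))  # steeper share before the pause
    n2 = n_rest - n1
    z = np.concatenate(
        [
            np.linspace(1.0, level, n1, endpoint=False),
            np.full(n_pause, level),
            np.linspace(level, 0.0, n2),
        ]
    )
    return curve_from(z, duration_s=total_s)


class TestExtractExpiration:
    def test_linear_decay_is_identity(self):
        z = np.linspace(5.0, 2.0, 50)
        c = GlobalCurve(z=z, fps=FPS, filtered=True)
        # segment runs from end-inspiration (index 1) to end-expiration
        e = extract_expiration(c, BreathSegment(0, 1, 49, tiv=3.0, t_insp=1 / FPS))
        assert np.allclose(e.z_norm, 1 - e.tau, atol=1e-9)

    def test_endpoints_normalised(self):
        rng = np.random.default_rng(0)
        z = np.sort(rng.uniform(0, 1, 30))[::-1].copy()
        c = GlobalCurve(z=np.concatenate([[z[0] - 1], z]), fps=FPS, filtered=True)
        e = extract_expiration(c, BreathSegment(0, 1, 30, tiv=1.0, t_insp=1 / FPS))
        assert e.z_norm[0] == 1.0 and e.z_norm[-1] == 0.0

    def test_too_short_rejected(self):
        c = GlobalCurve(z=np.linspace(1, 0, 10), fps=FPS, filtered=True)
        with pytest.raises(ValueError, match="too short"):
            extract_expiration(c, BreathSegment(0, 5, 7, tiv=1.0, t_insp=0.1))


class TestDetectPause:
    def test_exponential_decay_has_none(self):
        tau = np.linspace(0, 1, 170)
        z = (np.exp(-3 * tau) - np.exp(-3)) / (1 - np.exp(-3))
        assert detect_pause(curve_from(z, 3.5)) is None

    def test_constructed_plateau_level(self):
        pause = detect_pause(plateau_curve(level=0.6, pause_s=0.5))
        assert pause is not None
        assert pause.level == pytest.approx(0.60, abs=0.02)

    def test_short_plateau_rejected(self):
        assert detect_pause(plateau_curve(level=0.6, pause_s=0.2)) is None

    def test_concave_and_convex_have_none(self):
        tau = np.linspace(0, 1, 170)
        assert detect_pause(curve_from(1 - tau**2, 3.5)) is None
        assert detect_pause(curve_from((1 - tau) ** 2, 3.5)) is None


class TestClassifyBreath:
    def test_concave_is_brp1(self):
        tau = np.linspace(0, 1, 120)
        e = curve_from(1 - tau**2)
        assert classify_breath(e, detect_pause(e)).value == "BrP1"

    def test_convex_is_brp2(self):
        tau = np.linspace(0, 1, 120)
        e = curve_from((1 - tau) ** 2)
        assert classify_breath(e, detect_pause(e)).value == "BrP2"

    @pytest.mark.parametrize("level,expected", [(0.6, "BrP3"), (0.4, "BrP4")])
    def test_pause_level_splits_brp3_brp4(self, level, expected):
        e = plateau_curve(level=level)
        label = classify_breath(e, detect_pause(e))
        assert label.value == expected
        assert label.pause_level == pytest.approx(level, abs=0.02)

    def test_pause_level_presence_invariant(self):
        with pytest.raises(ValueError):
            BrPLabel("BrP3")
        with pytest.raises(ValueError):
            BrPLabel("BrP1", pause_level=0.7)

    def test_classification_invariant_to_scaling_and_resampling(self):
        for level, expected in ((0.6, "BrP3"), (0.4, "BrP4")):
            e = plateau_curve(level=level, total_s=4.0)
            # resample the expiration at a different rate
            tau2 = np.linspace(0, 1, 97)
            z2 = np.interp(tau2, e.tau, e.z_norm)
            e2 = ExpiratoryCurve(z2, tau2, duration_s=4.0)
            assert classify_breath(e2, detect_pause(e2)).value == expected


class TestClassifyRecording:
    def test_uniform_recordings(self):
        labels = [BrPLabel("BrP3", 0.62)] * 10
        assert classify_recording(labels).value == "BrP3"
        assert classify_recording([BrPLabel("BrP1")] * 20).value == "BrP1"

    def test_ninety_percent_is_mixed(self):
        labels = [BrPLabel("BrP3", 0.6)] * 9 + [BrPLabel("BrP2")]
        assert classify_recording(labels).value == "mixed"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_recording([])


class TestRoundTrip:
    @pytest.mark.parametrize("brp", [1, 2, 3, 4])
    def test_zero_noise_waveforms_recover_label(self, brp):
        for seed in (0, 1, 2):
            vol, bounds = breathing_waveform(brp, 10, 60, FPS, seed=seed)
            c = GlobalCurve(z=6.65 * vol, fps=FPS, filtered=True)
            for i0, i1, i2 in bounds:
                b = BreathSegment(i0, i1, i2, tiv=6.65 * (vol[i1] - vol[i0]),
                                  t_insp=(i1 - i0) / FPS)
                e = extract_expiration(c, b)
                assert classify_breath(e, detect_pause(e)).value == f"BrP{brp}"

    @pytest.mark.parametrize("brp", [1, 2, 3, 4])
    def test_flutter_and_noise_recover_95pct(self, brp):
        rng = np.random.default_rng(brp)
        vol, bounds = breathing_waveform(brp, 10, 120, FPS, seed=7 + brp)
        t = np.arange(len(vol)) / FPS
        tiv = 6.65
        z = tiv * vol + 0.03 * tiv * np.sin(2 * np.pi * 4.0 * t)
        z = z + rng.normal(0, 0.02 * tiv, len(z))
        from avieit import remove_cardiac

        c = remove_cardiac(GlobalCurve(z=z, fps=FPS))
        ok = 0
        for i0, i1, i2 in bounds:
            b = BreathSegment(i0, i1, i2, tiv=max(c.z[i1] - c.z[i0], 0.0),
                              t_insp=(i1 - i0) / FPS)
            e = extract_expiration(c, b)
            ok += classify_breath(e, detect_pause(e)).value == f"BrP{brp}"
        assert ok / len(bounds) >= 0.95
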