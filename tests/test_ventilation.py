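import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avieit import (
    centre_of_ventilation,
    regional_distribution,
    rl_ratio,
    tidal_image,
    variables_for_breaths,
)
from avieit.breaths import BreathSegment, detect_breaths, global_curve, remove_cardiac
from avieit.ventilation import REGION_NAMES, FunctionalImage, _bbox


def disk_mask(n=32):
    r, c = np.mgrid[0:n, 0:n]
    return (r - (n - 1) / 2) ** 2 + (c - (n - 1) / 2) ** 2 <= (n / 2 - 1.5) ** 2


@pytest.fixture
def mask():
    return disk_mask()


def image(mask, pixels):
    pix = np.where(mask, pixels, 0.0)
    return FunctionalImage(pixels=pix, mask=mask)


class TestCoV:
    def test_leftmost_column_gives_100(self, mask):
        r0, r1, c0, c1 = _bbox(mask)
        pix = np.zeros((32, 32))
        pix[mask[:, c1], c1] = 1.0
        assert centre_of_ventilation(image(mask, pix), "rl") == 100.0

    def test_rightmost_column_gives_0(self, mask):
        r0, r1, c0, c1 = _bbox(mask)
        pix = np.zeros((32, 32))
        pix[mask[:, c0], c0] = 1.0
        assert centre_of_ventilation(image(mask, pix), "rl") == 0.0

    def test_ventral_row_gives_0(self, mask):
        r0, r1, c0, c1 = _bbox(mask)
        pix = np.zeros((32, 32))
        pix[r1, mask[r1, :]] = 1.0  # highest row index = ventral-most
        assert centre_of_ventilation(image(mask, pix), "vd") == 0.0

    def test_mirror_symmetric_gives_50(self, mask):
        rng = np.random.default_rng(0)
        half = rng.uniform(0, 1, (32, 32))
        pix = half + half[:, ::-1]
        assert centre_of_ventilation(image(mask, pix), "rl") == pytest.approx(50.0, abs=1e-9)

    def test_all_zero_rejected(self, mask):
        with pytest.raises(ValueError, match="no ventilation"):
            centre_of_ventilation(image(mask, np.zeros((32, 32))), "rl")

    @given(seed=st.integers(0, 100), scale=st.floats(0.1, 50))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_and_mirror_equivariance(self, seed, scale):
        mask = disk_mask()
        rng = np.random.default_rng(seed)
        pix = np.where(mask, rng.uniform(-0.2, 1.0, (32, 32)), 0.0)
        f = FunctionalImage(pix, mask)
        fs = FunctionalImage(scale * pix, mask)
        fm = FunctionalImage(pix[:, ::-1].copy(), mask[:, ::-1].copy())
        assert centre_of_ventilation(fs, "rl") == pytest.approx(
            centre_of_ventilation(f, "rl"), abs=1e-9
        )
        assert centre_of_ventilation(fm, "rl") == pytest.approx(
            100 - centre_of_ventilation(f, "rl"), abs=1e-9
        )
        assert rl_ratio(fs) == pytest.approx(rl_ratio(f), rel=1e-12)
        assert rl_ratio(fm) == pytest.approx(1 / rl_ratio(f), rel=1e-9)
        reg = regional_distribution(f)
        reg_s = regional_distribution(fs)
        reg_m = regional_distribution(fm)
        for band in ("D", "CD", "CV", "V"):
            assert reg_s[f"R_{band}"] == pytest.approx(reg[f"R_{band}"], abs=1e-9)
            assert reg_m[f"R_{band}"] == pytest.approx(reg[f"L_{band}"], abs=1e-9)


class TestRLRatio:
    def test_symmetric_is_one(self, mask):
        rng = np.random.default_rng(1)
        half = rng.uniform(0, 1, (32, 32))
        assert rl_ratio(image(mask, half + half[:, ::-1])) == pytest.approx(1.0, abs=1e-9)

    def test_sixty_forty_split(self, mask):
        r0, r1, c0, c1 = _bbox(mask)
        pix = np.zeros((32, 32))
        # place 60% of signal on one right-side pixel, 40% on one left-side
        mid_row = (r0 + r1) // 2
        pix[mid_row, c0 + 1] = 60.0
        pix[mid_row, c1 - 1] = 40.0
        assert rl_ratio(image(mask, pix)) == pytest.approx(1.5, rel=1e-12)

    def test_right_only_signal_rejected(self, mask):
        r0, r1, c0, c1 = _bbox(mask)
        pix = np.zeros((32, 32))
        pix[(r0 + r1) // 2, c0 + 1] = 1.0
        with pytest.raises(ZeroDivisionError, match="RL ratio"):
            rl_ratio(image(mask, pix))


class TestRegionalDistribution:
    def test_sum_is_exactly_100(self, coarse_sim):
        _, _, truth, stream = coarse_sim
        curve = remove_cardiac(global_curve(stream))
        b = detect_breaths(curve)[0]
        reg = regional_distribution(tidal_image(stream, b))
        assert sum(reg.values()) == pytest.approx(100.0, abs=1e-9)
        assert set(reg) == set(REGION_NAMES)
        assert all(v >= 0 for v in reg.values())

    def test_single_region_gets_everything(self, mask):
        r0, r1, c0, c1 = _bbox(mask)
        pix = np.zeros((32, 32))
        pix[r0 + 1, 14] = 3.0  # dorsal band, just right of the midline
        assert mask[r0 + 1, 14]
        reg = regional_distribution(image(mask, pix))
        assert reg["R_D"] == pytest.approx(100.0, abs=1e-9)
        assert sum(v for k, v in reg.items() if k != "R_D") == pytest.approx(0.0, abs=1e-12)

    def test_uniform_image_matches_pixel_counts(self):
        # square mask: every pixel weight 1 -> region % = pixel-count share
        mask = np.zeros((32, 32), bool)
        mask[4:28, 4:28] = True
        pix = mask.astype(float)
        reg = regional_distribution(FunctionalImage(pix, mask))
        for name in REGION_NAMES:
            assert reg[name] == pytest.approx(100.0 / 8, abs=1e-9)


class TestTidalImageAndAggregation:
    def test_identical_frames_give_zero(self, coarse_sim):
        _, _, _, stream = coarse_sim
        b = BreathSegment(0, 1, 2, tiv=0.0, t_insp=1 / 48)
        img = tidal_image(
            type(stream)(
                frames=np.repeat(stream.frames[:1], 3, axis=0),
                fps=stream.fps,
                mask=stream.mask,
            ),
            b,
        )
        assert np.all(img.pixels == 0)

    def test_out_of_range_rejected(self, coarse_sim):
        _, _, _, stream = coarse_sim
        with pytest.raises(IndexError):
            tidal_image(stream, BreathSegment(0, 10**6, 10**6 + 1, tiv=1.0, t_insp=0.2))

    def test_tidal_sum_consistent_with_global_curve(self, fine_phantom, fine_model):
        from avieit import ScenarioConfig, reconstruct, simulate_recording

        cfg = ScenarioConfig(duration_s=30.0, noise_sd=0.0, seed=9)
        rec, _ = simulate_recording(fine_phantom, cfg)
        stream = reconstruct(
            fine_model, rec.voltages[rec.ref_frame], rec.voltages, fps=rec.fps
        )
        curve = remove_cardiac(global_curve(stream))
        b = detect_breaths(curve)[1]
        img = tidal_image(stream, b)
        raw = global_curve(stream).z
        raw_tiv = raw[b.i_end_insp] - raw[b.i_start_insp]
        # the signed in-mask sum equals the global-curve difference exactly
        assert img.pixels[img.mask].sum() == pytest.approx(raw_tiv, rel=1e-12)
        # clamping adds only the small negative reconstruction side lobes
        assert img.clamped.sum() == pytest.approx(raw_tiv, rel=0.01)

    def test_means_over_breaths(self, coarse_sim):
        _, _, _, stream = coarse_sim
        curve = remove_cardiac(global_curve(stream))
        breaths = detect_breaths(curve)
        df, means = variables_for_breaths(stream, breaths[:2])
        assert len(df) == 2
        assert means["cov_rl"] == pytest.approx(df["cov_rl"].mean())
        df1, means1 = variables_for_breaths(stream, breaths[:1])
        assert means1["cov_rl"] == df1["cov_rl"].iloc[0]

    def test_imposed_left_shift_raises_cov(self, coarse_phantom, coarse_model):
        from avieit import ScenarioConfig, reconstruct, simulate_recording

        covs = {}
        for shift in (0.0, 0.3):
            cfg = ScenarioConfig(
                duration_s=30.0, shift=shift, recumbency="right_lateral", seed=5
            )
            rec, _ = simulate_recording(coarse_phantom, cfg)
            stream = reconstruct(
                coarse_model, rec.voltages[rec.ref_frame], rec.voltages, fps=rec.fps
            )
            breaths = detect_breaths(remove_cardiac(global_curve(stream)))
            _, means = variables_for_breaths(stream, breaths)
            covs[shift] = means["cov_rl"]
        # right-lateral recumbency: non-dependent side is the left
        assert covs[0.3] > covs[0.0]
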