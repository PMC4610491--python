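"""Radon direction estimation, sinc length fitting, focus scoring, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blurage import (
    FocusDecision,
    MotionBlurParams,
    apply_motion_blur,
    assign_group,
    estimate_direction,
    estimate_length,
    extract_profile,
    fit_sinc,
    focus_score,
    learn_focus_threshold,
    log_power_spectrum,
    modified_radon,
    rho_range_sum,
)
from blurage.blur_estimation import (
    GROUP_IDS,
    RadonMap,
    SpectralProfile,
    focus_and_direction,
    radon_profile,
)
from blurage.blur_model import SpectrumImage
from blurage.synthetic import FixtureSpec, make_texture


def _brute_force_radon(values, radius, rhos, thetas_deg):
    """Independent nested-loop oracle: for each (rho, theta) walk the
    line point by point and interpolate each sample by hand."""
    values = values - values.min()
    h, w = values.shape
    cy, cx = h // 2, w // 2
    out = np.zeros((len(rhos), len(thetas_deg)))
    smax = int(np.floor(radius))
    for j, theta in enumerate(thetas_deg):
        th = np.deg2rad(theta)
        for i, rho in enumerate(rhos):
            acc = 0.0
            for s in range(-smax, smax + 1):
                x = rho * np.cos(th) - s * np.sin(th)
                y = rho * np.sin(th) + s * np.cos(th)
                if x * x + y * y > radius * radius + 1e-9:
                    continue
                r, c = y + cy, x + cx
                r0, c0 = int(np.floor(r)), int(np.floor(c))
                fr, fc = r - r0, c - c0
                val = 0.0
                for dr, wr in ((0, 1 - fr), (1, fr)):
                    for dc, wc in ((0, 1 - fc), (1, fc)):
                        rr, cc = r0 + dr, c0 + dc
                        if 0 <= rr < h and 0 <= cc < w:
                            val += wr * wc * values[rr, cc]
                acc += val
            out[i, j] = acc
    return out


class TestModifiedRadon:
    def test_matches_brute_force_oracle_on_toy_grid(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 10, (15, 15))
        spectrum = SpectrumImage(values=values, source_size=(15, 15))
        rhos = np.arange(-3.0, 4.0)
        radon = modified_radon(spectrum, radius=6.0, theta_step=15.0, rhos=rhos)
        oracle = _brute_force_radon(values, 6.0, rhos, radon.thetas_deg)
        np.testing.assert_allclose(radon.values, oracle, atol=1e-9)

    def test_axis_aligned_center_line_equals_direct_column_sum(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 5, (21, 21))
        spectrum = SpectrumImage(values=values, source_size=(21, 21))
        radius = 8.0
        radon = modified_radon(spectrum, radius, theta_step=90.0, rhos=np.array([0.0]))
        shifted = values - values.min()
        r = int(radius)
        # theta=0: the rho=0 line runs along +y through the center
        col = shifted[10 - r : 10 + r + 1, 10].sum()
        row = shifted[10, 10 - r : 10 + r + 1].sum()
        assert radon.values[0, 0] == pytest.approx(col, abs=1e-9)
        assert radon.values[0, 1] == pytest.approx(row, abs=1e-9)

    def test_constant_spectrum_is_isotropic(self):
        # constant plateau covering the accumulation circle (the lower
        # corners keep the min-shift from zeroing everything out)
        yy, xx = np.mgrid[0:41, 0:41] - 20.0
        values = np.where(np.hypot(yy, xx) <= 19.0, 3.0, 1.0)
        spectrum = SpectrumImage(values=values, source_size=(41, 41))
        radon = modified_radon(spectrum, radius=15.0, theta_step=5.0,
                               rhos=np.array([0.0]))
        p = radon.values[0]
        assert np.ptp(p) / p.mean() < 0.05

    def test_rejects_bad_radius(self):
        spectrum = SpectrumImage(values=np.ones((32, 32)), source_size=(32, 32))
        with pytest.raises(ValueError):
            modified_radon(spectrum, radius=0.0)
        with pytest.raises(ValueError):
            modified_radon(spectrum, radius=17.0)


class TestRhoRangeSum:
    def _radon(self, rng):
        rhos = np.arange(-5.0, 6.0)
        values = rng.uniform(0, 1, (len(rhos), 180))
        return RadonMap(values=values, rhos=rhos,
                        thetas_deg=np.arange(0.0, 180.0), radius=10.0)

    def test_margin_zero_is_central_row(self):
        radon = self._radon(np.random.default_rng(2))
        score = rho_range_sum(radon, margin=0)
        np.testing.assert_allclose(score.p, radon.values[5])

    def test_margin_two_sums_five_rows(self):
        radon = self._radon(np.random.default_rng(3))
        score = rho_range_sum(radon, margin=2)
        np.testing.assert_allclose(score.p, radon.values[3:8].sum(axis=0))

    def test_monotone_in_margin_for_nonnegative_maps(self):
        radon = self._radon(np.random.default_rng(4))
        p_prev = rho_range_sum(radon, margin=0).p
        for margin in (1, 2, 3):
            p = rho_range_sum(radon, margin=margin).p
            assert np.all(p >= p_prev - 1e-12)
            p_prev = p

    def test_margin_beyond_radius_rejected(self):
        radon = self._radon(np.random.default_rng(5))
        with pytest.raises(ValueError):
            rho_range_sum(radon, margin=11)


class TestDirectionEstimation:
    @pytest.mark.parametrize("theta,length", [(90.0, 9), (45.0, 7)])
    def test_recovers_canonical_directions(self, theta, length):
        texture = make_texture(FixtureSpec(seed=8, size=256))
        blurred = apply_motion_blur(texture, MotionBlurParams(theta, length))
        estimate = estimate_direction(log_power_spectrum(blurred))
        error = min(abs(estimate - theta), 180 - abs(estimate - theta))
        assert error <= 1.0

    def test_focus_and_direction_consistent_with_separate_calls(self):
        texture = make_texture(FixtureSpec(seed=9, size=128))
        blurred = apply_motion_blur(texture, MotionBlurParams(0.0, 9))
        spectrum = log_power_spectrum(blurred)
        fs, theta = focus_and_direction(spectrum)
        assert fs == pytest.approx(focus_score(spectrum))
        assert theta == pytest.approx(estimate_direction(spectrum))


class TestProfileAndSincFit:
    def test_profile_at_zero_degrees_reads_center_row(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(0, 4, (33, 33))
        spectrum = SpectrumImage(values=values, source_size=(33, 33))
        profile = extract_profile(spectrum, 0.0)
        assert len(profile.samples) % 2 == 1
        half = len(profile.samples) // 2
        np.testing.assert_allclose(
            profile.samples, values[16, 16 - half : 16 + half + 1], atol=1e-9
        )

    def test_dc_dominates_profile_of_blurred_texture(self):
        texture = make_texture(FixtureSpec(seed=10, size=128))
        blurred = apply_motion_blur(texture, MotionBlurParams(135.0, 9))
        profile = extract_profile(log_power_spectrum(blurred), 135.0)
        assert np.argmax(profile.samples) == len(profile.samples) // 2

    def test_recovers_exact_analytic_null_spacing(self):
        t = np.arange(-127.0, 128.0)
        samples = 3.0 + np.log(np.sinc(t / 32.0) ** 2 + 1e-6)
        profile = SpectralProfile(samples=samples, spacing=1.0, theta_deg=0.0)
        assert fit_sinc(profile) == pytest.approx(32.0, abs=0.5)

    def test_recovers_null_spacing_of_simulated_blur(self):
        # N=256, L=8 puts the spectral nulls 32 bins apart
        texture = make_texture(FixtureSpec(seed=11, size=256))
        blurred = apply_motion_blur(texture, MotionBlurParams(0.0, 8))
        profile = extract_profile(log_power_spectrum(blurred), 0.0)
        assert fit_sinc(profile) == pytest.approx(32.0, abs=2.0)

    def test_fit_is_stable_under_small_profile_noise(self):
        t = np.arange(-127.0, 128.0)
        clean = 3.0 + np.log(np.sinc(t / 32.0) ** 2 + 1e-6)
        noisy = clean + np.random.default_rng(12).normal(0, 0.3, clean.shape)
        d_clean = fit_sinc(
            SpectralProfile(samples=clean, spacing=1.0, theta_deg=0.0)
        )
        d_noisy = fit_sinc(
            SpectralProfile(samples=noisy, spacing=1.0, theta_deg=0.0)
        )
        assert abs(d_noisy - d_clean) < 1.0

    def test_flat_profile_signals_no_blur_structure(self):
        profile = SpectralProfile(
            samples=np.full(255, 2.0), spacing=1.0, theta_deg=0.0
        )
        with pytest.raises(ValueError, match="flat profile"):
            fit_sinc(profile)

    def test_local_background_mode_matches_on_analytic_profile(self):
        t = np.arange(-127.0, 128.0)
        samples = 5.0 + np.log(np.sinc(t / 20.0) ** 2 + 1e-6)
        profile = SpectralProfile(samples=samples, spacing=1.0, theta_deg=0.0)
        assert fit_sinc(profile, background="local") == pytest.approx(20.0, abs=0.5)

    def test_radon_profile_agrees_with_line_profile_on_blurred_texture(self):
        # both profiles see the same null spacing
        texture = make_texture(FixtureSpec(seed=13, size=256))
        blurred = apply_motion_blur(texture, MotionBlurParams(90.0, 8))
        spectrum = log_power_spectrum(blurred)
        d_line = fit_sinc(extract_profile(spectrum, 90.0))
        d_pooled = fit_sinc(radon_profile(spectrum, 90.0), background="local")
        assert d_line == pytest.approx(32.0, abs=2.0)
        assert d_pooled == pytest.approx(32.0, abs=2.0)


class TestEstimateLength:
    def test_plain_ratio(self):
        assert estimate_length(30.0, 240) == pytest.approx(8.0)

    def test_full_period_snaps_to_no_blur(self):
        assert estimate_length(256.0, 256, snap_grid=(1, 3, 5)) == 1.0

    def test_snapping_picks_nearest_grid_value(self):
        assert estimate_length(36.0, 256, snap_grid=(1, 3, 5, 9)) == 9.0
        # exact midpoint ties break toward the smaller length
        assert estimate_length(32.0, 256, snap_grid=(1, 3, 5, 7, 9)) == 7.0

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            estimate_length(0.0, 256)

    def test_end_to_end_length_recovery(self):
        texture = make_texture(FixtureSpec(seed=14, size=256))
        blurred = apply_motion_blur(texture, MotionBlurParams(0.0, 11))
        spectrum = log_power_spectrum(blurred)
        theta = estimate_direction(spectrum)
        d = fit_sinc(extract_profile(spectrum, theta))
        assert estimate_length(d, 256) == pytest.approx(11.0, abs=1.0)


class TestFocusScore:
    def test_isotropic_spectrum_scores_near_100(self):
        spectrum = SpectrumImage(values=np.full((64, 64), 2.0), source_size=(64, 64))
        assert focus_score(spectrum) == pytest.approx(100.0, abs=1.0)

    def test_never_exceeds_100_plus_tolerance(self):
        for seed in range(5):
            texture = make_texture(FixtureSpec(seed=seed, size=128))
            assert focus_score(log_power_spectrum(texture)) <= 100.0 + 1e-6

    @pytest.mark.parametrize("length", [5, 9, 15])
    def test_blur_lowers_the_score(self, length):
        texture = make_texture(FixtureSpec(seed=15, size=256))
        fs_sharp = focus_score(log_power_spectrum(texture))
        blurred = apply_motion_blur(texture, MotionBlurParams(45.0, length))
        fs_blurred = focus_score(log_power_spectrum(blurred))
        assert fs_blurred < fs_sharp


class TestLearnFocusThreshold:
    def test_separable_sets_take_interval_midpoint(self):
        threshold, eer = learn_focus_threshold([99.0, 98.0], [50.0, 60.0])
        assert threshold == pytest.approx(79.0)
        assert eer == 0.0

    def test_identical_sets_give_half_error_rate(self):
        threshold, eer = learn_focus_threshold([1.0, 2.0], [1.0, 2.0])
        assert eer == pytest.approx(0.5)
        assert 1.0 <= threshold <= 2.0

    def test_eer_matches_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(16)
        focused = rng.normal(95, 3, 60)
        blurred = rng.normal(80, 8, 200)
        _, eer = learn_focus_threshold(focused, blurred)

        best = np.inf
        for th in np.unique(np.concatenate([focused, blurred, [200.0]])):
            fnr = np.mean(focused < th)
            fpr = np.mean(blurred >= th)
            if abs(fnr - fpr) < best:
                best = abs(fnr - fpr)
                oracle = (fnr + fpr) / 2
        assert eer == pytest.approx(oracle, abs=1e-12)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            learn_focus_threshold([], [1.0])


class TestAssignGroup:
    def test_spec_examples(self):
        blurred = FocusDecision(score=50.0, threshold=90.0, label="blurred")
        focused = FocusDecision(score=99.0, threshold=90.0, label="focused")
        assert assign_group(blurred, 45.0, 7.0) == "slight-45"
        assert assign_group(focused) == "focused"
        assert assign_group(blurred, 92.0, 12.3) == "blurred-90"

    def test_trivial_blur_lengths_fold_into_focused(self):
        blurred = FocusDecision(score=70.0, threshold=90.0, label="blurred")
        assert assign_group(blurred, 45.0, 3.0) == "focused"

    def test_direction_wraps_modulo_180(self):
        blurred = FocusDecision(score=50.0, threshold=90.0, label="blurred")
        assert assign_group(blurred, 178.0, 7.0) == "slight-0"

    def test_blurred_without_estimates_rejected(self):
        blurred = FocusDecision(score=50.0, threshold=90.0, label="blurred")
        with pytest.raises(ValueError):
            assign_group(blurred)

    @settings(max_examples=60, deadline=None)
    @given(
        label=st.sampled_from(["focused", "blurred"]),
        theta=st.floats(min_value=-360.0, max_value=360.0),
        length=st.floats(min_value=1.0, max_value=30.0),
    )
    def test_total_and_deterministic_over_nine_groups(self, label, theta, length):
        decision = FocusDecision(score=50.0, threshold=90.0, label=label)
        group = assign_group(decision, theta, length)
        assert group in GROUP_IDS
        assert assign_group(decision, theta, length) == group
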