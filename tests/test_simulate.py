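"""Forward model and synthetic disc generator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rgbassay as ra
from rgbassay.simulate import _disc_mask


class TestForwardEffectiveIntensity:
    @pytest.mark.parametrize("conc, expected_blue", [
        (0.0, 0.0),                      # blank develops no colour
        (10.0, 0.049 + 0.009 * 10),      # low-range line
        (100.0, 0.243 + 0.001 * 100),    # high-range line
        (20.0, 0.229),                   # low-range upper boundary
        (35.0, 0.278),                   # high-range lower boundary
    ])
    def test_piecewise_line(self, zero_noise_config, conc, expected_blue):
        eff = ra.forward_effective_intensity(zero_noise_config, conc)
        assert eff["blue"] == pytest.approx(expected_blue, abs=1e-12)

    def test_gap_interpolates_between_boundary_values(self, zero_noise_config):
        mid = ra.forward_effective_intensity(zero_noise_config, 27.5)["blue"]
        assert mid == pytest.approx((0.229 + 0.278) / 2)

    def test_time_scaling_is_linear(self, zero_noise_config):
        full = ra.forward_effective_intensity(zero_noise_config, 10, 7.0)
        half = ra.forward_effective_intensity(zero_noise_config, 10, 3.5)
        for ch in ("red", "green", "blue"):
            assert half[ch] == pytest.approx(full[ch] / 2)

    def test_channels_scale_by_rate_ratio(self, default_config):
        eff = ra.forward_effective_intensity(default_config, 50)
        r, g, b = default_config.channel_rates
        assert eff["red"] == pytest.approx(eff["blue"] * r / b)
        assert eff["green"] == pytest.approx(eff["blue"] * g / b)

    @given(c=st.floats(0, 400))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_concentration(self, c):
        cfg = ra.GeneratorConfig()
        lo = ra.forward_effective_intensity(cfg, c)["blue"]
        hi = ra.forward_effective_intensity(cfg, c + 1.0)["blue"]
        assert hi >= lo

    def test_channel_ordering_blue_ge_green_ge_red(self, default_config):
        for c in (2, 10, 27, 250):
            eff = ra.forward_effective_intensity(default_config, c, 4.0)
            assert eff["blue"] >= eff["green"] >= eff["red"]

    @pytest.mark.parametrize("conc, time", [(-1, 7), (10, -1), (10, 8)])
    def test_invalid_inputs_raise(self, default_config, conc, time):
        with pytest.raises(ValueError):
            ra.forward_effective_intensity(default_config, conc, time)


class TestForwardChannelMeans:
    def test_zero_signal_returns_blank_means(self, zero_noise_config):
        means = ra.forward_channel_means(zero_noise_config, 0)
        assert tuple(means.values()) == zero_noise_config.blank_channel_means

    def test_log10_two_halves_the_blank(self):
        cfg = ra.GeneratorConfig(blank_channel_means=(200, 200, 200))
        eff = {"red": 0.0, "green": 0.0, "blue": np.log10(2)}
        from rgbassay.simulate import _means_from_effective
        means = _means_from_effective(cfg, eff)
        assert means["blue"] == pytest.approx(100.0)
        assert means["red"] == pytest.approx(200.0)

    def test_low_range_worked_value(self, zero_noise_config):
        # blue blank 200, 10 uM -> 200 * 10**-0.139
        means = ra.forward_channel_means(zero_noise_config, 10)
        assert means["blue"] == pytest.approx(200 * 10**-0.139)
        assert means["blue"] == pytest.approx(145.221, abs=1e-3)


class TestRenderDisc:
    def test_zero_noise_pixels_exact(self, small_config):
        img = ra.render_disc(small_config, (120, 80, 40), seed=0)
        mask = _disc_mask(small_config.image_size_px,
                          small_config.disc_diameter_px)
        assert (img[mask] == (120, 80, 40)).all()
        assert (img[~mask] == small_config.background_level).all()

    def test_seeded_determinism_bit_identical(self, default_config):
        a = ra.render_disc(default_config, (150, 140, 130), seed=7)
        b = ra.render_disc(default_config, (150, 140, 130), seed=7)
        assert (a == b).all()
        c = ra.render_disc(default_config, (150, 140, 130), seed=8)
        assert (a != c).any()

    def test_noisy_disc_means_near_requested(self):
        cfg = ra.GeneratorConfig(pixel_noise_sd=3.0)  # disc ~11300 px
        img = ra.render_disc(cfg, (150.0, 140.0, 130.0), seed=3)
        mask = _disc_mask(cfg.image_size_px, cfg.disc_diameter_px)
        means = img[mask].mean(axis=0)
        # SE of the mean ~ 3/sqrt(11300) ~ 0.03; allow rounding bias
        assert np.allclose(means, (150, 140, 130), atol=0.1)

    def test_disc_larger_than_image_raises(self):
        cfg = ra.GeneratorConfig(disc_diameter_px=200, image_size_px=100)
        with pytest.raises(ValueError):
            ra.render_disc(cfg, (100, 100, 100), seed=0)


class TestGenerateExperiment:
    def test_counting_contract(self, small_config, tmp_path):
        samples, meta = ra.generate_experiment(
            small_config, [5, 10, 15, 20, 35], replicates=3, out_dir=tmp_path)
        assert len(samples) == 16            # 15 standards + 1 blank
        assert len(meta) == 16
        assert (meta["role"] == "blank").sum() == 1
        assert len(list(tmp_path.glob("*.png"))) == 16
        assert (tmp_path / "metadata.csv").exists()
        assert (tmp_path / "generator_config.json").exists()

    def test_zero_noise_round_trip_recovers_forward_model(self, small_config):
        samples, _ = ra.generate_experiment(small_config, [10.0], 1)
        sample, blank = samples
        roi_b = ra.detect_disc(blank.image)
        roi_s = ra.detect_disc(sample.image)
        eff = ra.effective_intensity(
            ra.mean_channel_intensities(blank.image, roi_b),
            ra.mean_channel_intensities(sample.image, roi_s))
        truth = ra.forward_effective_intensity(small_config, 10.0)
        # 8-bit quantization bounds the error for blank means >= 150
        assert eff.effective_blue == pytest.approx(truth["blue"], abs=0.005)

    def test_seeded_determinism(self, default_config):
        cfg = dataclasses.replace(default_config, seed=42)
        s1, m1 = ra.generate_experiment(cfg, [10, 100], 2)
        s2, m2 = ra.generate_experiment(cfg, [10, 100], 2)
        for a, b in zip(s1, s2):
            assert (a.image == b.image).all()
        assert m1.drop(columns="image_path").equals(m2.drop(columns="image_path"))

    def test_blank_replicate_sd_matches_configured_noise(self):
        # replicate scatter on the statistic should reproduce the set SD
        sigma = 4.611e-5
        cfg = ra.GeneratorConfig(effective_intensity_sd=sigma,
                                 pixel_noise_sd=0.0, seed=11,
                                 disc_diameter_px=60, image_size_px=80)
        samples, _ = ra.generate_experiment(cfg, [10.0], replicates=40)
        effs = []
        blank_blue = cfg.blank_channel_means[2]
        for s in samples[:-1]:
            effs.append(np.log10(blank_blue / s.channel_truth[2]))
        sd = np.std(effs, ddof=1)
        # chi-square 99% band for the sample SD of n = 40 normal draws
        assert 0.7 * sigma < sd < 1.4 * sigma

    def test_invalid_inputs_raise(self, small_config):
        with pytest.raises(ValueError):
            ra.generate_experiment(small_config, [], 3)
        with pytest.raises(ValueError):
            ra.generate_experiment(small_config, [10], 0)


class TestKineticTimeCourse:
    def test_rates_times_time(self, default_config):
        tc = ra.kinetic_time_course(default_config, [1, 4, 7])
        r, g, b = default_config.channel_rates
        assert tc["effective_blue"].tolist() == pytest.approx([b, 4 * b, 7 * b])
        assert tc["effective_red"].tolist() == pytest.approx([r, 4 * r, 7 * r])


class TestGeneratorConfig:
    @pytest.mark.parametrize("kwargs", [
        {"low_range_bounds": (20.0, 5.0)},
        {"low_range_bounds": (5.0, 40.0)},      # overlaps high range
        {"low_range_slope": -0.1},
        {"blank_channel_means": (300.0, 190.0, 200.0)},
        {"pixel_noise_sd": -1.0},
        {"reaction_time": 0.0},
    ])
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            ra.GeneratorConfig(**kwargs)

    def test_json_round_trip(self, tmp_path, default_config):
        path = tmp_path / "cfg.json"
        default_config.to_json(path)
        assert ra.GeneratorConfig.from_json(path) == default_config
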