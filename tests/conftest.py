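import dataclasses

import pytest

import rgbassay as ra


@pytest.fixture(scope="session")
def default_config() -> ra.GeneratorConfig:
    return ra.GeneratorConfig()


@pytest.fixture(scope="session")
def zero_noise_config() -> ra.GeneratorConfig:
    return ra.GeneratorConfig(effective_intensity_sd=0.0, pixel_noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_standards(zero_noise_config):
    """Standards spanning both dynamic ranges, generated without noise."""
    concs = [5.0, 7.5, 10.0, 15.0, 20.0, 35.0, 50.0, 100.0, 200.0, 300.0, 400.0]
    signals = [ra.forward_effective_intensity(zero_noise_config, c)["blue"]
               for c in concs]
    return concs, signals


@pytest.fixture(scope="session")
def fitted_results(noise_free_standards) -> ra.CalibrationResults:
    """Calibration fitted on noise-free standards with a known blank SD."""
    sigma = 4.611e-5  # a.u.; gives LOD = 3 sigma / 0.009 = 15.37 nM
    concs, signals = noise_free_standards
    model = ra.DualRangeCalibration(
        concs, signals, blank_replicates=[-sigma, 0.0, sigma])
    return model.fit()


@pytest.fixture()
def small_config() -> ra.GeneratorConfig:
    """A compact disc for image-heavy tests (radius 30 px, ~2800 ROI px)."""
    return ra.GeneratorConfig(disc_diameter_px=60, image_size_px=80,
                              effective_intensity_sd=0.0, pixel_noise_sd=0.0)


def replace(cfg, **kwargs):
    return dataclasses.replace(cfg, **kwargs)
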