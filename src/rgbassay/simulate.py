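"""Forward model and synthetic disc-image generator.

The generator emulates the data-producing process of a paper-disc
colorimetric creatinine assay imaged with a smartphone camera:

* concentration -> blue-channel effective intensity via a two-range
  piecewise-linear calibration model (low range 5-20 uM, high range
  35-400 uM), with linear interpolation across the 20-35 uM gap and a
  linear ramp from the origin below 5 uM;
* colour development linear in time through the origin, so a signal at
  time t < reaction_time is the endpoint value scaled by t/reaction_time,
  and the red/green channels scale from blue by the ratio of their
  per-minute development rates;
* effective intensities map back to 8-bit channel means through the
  blank-referenced log-ratio (mean = blank_mean * 10**-effective);
* discs are rendered as filled circles on a uniform background with
  optional Gaussian pixel noise, and replicate scatter enters as Gaussian
  noise on the blue effective intensity.

All randomness derives from a single root seed through stable
``numpy.random.SeedSequence`` offsets, so a configuration reproduces its
images and tables bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "GeneratorConfig",
    "SyntheticSample",
    "forward_effective_intensity",
    "forward_channel_means",
    "kinetic_time_course",
    "render_disc",
    "generate_experiment",
]

CHANNELS = ("red", "green", "blue")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the forward model.

    Defaults encode the assay's published operating point: the two
    dynamic-range regression lines, the per-channel colour-development
    rates over 1-7 min, the 7.0 min optimised reaction time, and a
    replicate noise level chosen so that 3*sigma/slope reproduces the
    assay's detection limit (15.37 nM).
    """

    low_range_intercept: float = 0.049      # a.u.
    low_range_slope: float = 0.009          # a.u. per uM
    low_range_bounds: tuple[float, float] = (5.0, 20.0)    # uM
    high_range_intercept: float = 0.243     # a.u.
    high_range_slope: float = 0.001         # a.u. per uM
    high_range_bounds: tuple[float, float] = (35.0, 400.0)  # uM
    channel_rates: tuple[float, float, float] = (0.0248, 0.0619, 0.1138)  # a.u./min, RGB
    reaction_time: float = 7.0              # min
    blank_channel_means: tuple[float, float, float] = (200.0, 190.0, 200.0)
    effective_intensity_sd: float = 4.611e-5  # a.u.; = slope * LOD / 3
    pixel_noise_sd: float = 2.0             # 8-bit intensity units
    disc_diameter_px: int = 120             # physical diameter 5.0 mm
    image_size_px: int = 160
    background_level: int = 245
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.low_range_bounds[0] < self.low_range_bounds[1]
                and self.high_range_bounds[0] < self.high_range_bounds[1]):
            raise ValueError("range bounds must be ordered")
        if self.low_range_bounds[1] > self.high_range_bounds[0]:
            raise ValueError("dynamic ranges must not overlap")
        if self.low_range_slope < 0 or self.high_range_slope < 0:
            raise ValueError("slopes must be non-negative")
        if any(not (0.0 <= m <= 255.0) for m in self.blank_channel_means):
            raise ValueError("blank channel means must lie in [0, 255]")
        if self.effective_intensity_sd < 0 or self.pixel_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.reaction_time <= 0:
            raise ValueError("reaction_time must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("low_range_bounds", "high_range_bounds", "channel_rates",
                    "blank_channel_means"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticSample:
    """One generated disc: ground truth plus the rendered image."""

    true_concentration: float
    replicate_index: int
    time: float
    noiseless_effective_blue: float
    channel_truth: tuple[float, float, float]
    image: np.ndarray | None = None
    image_path: Path | None = None


def _endpoint_blue(config: GeneratorConfig, concentration: float) -> float:
    """Blue effective intensity at t = reaction_time (piecewise linear)."""
    lo_lo, lo_hi = config.low_range_bounds
    hi_lo, hi_hi = config.high_range_bounds
    low = lambda c: config.low_range_intercept + config.low_range_slope * c
    high = lambda c: config.high_range_intercept + config.high_range_slope * c
    c = float(concentration)
    if c == 0.0:
        return 0.0
    if c < lo_lo:
        # linear ramp from the blank (0, 0) to the low-range value at its
        # lower bound: a blank disc develops no colour
        return low(lo_lo) * c / lo_lo
    if c <= lo_hi:
        return low(c)
    if c < hi_lo:
        # the assay's behaviour between the two ranges is unspecified;
        # interpolate between the boundary values for continuity
        y0, y1 = low(lo_hi), high(hi_lo)
        return y0 + (y1 - y0) * (c - lo_hi) / (hi_lo - lo_hi)
    return high(c)


def forward_effective_intensity(
    config: GeneratorConfig, concentration: float, time: float | None = None
) -> dict[str, float]:
    """Noiseless per-channel effective intensity at a concentration and time.

    The blue value at ``time == reaction_time`` follows the piecewise
    two-range calibration model; earlier times scale linearly as
    ``time / reaction_time``; red and green scale from blue by the ratio
    of their development rates to the blue rate.
    """
    if time is None:
        time = config.reaction_time
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if not (0 <= time <= config.reaction_time):
        raise ValueError(
            f"time must lie in [0, {config.reaction_time}] min, got {time}")
    blue = _endpoint_blue(config, concentration) * (time / config.reaction_time)
    r_rate, g_rate, b_rate = config.channel_rates
    return {
        "red": blue * r_rate / b_rate,
        "green": blue * g_rate / b_rate,
        "blue": blue,
    }


def forward_channel_means(
    config: GeneratorConfig, concentration: float, time: float | None = None
) -> dict[str, float]:
    """8-bit channel means implied by the forward effective intensities.

    Inverts the blank-referenced log-ratio: mean = blank * 10**-effective,
    clipped to the 8-bit range.
    """
    eff = forward_effective_intensity(config, concentration, time)
    return _means_from_effective(config, eff)


def _means_from_effective(
    config: GeneratorConfig, eff: dict[str, float]
) -> dict[str, float]:
    means = {}
    for ch, blank in zip(CHANNELS, config.blank_channel_means):
        means[ch] = float(np.clip(blank * 10.0 ** (-eff[ch]), 0.0, 255.0))
    return means


def kinetic_time_course(
    config: GeneratorConfig, times: Sequence[float]
) -> pd.DataFrame:
    """Noiseless colour-development time course at the assay condition.

    Returns per-channel effective intensities equal to ``rate * time`` for
    each requested time, i.e. the channel-selection experiment in which
    each channel develops linearly through the origin at its per-minute
    rate. Columns: time_min, effective_red, effective_green, effective_blue.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    r, g, b = config.channel_rates
    return pd.DataFrame({
        "time_min": times,
        "effective_red": r * times,
        "effective_green": g * times,
        "effective_blue": b * times,
    })


def _disc_mask(image_size: int, diameter: int) -> np.ndarray:
    """Boolean mask of pixels whose centers fall strictly inside the disc."""
    radius = diameter / 2.0
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    return (xx - c) ** 2 + (yy - c) ** 2 < radius**2


def render_disc(
    config: GeneratorConfig,
    channel_means: dict[str, float] | Sequence[float],
    seed: int,
) -> np.ndarray:
    """Render an 8-bit RGB image of one disc.

    A filled circle of ``disc_diameter_px`` centered in a square
    ``image_size_px`` frame; in-disc pixels take the requested channel
    means plus independent Gaussian noise (SD ``pixel_noise_sd``), the rest
    a uniform ``background_level``. Values are clipped to [0, 255] and
    rounded. Deterministic for a fixed seed. No edge antialiasing: the
    pixel-center-in-circle rule here matches the ROI rule used downstream.
    """
    if isinstance(channel_means, dict):
        means = [channel_means[ch] for ch in CHANNELS]
    else:
        means = list(channel_means)
    if any(not (0.0 <= m <= 255.0) for m in means):
        raise ValueError("channel means must lie in [0, 255]")
    if config.disc_diameter_px > config.image_size_px:
        raise ValueError("disc does not fit inside the image")
    n = config.image_size_px
    img = np.full((n, n, 3), float(config.background_level))
    mask = _disc_mask(n, config.disc_diameter_px)
    img[mask] = means
    if config.pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        img[mask] += rng.normal(0.0, config.pixel_noise_sd, (int(mask.sum()), 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_experiment(
    config: GeneratorConfig,
    concentrations: Sequence[float],
    replicates: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Simulate a standards run: replicate discs plus one batch blank.

    For each concentration x replicate, Gaussian noise with SD
    ``effective_intensity_sd`` is added to the noiseless blue effective
    intensity; red and green follow the noisy blue scaled by their rate
    ratios, so per-replicate channel ordering is preserved. Channel means
    are back-computed and a disc image rendered per sample, plus one blank
    disc for the batch. When ``out_dir`` is given, PNG images, a metadata
    CSV and the config JSON are written there; otherwise images stay in
    memory on the returned samples.

    Returns the samples (blank last, concentration 0) and the metadata
    table with columns image_path, role, concentration_uM, replicate,
    time_min, seed.
    """
    if len(concentrations) == 0:
        raise ValueError("need at least one concentration")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    r_rate, g_rate, b_rate = config.channel_rates
    t = config.reaction_time

    samples: list[SyntheticSample] = []
    rows = []
    stream = 0
    for conc in concentrations:
        truth_blue = forward_effective_intensity(config, conc, t)["blue"]
        for rep in range(replicates):
            noise_rng = np.random.default_rng([config.seed, stream])
            blue = truth_blue
            if config.effective_intensity_sd > 0:
                blue = blue + noise_rng.normal(0.0, config.effective_intensity_sd)
            eff = {
                "red": blue * r_rate / b_rate,
                "green": blue * g_rate / b_rate,
                "blue": blue,
            }
            means = _means_from_effective(config, eff)
            img = render_disc(config, means, seed=_image_seed(config.seed, stream))
            sample = SyntheticSample(
                true_concentration=float(conc),
                replicate_index=rep,
                time=t,
                noiseless_effective_blue=truth_blue,
                channel_truth=tuple(means[ch] for ch in CHANNELS),
                image=img,
            )
            if out_path is not None:
                fname = f"standard_c{conc:g}_r{rep}.png"
                Image.fromarray(img).save(out_path / fname)
                sample.image_path = out_path / fname
                sample.image = None
            samples.append(sample)
            rows.append({
                "image_path": fname if out_path is not None else "",
                "role": "standard",
                "concentration_uM": float(conc),
                "replicate": rep,
                "time_min": t,
                "seed": _image_seed(config.seed, stream),
            })
            stream += 1

    # one blank disc per batch: the white reference of the log-ratio
    blank_means = dict(zip(CHANNELS, config.blank_channel_means))
    blank_img = render_disc(config, blank_means, seed=_image_seed(config.seed, stream))
    blank = SyntheticSample(
        true_concentration=0.0, replicate_index=0, time=t,
        noiseless_effective_blue=0.0,
        channel_truth=tuple(config.blank_channel_means), image=blank_img,
    )
    if out_path is not None:
        Image.fromarray(blank_img).save(out_path / "blank.png")
        blank.image_path = out_path / "blank.png"
        blank.image = None
    samples.append(blank)
    rows.append({
        "image_path": "blank.png" if out_path is not None else "",
        "role": "blank", "concentration_uM": 0.0, "replicate": 0,
        "time_min": t, "seed": _image_seed(config.seed, stream),
    })

    meta = pd.DataFrame(rows)
    if out_path is not None:
        meta.to_csv(out_path / "metadata.csv", index=False)
        config.to_json(out_path / "generator_config.json")
    return samples, meta


def _image_seed(root_seed: int, stream: int) -> int:
    # stable per-image stream offset, kept below 2**31
    return (root_seed * 100_003 + 7 * stream + 1) % (2**31 - 1)
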