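"""Blank-referenced effective intensity and analytical-channel selection.

The signal statistic is the log-ratio of blank to sample mean channel
intensity,

    effective_I = log10(I_blank / I_sample),

computed per colour channel — the colorimetric analogue of absorbance:
zero for a disc identical to the blank reference and increasing as the
developed chromophore absorbs more of that channel's complementary light.
For the reddish-orange creatinine-picric acid product the blue channel
changes fastest and is the analytical channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .imaging import ChannelIntensities

__all__ = [
    "EffectiveIntensity",
    "ChannelSensitivity",
    "effective_intensity",
    "channel_sensitivity",
    "select_channel",
]

# tie-break priority: blue wins over green over red
_CHANNEL_PRIORITY = ("blue", "green", "red")


@dataclass(frozen=True)
class EffectiveIntensity:
    effective_red: float
    effective_green: float
    effective_blue: float
    blank_reference_id: str = ""

    def __getitem__(self, channel: str) -> float:
        return getattr(self, f"effective_{channel}")


@dataclass(frozen=True)
class ChannelSensitivity:
    """Per-channel colour-development rates fitted from a time course."""

    rate_red: float
    rate_green: float
    rate_blue: float
    rate_se_red: float
    rate_se_green: float
    rate_se_blue: float
    selected_channel: str
    time_points: tuple[float, ...]

    def rate(self, channel: str) -> float:
        return getattr(self, f"rate_{channel}")


def effective_intensity(
    blank: ChannelIntensities,
    sample: ChannelIntensities,
    blank_reference_id: str = "",
) -> EffectiveIntensity:
    """log10(blank mean / sample mean), per channel.

    Sample means at or below zero are clipped to 0.5 (half an 8-bit step)
    with a warning; a non-positive blank mean is an error, because the
    blank is the white reference of the ratio.
    """
    values = {}
    for ch in ("red", "green", "blue"):
        b = getattr(blank, f"mean_{ch}")
        s = getattr(sample, f"mean_{ch}")
        if b <= 0:
            raise ValueError(
                f"blank {ch} mean is {b}; the blank must be a valid white "
                "reference with positive intensity")
        if s <= 0:
            warnings.warn(
                f"sample {ch} mean {s} clipped to 0.5 (saturated-dark "
                "artifact?)", stacklevel=2)
            s = 0.5
        values[ch] = float(np.log10(b / s))
    return EffectiveIntensity(
        effective_red=values["red"], effective_green=values["green"],
        effective_blue=values["blue"], blank_reference_id=blank_reference_id)


def _slope_through_origin(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope = float(np.dot(t, y) / np.dot(t, t))
    resid = y - slope * t
    dof = max(len(t) - 1, 1)
    se = float(np.sqrt(resid @ resid / dof / np.dot(t, t)))
    return slope, se


def _slope_free_intercept(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    fit = sm.OLS(y, sm.add_constant(t)).fit()
    return float(fit.params[1]), float(fit.bse[1])


def channel_sensitivity(
    series: Sequence[tuple[float, EffectiveIntensity]],
    through_origin: bool = True,
) -> ChannelSensitivity:
    """Fit effective intensity vs time per channel and pick the fastest.

    By default the regression is forced through the origin, since no
    colour has developed at t = 0; set ``through_origin=False`` for a free
    intercept. The analytical channel is the one with the largest fitted
    rate, ties broken blue > green > red.
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    t = np.array([p[0] for p in series], dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("time points must not all coincide")
    rates: dict[str, float] = {}
    ses: dict[str, float] = {}
    for ch in ("red", "green", "blue"):
        y = np.array([p[1][ch] for p in series], dtype=float)
        fit = _slope_through_origin if through_origin else _slope_free_intercept
        rates[ch], ses[ch] = fit(t, y)
    selected = max(_CHANNEL_PRIORITY, key=lambda ch: (rates[ch], -_CHANNEL_PRIORITY.index(ch)))
    return ChannelSensitivity(
        rate_red=rates["red"], rate_green=rates["green"],
        rate_blue=rates["blue"], rate_se_red=ses["red"],
        rate_se_green=ses["green"], rate_se_blue=ses["blue"],
        selected_channel=selected, time_points=tuple(t))


def select_channel(sensitivity: ChannelSensitivity) -> str:
    """The channel with the largest fitted rate (ties: blue > green > red)."""
    return sensitivity.selected_channel
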