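"""Two-range linear calibration with LOD/LOQ and inverse prediction.

The assay responds linearly to creatinine over two separate dynamic
ranges (nominally 5-20 uM and 35-400 uM), each fitted by ordinary least
squares:

    effective_I_blue = intercept + slope * [Cr]   (per range)

The detection and quantification limits follow the blank-replicate
convention,

    LOD = k_LOD * sigma_blank / slope_low,   k_LOD = 3
    LOQ = k_LOQ * sigma_blank / slope_low,   k_LOQ = 10,

where sigma_blank is the sample standard deviation of repeated blank
readings and slope_low the lower-range slope — the lower curve governs
both limits. Inverse prediction routes an unknown signal low-range-first:
the low line is inverted, and only when the implied concentration exceeds
the low range does the high line take over; signals mapping into the
inter-range gap are flagged and reported via linear interpolation between
the two range boundary responses.

The module follows the statsmodels idiom: ``DualRangeCalibration`` is the
model specification bound to data, ``fit()`` returns a
``CalibrationResults`` carrying the estimates, their standard errors,
diagnostics, and the prediction methods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DualRangeCalibration",
    "CalibrationResults",
    "RangeFit",
    "ConcentrationEstimate",
]


@dataclass(frozen=True)
class RangeFit:
    """OLS fit of one linear dynamic range."""

    intercept: float            # a.u.
    slope: float                # a.u. per uM
    intercept_se: float
    slope_se: float
    adj_r_squared: float
    residual_sd: float          # a.u.
    bounds: tuple[float, float]  # uM, inclusive
    n_standards: int

    def forward(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration

    def inverse(self, effective_blue: float) -> float:
        return (effective_blue - self.intercept) / self.slope


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse-predicted concentration for one signal value."""

    concentration: float        # uM
    range_used: str             # low | high | gap | below-lod
    effective_blue_input: float
    flag: str                   # ok | below-lod | in-gap | above-range


class DualRangeCalibration:
    """Two-range linear calibration model bound to standards data.

    Parameters
    ----------
    concentrations, effective_blue : array-like
        Standards: nominal concentration (uM) and measured blue-channel
        effective intensity (a.u.).
    range_split : pair of (low, high) bounds
        Inclusive concentration bounds of the two dynamic ranges, e.g.
        ``((5, 20), (35, 400))``. Standards outside both ranges are
        ignored with a warning.
    blank_replicates : array-like
        Repeated blank effective-intensity readings for the LOD/LOQ
        blank SD (>= 3 required).
    lod_multiplier, loq_multiplier : float
        The k of k * sigma_blank / slope; defaults 3 and 10.
    """

    def __init__(
        self,
        concentrations: Sequence[float],
        effective_blue: Sequence[float],
        blank_replicates: Sequence[float],
        range_split: tuple[tuple[float, float], tuple[float, float]] = (
            (5.0, 20.0), (35.0, 400.0)),
        lod_multiplier: float = 3.0,
        loq_multiplier: float = 10.0,
    ) -> None:
        self.concentrations = np.asarray(concentrations, dtype=float)
        self.effective_blue = np.asarray(effective_blue, dtype=float)
        if self.concentrations.shape != self.effective_blue.shape:
            raise ValueError("concentrations and signals must align")
        self.blank_replicates = np.asarray(blank_replicates, dtype=float)
        if self.blank_replicates.size < 3:
            raise ValueError("need >= 3 blank replicates for the LOD")
        low, high = range_split
        if not (low[0] < low[1] and high[0] < high[1] and low[1] <= high[0]):
            raise ValueError("ranges must be ordered and non-overlapping")
        self.range_split = (tuple(low), tuple(high))
        self.lod_multiplier = float(lod_multiplier)
        self.loq_multiplier = float(loq_multiplier)

    @classmethod
    def from_dataframe(
        cls,
        standards: pd.DataFrame,
        blank_replicates: Sequence[float],
        concentration_col: str = "concentration_uM",
        signal_col: str = "effective_blue",
        **kwargs,
    ) -> "DualRangeCalibration":
        return cls(standards[concentration_col].to_numpy(),
                   standards[signal_col].to_numpy(),
                   blank_replicates, **kwargs)

    def _fit_range(self, bounds: tuple[float, float]) -> RangeFit:
        lo, hi = bounds
        mask = (self.concentrations >= lo) & (self.concentrations <= hi)
        x = self.concentrations[mask]
        y = self.effective_blue[mask]
        if x.size < 3:
            raise ValueError(
                f"range {bounds} has {x.size} standards; >= 3 required")
        with warnings.catch_warnings():
            # a perfect (noise-free) line triggers harmless kurtosis warnings
            warnings.simplefilter("ignore")
            ols = sm.OLS(y, sm.add_constant(x)).fit()
        resid_sd = float(np.sqrt(ols.ssr / max(ols.df_resid, 1)))
        return RangeFit(
            intercept=float(ols.params[0]), slope=float(ols.params[1]),
            intercept_se=float(ols.bse[0]), slope_se=float(ols.bse[1]),
            adj_r_squared=float(ols.rsquared_adj), residual_sd=resid_sd,
            bounds=(float(lo), float(hi)), n_standards=int(x.size))

    def fit(self) -> "CalibrationResults":
        low = self._fit_range(self.range_split[0])
        high = self._fit_range(self.range_split[1])
        for rng, name in ((low, "low"), (high, "high")):
            if rng.slope <= 0:
                warnings.warn(
                    f"{name}-range slope {rng.slope:.4g} is not positive: "
                    "degenerate assay", stacklevel=2)
        blank_sd = float(np.std(self.blank_replicates, ddof=1))
        lod = self.lod_multiplier * blank_sd / low.slope if low.slope > 0 else np.nan
        loq = self.loq_multiplier * blank_sd / low.slope if low.slope > 0 else np.nan
        return CalibrationResults(
            model=self, low=low, high=high, blank_sd=blank_sd,
            lod=float(lod), loq=float(loq),
            n_blank_replicates=int(self.blank_replicates.size))


class CalibrationResults:
    """Fitted two-range calibration: estimates, limits, inverse prediction."""

    def __init__(self, model: DualRangeCalibration | None, low: RangeFit,
                 high: RangeFit, blank_sd: float, lod: float, loq: float,
                 n_blank_replicates: int) -> None:
        self.model = model
        self.low = low
        self.high = high
        self.blank_sd = blank_sd
        self.lod = lod      # uM
        self.loq = loq      # uM
        self.n_blank_replicates = n_blank_replicates

    # -- inverse prediction -------------------------------------------------

    def _gap_inverse(self, effective_blue: float) -> float:
        y0 = self.low.forward(self.low.bounds[1])
        y1 = self.high.forward(self.high.bounds[0])
        c0, c1 = self.low.bounds[1], self.high.bounds[0]
        return c0 + (effective_blue - y0) * (c1 - c0) / (y1 - y0)

    def predict_concentration(self, effective_blue: float) -> ConcentrationEstimate:
        """Invert the calibration for one blue effective intensity.

        Routing is low-range-first: the low line is inverted; if the
        implied concentration exceeds the low range's upper bound, the
        high line is used instead. A high-range inverse inside the
        inter-range gap is flagged ``in-gap`` and reported via the
        gap-interpolated inverse; below-LOD and above-range results are
        flagged but still carry the extrapolated value.
        """
        if not np.isfinite(effective_blue):
            raise ValueError("effective intensity must be finite")
        if self.low.slope <= 0 or self.high.slope <= 0:
            raise ValueError("cannot invert a calibration with non-positive slope")
        y = float(effective_blue)
        # boundary standards (e.g. 20, 35, 400 uM) must not be mis-routed
        # by last-digit rounding of the inverse
        eps = 1e-9 * max(1.0, self.high.bounds[1])
        c_low = self.low.inverse(y)
        if c_low <= self.low.bounds[1] + eps:
            conc, rng = min(c_low, self.low.bounds[1]), "low"
            flag = "below-lod" if conc < self.lod else "ok"
            if flag == "below-lod":
                rng = "below-lod"
        else:
            c_high = self.high.inverse(y)
            if c_high < self.high.bounds[0] - eps:
                conc, rng, flag = self._gap_inverse(y), "gap", "in-gap"
            elif c_high <= self.high.bounds[1] + eps:
                conc = float(np.clip(c_high, self.high.bounds[0],
                                     self.high.bounds[1]))
                rng, flag = "high", "ok"
            else:
                conc, rng, flag = c_high, "high", "above-range"
        return ConcentrationEstimate(
            concentration=float(conc), range_used=rng,
            effective_blue_input=y, flag=flag)

    def predict(self, effective_blue: Sequence[float] | float) -> pd.DataFrame:
        """Vectorised inverse prediction, one row per input signal."""
        values = np.atleast_1d(np.asarray(effective_blue, dtype=float))
        rows = [self.predict_concentration(v).__dict__ for v in values]
        return pd.DataFrame(rows)

    def round_trip_check(
        self, generator_config, concentrations: Sequence[float]
    ) -> pd.DataFrame:
        """Forward-then-invert each concentration through the generator.

        For a model fitted on noise-free data from the same forward
        family, estimated equals true inside either range.
        """
        from .simulate import forward_effective_intensity
        rows = []
        for c in concentrations:
            y = forward_effective_intensity(generator_config, c)["blue"]
            est = self.predict_concentration(y)
            rows.append({"true_uM": float(c), "estimated_uM": est.concentration,
                         "range_used": est.range_used, "flag": est.flag})
        return pd.DataFrame(rows)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = ["Dual-range colorimetric calibration", "=" * 52]
        for name, rng in (("Low", self.low), ("High", self.high)):
            lines += [
                f"{name} range {rng.bounds[0]:g}-{rng.bounds[1]:g} uM "
                f"(n={rng.n_standards}):",
                f"  effective_I_blue = {rng.intercept:.4f} (+/-{rng.intercept_se:.4f})"
                f" + {rng.slope:.4f} (+/-{rng.slope_se:.4f}) [Cr uM]",
                f"  adj R^2 = {rng.adj_r_squared:.4f}   residual SD = "
                f"{rng.residual_sd:.3g} a.u.",
            ]
        lines += [
            f"Blank SD = {self.blank_sd:.3g} a.u. "
            f"(n={self.n_blank_replicates} replicates)",
            f"LOD ({self.model.lod_multiplier if self.model else 3:g} sigma) = "
            f"{self.lod * 1000:.2f} nM",
            f"LOQ ({self.model.loq_multiplier if self.model else 10:g} sigma) = "
            f"{self.loq * 1000:.2f} nM",
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def rng_dict(r: RangeFit) -> dict:
            return {"intercept": r.intercept, "slope": r.slope,
                    "intercept_se": r.intercept_se, "slope_se": r.slope_se,
                    "adj_r_squared": r.adj_r_squared,
                    "residual_sd": r.residual_sd, "bounds": list(r.bounds),
                    "n_standards": r.n_standards}
        return {"low": rng_dict(self.low), "high": rng_dict(self.high),
                "blank_sd": self.blank_sd, "lod_uM": self.lod,
                "loq_uM": self.loq,
                "n_blank_replicates": self.n_blank_replicates}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResults":
        raw = json.loads(Path(path).read_text())

        def rng(d: dict) -> RangeFit:
            return RangeFit(intercept=d["intercept"], slope=d["slope"],
                            intercept_se=d["intercept_se"],
                            slope_se=d["slope_se"],
                            adj_r_squared=d["adj_r_squared"],
                            residual_sd=d["residual_sd"],
                            bounds=tuple(d["bounds"]),
                            n_standards=d["n_standards"])
        return cls(model=None, low=rng(raw["low"]), high=rng(raw["high"]),
                   blank_sd=raw["blank_sd"], lod=raw["lod_uM"],
                   loq=raw["loq_uM"],
                   n_blank_replicates=raw["n_blank_replicates"])
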