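"""Analytical validation statistics: selectivity, recovery, precision.

Covers the standard figures of merit used to validate a colorimetric
assay against a serum matrix:

* selectivity coefficient k_sel = interferent signal / analyte signal,
  expected << 1 for a specific sensor;
* mixed-sample sensitivity, the percentage of the pure-analyte signal
  retained when interferents are co-present;
* spike recovery, %R = 100 * (spiked - blank) / added, summarised per
  spike level with replicate mean, SD and RSD;
* relative standard deviation (n-1 sample SD over mean, in percent);
* shelf-life series as percent of the initial signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResults

__all__ = [
    "SelectivityResult",
    "RecoveryRecord",
    "INTERFERENTS",
    "SERUM_RECOVERY_TABLE",
    "selectivity_coefficient",
    "mixed_sample_sensitivity",
    "percent_recovery",
    "recovery_study",
    "recovery_table",
    "rsd",
    "stability_series",
]

# serum constituents screened for cross-reactivity
INTERFERENTS = ("glucose", "BSA", "uric acid", "citric acid", "vitamin C",
                "Na+", "K+", "Cl-")

# Reference spiked-serum recovery dataset (worked-example inputs): spiked
# and recovered creatinine per level, with the reported recovery and RSD.
SERUM_RECOVERY_TABLE = pd.read_csv(StringIO("""\
spiked_uM,recovered_uM,recovered_sd_uM,recovery_percent,rsd_percent
5,4.77,0.05,95.40,1.10
7.5,6.75,0.18,90.09,2.80
10,9.54,0.25,95.46,2.66
15,13.45,0.26,89.71,1.96
20,19.46,0.39,97.30,2.02
35,32.99,0.99,94.27,3.02
50,47.31,1.41,94.62,2.98
100,92.55,2.92,92.55,3.15
150,139.99,4.61,93.32,3.29
200,189.29,5.39,94.64,2.84
300,288.73,3.62,96.24,1.25
400,384.50,4.01,96.12,1.04
"""))


@dataclass(frozen=True)
class SelectivityResult:
    interferent: str
    signal_interferent: float
    signal_creatinine: float
    k_sel: float


@dataclass(frozen=True)
class RecoveryRecord:
    """One spike level of a recovery study."""

    spiked: float           # uM added
    recovered_mean: float   # uM
    recovered_sd: float     # uM
    recovery_percent: float
    rsd_percent: float
    n_replicates: int
    flag: str = "ok"


def selectivity_coefficient(
    signal_interferent: float, signal_creatinine: float,
    interferent: str = "",
) -> SelectivityResult:
    """k_sel = interferent signal / creatinine signal."""
    if signal_creatinine <= 0:
        raise ZeroDivisionError(
            "creatinine signal must be positive to define k_sel")
    return SelectivityResult(
        interferent=interferent,
        signal_interferent=float(signal_interferent),
        signal_creatinine=float(signal_creatinine),
        k_sel=float(signal_interferent) / float(signal_creatinine))


def mixed_sample_sensitivity(signal_mixed: float, signal_pure: float) -> float:
    """Percent of the pure-creatinine signal retained in a mixed sample."""
    if signal_pure <= 0:
        raise ZeroDivisionError("pure-sample signal must be positive")
    return 100.0 * float(signal_mixed) / float(signal_pure)


def percent_recovery(
    spiked_measurement: float, blank_measurement: float, standard_added: float
) -> float:
    """%R = 100 * (spiked - blank) / added."""
    if standard_added <= 0:
        raise ValueError("amount of standard added must be positive")
    return 100.0 * (float(spiked_measurement) - float(blank_measurement)) \
        / float(standard_added)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, percent: 100 * sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD requires at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ZeroDivisionError("RSD undefined at zero mean")
    return 100.0 * float(np.std(arr, ddof=1)) / float(mean)


def recovery_study(
    results: CalibrationResults,
    measurements: Sequence[tuple[float, Sequence[float]]],
    blank_effective: float = 0.0,
) -> list[RecoveryRecord]:
    """Spike-recovery analysis of replicate signals at known spike levels.

    Each replicate blue effective intensity is converted to a
    concentration through the fitted calibration; the blank signal is
    converted the same way and subtracted, so the correction happens in
    concentration units. Per level: mean, SD, recovery %, RSD %. Levels
    with any replicate flagged above-range are excluded from the summary
    statistics and returned flagged.
    """
    blank_conc = results.predict_concentration(blank_effective).concentration
    blank_conc = max(blank_conc, 0.0)
    records = []
    for spiked, signals in sorted(measurements, key=lambda m: m[0]):
        if spiked <= 0:
            raise ValueError("spike levels must be positive")
        signals = list(signals)
        if len(signals) < 2:
            raise ValueError("need >= 2 replicates per level for an SD")
        estimates = [results.predict_concentration(s) for s in signals]
        if any(e.flag == "above-range" for e in estimates):
            warnings.warn(
                f"spike level {spiked} uM has above-range replicates; "
                "excluded from summary", stacklevel=2)
            records.append(RecoveryRecord(
                spiked=float(spiked), recovered_mean=np.nan,
                recovered_sd=np.nan, recovery_percent=np.nan,
                rsd_percent=np.nan, n_replicates=len(signals),
                flag="above-range"))
            continue
        recovered = np.array([e.concentration for e in estimates]) - blank_conc
        mean = float(recovered.mean())
        sd = float(np.std(recovered, ddof=1))
        records.append(RecoveryRecord(
            spiked=float(spiked), recovered_mean=mean, recovered_sd=sd,
            recovery_percent=100.0 * mean / float(spiked),
            rsd_percent=100.0 * sd / mean if mean != 0 else np.nan,
            n_replicates=len(signals)))
    return records


def recovery_table(records: Sequence[RecoveryRecord]) -> pd.DataFrame:
    """Recovery records as a table in the conventional column order."""
    return pd.DataFrame([
        {"spiked_uM": r.spiked, "recovered_uM": r.recovered_mean,
         "recovered_sd_uM": r.recovered_sd,
         "recovery_percent": r.recovery_percent,
         "rsd_percent": r.rsd_percent, "n": r.n_replicates, "flag": r.flag}
        for r in records])


def stability_series(signals_by_day: pd.DataFrame | Sequence[tuple[float, float]]) -> pd.DataFrame:
    """Signal retention over storage, as percent of the initial reading.

    Input: (day, signal) pairs or a DataFrame with columns day, signal.
    Output adds percent_of_initial = 100 * signal / first signal. No
    monotone decay is enforced; readings are reported as measured.
    """
    if not isinstance(signals_by_day, pd.DataFrame):
        signals_by_day = pd.DataFrame(signals_by_day, columns=["day", "signal"])
    if signals_by_day.empty:
        raise ValueError("stability table is empty")
    df = signals_by_day.sort_values("day").reset_index(drop=True)
    initial = float(df["signal"].iloc[0])
    if initial <= 0:
        raise ValueError("initial signal must be positive")
    df["percent_of_initial"] = 100.0 * df["signal"] / initial
    return df
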