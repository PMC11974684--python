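"""Plate-reader assay summaries: melt-curve Tm and trans-cleavage initial rate.

The thermal-shift assay reports dye fluorescence at 1 degC increments from
25 to 99 degC; the melting temperature is defined as the temperature of the
fluorescence peak (the raw-signal maximum, not a derivative).  A protein
that never folds/unfolds detectably shows no interior peak — the maximum
sits on a grid boundary — and is flagged rather than assigned a Tm.

Trans-cleavage (collateral ssDNA reporter) curves are summarised by their
initial rate: the ordinary least-squares slope of fluorescence against time
over an early window, by default the first 10% of the observed time span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MeltCurve", "TransCurve", "TmResult", "tm_from_melt", "initial_rate"]


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence vs temperature from a thermal-shift assay."""

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "temperatures", np.asarray(self.temperatures, dtype=float))
        object.__setattr__(self, "fluorescence", np.asarray(self.fluorescence, dtype=float))
        if self.temperatures.size != self.fluorescence.size:
            raise ValueError("temperature and fluorescence arrays must have equal length")
        if self.temperatures.size > 1 and not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TransCurve:
    """Fluorescence (RFU) vs time (s) from a trans-cleavage reporter assay."""

    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "fluorescence", np.asarray(self.fluorescence, dtype=float))
        if self.times.size != self.fluorescence.size:
            raise ValueError("time and fluorescence arrays must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")


@dataclass(frozen=True)
class TmResult:
    """Melting temperature with peak diagnostics.

    ``no_peak`` is set when the fluorescence maximum lies on a boundary of
    the temperature grid (no interior peak detectable); ``tm`` still reports
    the argmax temperature for inspection.  ``tie`` is set when several
    temperatures share the maximum; the lowest is reported.
    """

    tm: float
    no_peak: bool = False
    tie: bool = False


def tm_from_melt(curve: MeltCurve) -> TmResult:
    """Melting temperature = temperature of the global fluorescence maximum."""
    if curve.temperatures.size < 3:
        raise ValueError("need >= 3 points to call a melt peak")
    fl = curve.fluorescence
    peak_value = fl.max()
    peak_indices = np.flatnonzero(fl == peak_value)
    idx = int(peak_indices[0])  # ties broken toward the lowest temperature
    tie = peak_indices.size > 1
    if tie:
        warnings.warn(
            f"melt curve has {peak_indices.size} equally maximal points; "
            f"reporting the lowest temperature",
            stacklevel=2,
        )
    no_peak = idx == 0 or idx == fl.size - 1
    return TmResult(tm=float(curve.temperatures[idx]), no_peak=no_peak, tie=tie)


def initial_rate(curve: TransCurve, window: tuple[float, float] | None = None) -> float:
    """Initial trans-cleavage rate (RFU/s): OLS slope over an early window.

    ``window`` is (t_start, t_end) inclusive; by default the first 10% of
    the time span from the first sample.
    """
    t, fl = curve.times, curve.fluorescence
    if window is None:
        span = t[-1] - t[0]
        window = (t[0], t[0] + 0.1 * span)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"window [{lo}, {hi}] selects {int(mask.sum())} point(s); need >= 2"
        )
    slope, _intercept = np.polyfit(t[mask], fl[mask], 1)
    return float(slope)
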