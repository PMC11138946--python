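"""Epidemic wave delimitation and severity measures.

Waves are delimited on the daily-sampled detected-incidence series C(t) by
prominence-based peak nomination followed by trough rules:

  (i)   the trough between two successive waves has fewer than 500 cases;
  (ii)  a trough comes 5 or more days after the preceding peak;
  (iii) a wave lasts at least one week;
  (iv)  a peak's prominence is at least 10 cases/day above the higher of
        its flanking troughs;
  (v)   the prominence is at least 50% of the peak height.

If the series never exceeds one plus the initial number of infected
individuals the disease died out and there is no wave at all; otherwise at
least one wave (containing the global maximum) is reported.

Severity of a run is summarized by the wave count n_w, the overall peak
height H_p and time T_p, the time T_c1 at which the effective reproductive
number first falls to one, and the final epidemic size F_T = 1 - S(T)/N0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .epidemic import ReproductionSeries

__all__ = ["Wave", "WaveSet", "SeveritySummary", "WaveRules",
           "detect_waves", "severity_summary", "time_to_curb"]


@dataclass(frozen=True)
class WaveRules:
    """Thresholds of the five wave rules (defaults as stated above)."""

    trough_max: float = 500.0       # rule (i), cases/day
    peak_trough_gap: float = 5.0    # rule (ii), days
    min_duration: float = 7.0       # rule (iii), days
    min_prominence: float = 10.0    # rule (iv), cases/day
    prominence_ratio: float = 0.5   # rule (v)


@dataclass(frozen=True)
class Wave:
    """One delimited epidemic wave on the daily incidence series."""

    start: float
    end: float
    peak_day: float
    peak_height: float
    prominence: float
    left_trough: float
    right_trough: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class WaveSet:
    """Ordered, disjoint waves detected on one incidence series."""

    waves: tuple[Wave, ...]
    epidemic: bool
    days: np.ndarray = field(repr=False)
    C: np.ndarray = field(repr=False)

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def n_secondary(self) -> int:
        """Secondary-wave count max(n_w - 1, 0)."""
        return max(self.n_waves - 1, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start": w.start, "end": w.end, "peak_day": w.peak_day,
              "peak_height": w.peak_height, "prominence": w.prominence,
              "left_trough": w.left_trough, "right_trough": w.right_trough}
             for w in self.waves]
        )


def _trough_between(C: np.ndarray, i: int, j: int) -> int:
    """Index of the lowest point strictly between peak indices i < j."""
    seg = C[i + 1:j]
    return i + 1 + int(np.argmin(seg))


def detect_waves(
    C_daily,
    initial_infected: float = 4.0,
    rules: WaveRules | None = None,
) -> WaveSet:
    """Delimit epidemic waves on a daily incidence series.

    Parameters
    ----------
    C_daily
        Non-negative series of new detected cases per day at 1-day
        spacing; a pandas Series index is used as the day axis.
    initial_infected
        Infected-or-incubating individuals at t=0 (E0+Ia0+Is0+Id0); the
        epidemic is declared dead if C never reaches 1 + this count.
    rules
        Thresholds of the five wave rules.

    Peaks are nominated by prominence (rules iv-v), neighbouring peaks are
    merged when the trough between them violates rule (i) or (ii) (the
    lower peak is absorbed), and remaining waves shorter than rule (iii)'s
    week are dropped (the global peak's wave is always kept).
    """
    rules = rules or WaveRules()
    if isinstance(C_daily, pd.Series):
        days = np.asarray(C_daily.index, dtype=float)
        C = np.asarray(C_daily.values, dtype=float)
    else:
        C = np.asarray(C_daily, dtype=float)
        days = np.arange(C.shape[0], dtype=float)
    if C.size == 0:
        raise ValueError("empty incidence series")
    if np.any(C < 0):
        raise ValueError("incidence series must be non-negative")

    epidemic = bool(C.max() >= 1.0 + initial_infected)
    if not epidemic:
        return WaveSet(waves=(), epidemic=False, days=days, C=C)

    # Rule (iv)-(v): nominate candidate peaks by prominence.  Plateaus are
    # resolved to their first index.
    idx, props = find_peaks(C, prominence=rules.min_prominence)
    if idx.size:
        keep = props["prominences"] >= rules.prominence_ratio * C[idx]
        idx = idx[keep]
    g = int(np.argmax(C))
    if g not in idx:
        idx = np.sort(np.append(idx, g))
    peaks = list(np.sort(idx))

    # Rules (i)-(ii): merge peaks across troughs that fail to separate
    # waves, absorbing the lower of the two peaks; repeat to a fixed point.
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for k in range(len(peaks) - 1):
            i, j = peaks[k], peaks[k + 1]
            tr = _trough_between(C, i, j)
            bad = (C[tr] >= rules.trough_max
                   or days[tr] - days[i] < rules.peak_trough_gap)
            if bad:
                drop = k if C[i] < C[j] or (C[i] == C[j] and i != g) else k + 1
                if peaks[drop] == g:
                    drop = k + 1 if drop == k else k
                del peaks[drop]
                changed = True
                break

    # Delimit waves at the troughs between surviving peaks (series ends
    # bound the outermost waves).
    bounds = [0]
    for k in range(len(peaks) - 1):
        bounds.append(_trough_between(C, peaks[k], peaks[k + 1]))
    bounds.append(C.shape[0] - 1)

    proms = peak_prominences(C, np.asarray(peaks, dtype=int))[0] if peaks else []
    waves = []
    for k, pk in enumerate(peaks):
        waves.append(Wave(
            start=float(days[bounds[k]]),
            end=float(days[bounds[k + 1]]),
            peak_day=float(days[pk]),
            peak_height=float(C[pk]),
            prominence=float(proms[k]),
            left_trough=float(C[bounds[k]]),
            right_trough=float(C[bounds[k + 1]]),
        ))

    # Rule (iii): drop waves lasting less than a week, keeping the wave
    # holding the global maximum.
    kept = [w for w in waves
            if w.duration >= rules.min_duration or w.peak_day == float(days[g])]
    return WaveSet(waves=tuple(kept), epidemic=True, days=days, C=C)


def time_to_curb(reproduction: ReproductionSeries) -> float:
    """First down-crossing of the effective reproductive number through 1.

    Located by linear interpolation between output knots; NaN when the
    outbreak never takes off (R0 <= 1) or R(t) never falls to one.
    """
    if reproduction.R0 <= 1.0:
        return math.nan
    t, Rt = reproduction.t, reproduction.Rt
    above = Rt > 1.0
    for i in range(1, t.shape[0]):
        if above[i - 1] and not above[i]:
            r0, r1 = Rt[i - 1], Rt[i]
            return float(t[i - 1] + (r0 - 1.0) / (r0 - r1) * (t[i] - t[i - 1]))
    return math.nan


@dataclass(frozen=True)
class SeveritySummary:
    """Severity measures of one solved run."""

    epidemic: bool
    n_waves: int
    n_secondary: int
    peak_height: float
    peak_time: float
    time_to_curb: float
    final_size: float

    def to_dict(self) -> dict:
        return {
            "epidemic": self.epidemic,
            "n_waves": self.n_waves,
            "n_secondary": self.n_secondary,
            "peak_height": self.peak_height,
            "peak_time": self.peak_time,
            "time_to_curb": self.time_to_curb,
            "final_size": self.final_size,
        }


def severity_summary(
    trajectory,
    waves: WaveSet | None = None,
    reproduction: ReproductionSeries | None = None,
    T: float | None = None,
    rules: WaveRules | None = None,
) -> SeveritySummary:
    """Compute the severity measures of a solved trajectory.

    ``T`` defaults to the trajectory horizon.  Waves are delimited on the
    daily-sampled incidence (the observable daily counts); H_p and T_p are
    read off the finer output grid.  T_c1 comes from the
    effective-reproduction series (NaN when R0 <= 1 or no crossing);
    F_T = 1 - S(T)/N0.
    """
    daily = trajectory.daily_incidence()
    if waves is None:
        waves = detect_waves(daily, initial_infected=trajectory.initial.infected,
                             rules=rules)
    if reproduction is None:
        reproduction = trajectory.reproduction
    return SeveritySummary(
        epidemic=waves.epidemic,
        n_waves=waves.n_waves,
        n_secondary=waves.n_secondary,
        peak_height=trajectory.peak_incidence,
        peak_time=trajectory.peak_time,
        time_to_curb=time_to_curb(reproduction),
        final_size=trajectory.final_size(T),
    )
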