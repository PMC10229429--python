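"""Windowed physiological endpoints of an ultrasound-induced hypothermia bout.

Each endpoint compares an extremum inside a fixed post-stimulation search
window against a pre-stimulation baseline mean.  Window conventions are
half-open ``[start, end)`` in seconds relative to the ultrasound onset;
the presets encode the windows used for each signal:

=========  =====================  ==================
signal     baseline (s)           search (s)
=========  =====================  ==================
T_BAT      [-900, 0)              [420, 720)   (7-12 min)
T_core     [-360, -60)            [0, 1800)    (first 30 min)
VO2        [-360, -60)            [0, 1800)
RQ         [-1800, -120)          [2700, 3300) (45-55 min)
=========  =====================  ==================

Sampling is handled sample-wise (no interpolation) for extrema; only the
RQ ratio aligns VCO2 to VO2 timestamps by nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries

__all__ = [
    "EndpointConfig",
    "BAT_CONFIG",
    "CORE_CONFIG",
    "VO2_CONFIG",
    "RQ_CONFIG",
    "baseline_mean",
    "max_delta",
    "rq_trace",
    "max_delta_rq",
    "uih_onset",
    "uih_end",
    "uih_duration",
]


@dataclass(frozen=True)
class EndpointConfig:
    """Baseline and search windows in seconds relative to ultrasound onset."""

    baseline_window: tuple[float, float]
    search_window: tuple[float, float]
    aggregation: str = "min"

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        s0, s1 = self.search_window
        if not (b1 > b0 and s1 > s0):
            raise ValueError("windows must be non-empty")
        if b1 > 0:
            raise ValueError("baseline window must precede the stimulation onset")
        if self.aggregation not in ("min", "max"):
            raise ValueError("aggregation must be 'min' or 'max'")


BAT_CONFIG = EndpointConfig((-900.0, 0.0), (420.0, 720.0))
CORE_CONFIG = EndpointConfig((-360.0, -60.0), (0.0, 1800.0))
VO2_CONFIG = EndpointConfig((-360.0, -60.0), (0.0, 1800.0))
RQ_CONFIG = EndpointConfig((-1800.0, -120.0), (2700.0, 3300.0))


def baseline_mean(trace: TimeSeries, window: tuple[float, float]) -> float:
    """Arithmetic mean of samples with time in the half-open ``[start, end)``."""
    mask = trace.window_mask(*window)
    if not mask.any():
        raise ValueError("no baseline samples")
    return float(trace.values[mask].mean())


def max_delta(trace: TimeSeries, cfg: EndpointConfig, us_onset: float) -> float:
    """Windowed extremum minus the baseline mean (negative for a dip).

    With ``aggregation='min'`` this is the maximum *decrease*: the minimum
    of the trace inside the search window relative to the baseline mean.
    """
    b0, b1 = cfg.baseline_window
    base = baseline_mean(trace, (us_onset + b0, us_onset + b1))
    s0, s1 = cfg.search_window
    mask = trace.window_mask(us_onset + s0, us_onset + s1)
    if not mask.any():
        raise ValueError("no samples in search window")
    agg = np.min if cfg.aggregation == "min" else np.max
    return float(agg(trace.values[mask]) - base)


def rq_trace(vco2: TimeSeries, vo2: TimeSeries, align_tolerance_s: float = 30.0) -> TimeSeries:
    """Respiratory quotient VCO2/VO2, sampled on the VO2 timestamps.

    VCO2 samples are matched by nearest neighbour within the tolerance;
    unmatched points and points with VO2 <= 0 are NaN.
    """
    if vco2.times[-1] < vo2.times[0] or vo2.times[-1] < vco2.times[0]:
        raise ValueError("VCO2 and VO2 time ranges are disjoint")
    idx = np.searchsorted(vco2.times, vo2.times)
    idx = np.clip(idx, 1, len(vco2) - 1) if len(vco2) > 1 else np.zeros(len(vo2), dtype=int)
    if len(vco2) > 1:
        left = vco2.times[idx - 1]
        right = vco2.times[idx]
        use_left = (vo2.times - left) <= (right - vo2.times)
        nearest = np.where(use_left, idx - 1, idx)
    else:
        nearest = idx
    dist = np.abs(vco2.times[nearest] - vo2.times)
    vals = np.where(
        (dist <= align_tolerance_s) & (vo2.values > 0),
        vco2.values[nearest] / np.where(vo2.values > 0, vo2.values, 1.0),
        np.nan,
    )
    return TimeSeries(vo2.times.copy(), vals, "ratio")


def max_delta_rq(rq: TimeSeries, us_onset: float, cfg: EndpointConfig = RQ_CONFIG) -> float:
    """Lowest RQ in the 45-55 min window minus the pre-stimulation baseline."""
    return max_delta(rq, cfg, us_onset)


def uih_onset(
    trace: TimeSeries,
    us_onset: float,
    baseline_window: tuple[float, float] = (-360.0, -60.0),
) -> float | None:
    """First post-onset time the trace falls below baseline mean - 2 s.d.

    The s.d. is the sample standard deviation (n-1 denominator) of the
    baseline samples.  Returns the absolute sample time, or None if the
    threshold is never crossed.
    """
    b0, b1 = baseline_window
    mask = trace.window_mask(us_onset + b0, us_onset + b1)
    if mask.sum() < 2:
        raise ValueError("need at least 2 baseline samples")
    base = trace.values[mask]
    threshold = base.mean() - 2.0 * base.std(ddof=1)
    post = trace.times >= us_onset
    below = post & (trace.values < threshold)
    if not below.any():
        return None
    return float(trace.times[below][0])


def uih_end(t_core: TimeSeries, after: float, threshold: float = 34.0) -> float | None:
    """First time at/after ``after`` the core temperature returns to threshold.

    Requires the trace to be below the threshold at ``after`` (the bout
    must be in progress); returns None otherwise or if the temperature
    never comes back up.
    """
    at = t_core.times >= after
    if not at.any():
        raise ValueError("trace does not extend past 'after'")
    vals = t_core.values[at]
    times = t_core.times[at]
    if vals[0] >= threshold:
        return None  # was never below threshold at 'after'
    recovered = vals >= threshold
    if not recovered.any():
        return None
    return float(times[recovered][0])


def uih_duration(onset: float | None, end: float | None) -> float | None:
    """Bout duration in minutes, ``(end - onset) / 60``; None if either missing."""
    if onset is None or end is None:
        return None
    return (end - onset) / 60.0
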