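"""Capnogram container and breath segmentation.

A capnogram is a uniformly sampled CO2 partial-pressure time series from a
sidestream analyzer. During rebreathing through an external dead space the
inspired CO2 level rises breath by breath, so segmentation uses an adaptive
mid-range threshold (running minimum/maximum over a sliding window of a few
breath periods) with hysteresis, rather than a fixed cut-off that would fail
once the inspiratory trough climbs.

Pressures are handled internally in kPa; mmHg input is converted at the I/O
boundary (see :mod:`rebreathe.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import detrend

from .errors import (
    EndTidalError,
    InsufficientBreathsError,
    NoRespiratorySignalError,
)

#: kPa per mmHg (exact definition of the conventional millimetre of mercury).
MMHG_TO_KPA = 0.133322

#: Fallback nominal breath period (s) when the trace is too short or too
#: aperiodic for autocorrelation-based period estimation (12 breaths/min).
DEFAULT_BREATH_PERIOD_S = 5.0


@dataclass(frozen=True)
class CapnogramTrace:
    """Uniformly sampled CO2 partial-pressure time series.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing with uniform step
        ``1/sample_rate`` (tolerance 1e-9 s).
    pco2
        CO2 partial pressure per sample, kPa, non-negative.
    sample_rate
        Sampling frequency, Hz.
    meta
        Free-form provenance (seed, simulator parameters, source file...).
    """

    times: np.ndarray
    pco2: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pco2 = np.asarray(self.pco2, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pco2", pco2)
        if times.ndim != 1 or pco2.ndim != 1 or times.size != pco2.size:
            raise ValueError("times and pco2 must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("a capnogram needs at least two samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if np.any(pco2 < 0):
            raise ValueError("pco2 must be non-negative")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.max(np.abs(steps - 1.0 / self.sample_rate)) >= 1e-9:
            raise ValueError("times must be uniform with step 1/sample_rate")

    @property
    def duration(self) -> float:
        """Trace span in seconds."""
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BreathSegment:
    """One detected expiration with its end-tidal CO2 value.

    ``index`` 0 is the first expiration into the dead space (the subject
    starts the manoeuvre with an expiration); all Pet rises downstream are
    referenced to it. ``valid`` is False when the expiratory phase abuts a
    trace boundary and may be truncated.
    """

    index: int
    t_exp_start: float
    t_exp_end: float
    pet: float
    valid: bool = True

    def __post_init__(self) -> None:
        if not self.t_exp_start < self.t_exp_end:
            raise ValueError("t_exp_start must precede t_exp_end")


def extract_end_tidal(window: Sequence[float], tail_fraction: float = 0.25) -> float:
    """End-tidal CO2 from one expiratory window of samples.

    Median-of-3 smoothing (edges passed through) suppresses single-sample
    spikes; the end-tidal value is the maximum of the smoothed signal over
    the final ``tail_fraction`` of the window, which captures the end of the
    alveolar plateau. When samples tie for the maximum the later one is the
    conceptual end-tidal point; the returned value is the same either way.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise EndTidalError(
            "unresolvable end-tidal: expiratory window needs >= 3 samples"
        )
    smoothed = w.copy()
    smoothed[1:-1] = np.median(sliding_window_view(w, 3), axis=1)
    n_tail = max(1, int(np.ceil(tail_fraction * w.size)))
    return float(smoothed[-n_tail:].max())


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    win = max(1, min(win, x.size))
    kernel = np.full(win, 1.0 / win)
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.size]


def _estimate_breath_period(
    x: np.ndarray,
    sample_rate: float,
    min_period_s: float = 1.2,
    max_period_s: float = 20.0,
) -> float:
    """Dominant breath period via autocorrelation of the band-passed signal.

    A short moving average suppresses analyzer noise and a long one removes
    the slow rebreathing drift (which would otherwise dominate the
    autocorrelation at all lags); the first 25% of the trace is skipped so
    the manoeuvre-onset step does not swamp the respiratory oscillation.
    The period is the earliest strong autocorrelation peak between
    ``min_period_s`` and ``max_period_s``. Falls back to 5 s
    (12 breaths/min) when the trace is too short to resolve a period.
    """
    from scipy.signal import find_peaks

    lo = int(round(min_period_s * sample_rate))
    if x.size < 2 * lo + 2:
        return DEFAULT_BREATH_PERIOD_S
    xf = np.asarray(x[x.size // 4 :], dtype=float)
    xf = _moving_average(xf, int(round(0.3 * sample_rate)))
    xf = xf - _moving_average(xf, int(round(0.5 * max_period_s * sample_rate)))
    xf = detrend(xf)
    ac = np.correlate(xf, xf, mode="full")[xf.size - 1 :]
    hi = min(ac.size - 1, int(round(max_period_s * sample_rate)))
    if hi <= lo or ac[0] <= 0:
        return DEFAULT_BREATH_PERIOD_S
    peaks, _ = find_peaks(ac[: hi + 1])
    peaks = peaks[(peaks >= lo) & (ac[peaks] > 0)]
    if peaks.size == 0:
        return DEFAULT_BREATH_PERIOD_S
    # subharmonic guard: prefer the earliest peak comparable to the best one
    best = float(ac[peaks].max())
    lag = int(peaks[ac[peaks] >= 0.6 * best][0])
    return lag / sample_rate


def _runs(state: np.ndarray) -> list[tuple[bool, int, int]]:
    """Consecutive runs of a boolean array as (value, start, stop) with stop exclusive."""
    edges = np.flatnonzero(np.diff(state.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    stops = np.concatenate((edges + 1, [state.size]))
    return [(bool(state[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def _merge_short_runs(
    state: np.ndarray, min_samples: int
) -> list[tuple[bool, int, int]]:
    """Flip runs shorter than ``min_samples`` into their neighbours until stable."""
    work = state.copy()
    for _ in range(state.size):  # bounded; converges far sooner
        runs = _runs(work)
        short = [
            i for i, (_, a, b) in enumerate(runs) if (b - a) < min_samples
        ]
        if not short or len(runs) == 1:
            return runs
        # flip the shortest offender first, then re-derive runs
        i = min(short, key=lambda i: runs[i][2] - runs[i][1])
        val, a, b = runs[i]
        work[a:b] = not val
    return _runs(work)


def segment_breaths(
    trace: CapnogramTrace,
    min_phase_s: float = 0.3,
    window_breaths: float = 1.0,
    nominal_period_s: float | None = None,
    hysteresis_frac: float = 0.10,
    min_range_kpa: float = 0.2,
    tail_fraction: float = 0.25,
) -> list[BreathSegment]:
    """Segment a capnogram into expirations and extract end-tidal values.

    A Schmitt trigger on an adaptive mid-range threshold classifies each
    sample as expiratory (high CO2) or inspiratory (low CO2). The threshold
    is the mean of the running minimum and maximum over a sliding window of
    ``window_breaths`` nominal breath periods, with a hysteresis band of
    ``hysteresis_frac`` of the running range, so detection survives the
    rising inspiratory trough of rebreathing. Phases shorter than
    ``min_phase_s`` are merged into their neighbours (suppresses threshold
    chatter from analyzer noise).

    Raises
    ------
    NoRespiratorySignalError
        If the running range never exceeds ``min_range_kpa``.
    InsufficientBreathsError
        If fewer than three expirations are detected.
    """
    if min_phase_s <= 0:
        raise ValueError("min_phase_s must be positive")
    x = trace.pco2
    fs = trace.sample_rate
    if float(x.max() - x.min()) < min_range_kpa:
        raise NoRespiratorySignalError(
            f"no respiratory signal: range {x.max() - x.min():.3g} kPa "
            f"< {min_range_kpa} kPa"
        )
    period = (
        float(nominal_period_s)
        if nominal_period_s is not None
        else _estimate_breath_period(x, fs)
    )
    win = max(3, int(round(window_breaths * period * fs)))
    run_min = minimum_filter1d(x, size=win, mode="nearest")
    run_max = maximum_filter1d(x, size=win, mode="nearest")
    run_range = run_max - run_min
    if float(run_range.max()) < min_range_kpa:
        raise NoRespiratorySignalError("no respiratory signal: flat running range")
    mid = 0.5 * (run_min + run_max)
    half_band = 0.5 * hysteresis_frac * run_range
    upper = mid + half_band
    lower = mid - half_band

    state = np.empty(x.size, dtype=bool)
    high = bool(x[0] > mid[0])
    for i in range(x.size):
        if high:
            if x[i] < lower[i]:
                high = False
        elif x[i] > upper[i]:
            high = True
        state[i] = high

    runs = _merge_short_runs(state, min_samples=max(2, int(round(min_phase_s * fs))))

    segments: list[BreathSegment] = []
    for val, a, b in runs:
        if not val:
            continue
        window = x[a:b]
        if window.size < 3:
            continue
        pet = extract_end_tidal(window, tail_fraction=tail_fraction)
        complete = a > 0 and b < x.size
        segments.append(
            BreathSegment(
                index=len(segments),
                t_exp_start=float(trace.times[a]),
                t_exp_end=float(trace.times[b - 1]),
                pet=pet,
                valid=complete,
            )
        )
    if len(segments) < 3:
        raise InsufficientBreathsError(
            f"insufficient breaths: detected {len(segments)}, need >= 3"
        )
    return segments


def breath_periods(segments: Sequence[BreathSegment]) -> np.ndarray:
    """Breath periods (s) from consecutive expiration onsets."""
    starts = np.array([s.t_exp_start for s in segments], dtype=float)
    return np.diff(starts)
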