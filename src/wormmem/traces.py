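"""Trace normalization, resampling, feature windows, and derivatives.

Raw fluorescence F is normalized by the neuron's *ground state* F_G — the
baseline intensity the neuron sits at between stimulus-evoked transients —
giving the dimensionless F/F_G used throughout the downstream statistics.
Two F_G detectors are provided: a quantile-based one for long exchange
recordings (smooth with a 20-frame moving average, then average the smoothed
values lying strictly below the 10% quantile) and a tail-based one for short
recordings where the neuron returns to baseline by the end (mean of the last
10 frames).  An alternative peak normalization maps baseline to 0 and the
maximal fluorescence to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .datamodel import StimulusSchedule

__all__ = [
    "NormalizationMode",
    "NormalizedTrace",
    "ResponseWindow",
    "moving_average",
    "detect_ground_state",
    "detect_ground_state_tail",
    "normalize",
    "resample_linear",
    "time_derivative",
    "integrate_post_switch",
    "bin_and_znorm",
]


class NormalizationMode(str, Enum):
    ground_state = "ground_state"
    max = "max"


@dataclass
class NormalizedTrace:
    """A normalized fluorescence series on a (uniform or native) time base."""

    values: np.ndarray
    time: np.ndarray
    mode: NormalizationMode
    F_G: float
    F_max: float | None = None
    neuron_id: str | None = None
    animal_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.mode = NormalizationMode(self.mode)

    @property
    def frame_rate(self) -> float:
        dt = np.diff(self.time)
        return 1.0 / float(np.mean(dt))


@dataclass(frozen=True)
class ResponseWindow:
    """Integrated activity in a fixed window after one stimulus switch."""

    start: float
    duration: float
    integrated_activity: float
    switch_index: int


def moving_average(x: np.ndarray, kernel_frames: int) -> np.ndarray:
    """Centered moving average with edge truncation.

    Near the edges the window is clipped to the available samples and the
    mean taken over what remains, so output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if kernel_frames < 1:
        raise ValueError("kernel_frames must be >= 1")
    n = x.size
    k = int(kernel_frames)
    half_lo = (k - 1) // 2
    half_hi = k - 1 - half_lo
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def detect_ground_state(
    trace: np.ndarray, kernel_frames: int = 20, quantile: float = 0.10
) -> float:
    """Quantile-based ground state for long recordings.

    Smooth the intensity vector with a ``kernel_frames`` moving average, take
    the ``quantile`` (linear-interpolation) of the smoothed values, and return
    the mean of the smoothed values strictly below it.  If no smoothed value
    lies strictly below the quantile (constant trace), the quantile value
    itself is returned.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < kernel_frames:
        raise ValueError(
            f"trace has {trace.size} frames; quantile ground-state detection "
            f"needs at least kernel_frames={kernel_frames}"
        )
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    smoothed = moving_average(trace, kernel_frames)
    q = float(np.quantile(smoothed, quantile))
    below = smoothed[smoothed < q]
    if below.size == 0:
        return q
    return float(np.mean(below))


def detect_ground_state_tail(trace: np.ndarray, n_frames: int = 10) -> float:
    """Tail-based ground state: mean of the last ``n_frames`` intensities.

    Appropriate for short recordings in which the neuron has resumed its
    pre-stimulus baseline by the end of imaging; also the manual-override
    hook for interneurons whose baseline is identified by eye (pass the
    visually chosen frames as ``trace``).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < n_frames:
        raise ValueError(
            f"trace has {trace.size} frames; tail ground state needs >= {n_frames}"
        )
    return float(np.mean(trace[-n_frames:]))


def normalize(
    trace: np.ndarray,
    time: np.ndarray,
    mode: NormalizationMode | str = NormalizationMode.ground_state,
    F_G: float | None = None,
    F_max: float | None = None,
    **meta,
) -> NormalizedTrace:
    """Normalize raw F to F/F_G (ground-state mode) or (F−F_G)/(F_max−F_G).

    In ground-state mode the baseline maps to 1; in max mode the baseline
    maps to 0 and the peak to 1.
    """
    mode = NormalizationMode(mode)
    trace = np.asarray(trace, dtype=float)
    if F_G is None:
        raise ValueError("F_G is required (run a ground-state detector first)")
    if mode is NormalizationMode.ground_state:
        if not F_G > 0:
            raise ValueError(
                "F_G must be > 0 for F/F_G; use the tail detector or a manual "
                "override for this record"
            )
        values = trace / F_G
    else:
        if F_max is None or not F_max > F_G:
            raise ValueError("max mode requires F_max > F_G")
        values = (trace - F_G) / (F_max - F_G)
    return NormalizedTrace(
        values=values, time=np.asarray(time, float), mode=mode, F_G=float(F_G),
        F_max=None if F_max is None else float(F_max), **meta,
    )


def resample_linear(
    traces: Sequence[NormalizedTrace], target_rate: float | None = None
) -> list[NormalizedTrace]:
    """Linearly interpolate each trace to a uniform grid at ``target_rate``.

    Recordings acquired at mixed frame rates (2–5 Hz across datasets) are
    brought to a common rate, by default the highest rate present.  The grid
    for each trace spans its own recorded interval; values are never
    extrapolated beyond the original endpoints.
    """
    if not traces:
        return []
    for tr in traces:
        if tr.time.size < 2:
            raise ValueError("cannot resample a trace with fewer than 2 samples")
    if target_rate is None:
        target_rate = max(tr.frame_rate for tr in traces)
    dt = 1.0 / float(target_rate)
    out = []
    for tr in traces:
        t0, t1 = float(tr.time[0]), float(tr.time[-1])
        n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
        grid = t0 + dt * np.arange(n)
        vals = np.interp(grid, tr.time, tr.values)
        out.append(
            NormalizedTrace(
                values=vals, time=grid, mode=tr.mode, F_G=tr.F_G, F_max=tr.F_max,
                neuron_id=tr.neuron_id, animal_id=tr.animal_id,
            )
        )
    return out


def time_derivative(trace: NormalizedTrace, smooth_frames: int = 0) -> np.ndarray:
    """Finite-difference time derivative (1/s) of a uniformly sampled trace.

    Optionally pre-smooths with a centered moving average.  Central
    differences in the interior, one-sided at the ends, so the output has the
    input's length.  The derivative form isolates the sensory-evoked
    component of interneuron activity from slow baseline shifts.
    """
    t = trace.time
    dt = np.diff(t)
    if dt.size == 0:
        raise ValueError("derivative needs at least 2 samples")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform time base; resample_linear first")
    vals = trace.values
    if smooth_frames and smooth_frames > 1:
        vals = moving_average(vals, smooth_frames)
    return np.gradient(vals, t)


def integrate_post_switch(
    trace: NormalizedTrace,
    schedule: StimulusSchedule,
    window_s: float = 10.0,
    per_neuron_overrides: Mapping[str, float] | None = None,
) -> list[ResponseWindow]:
    """Sum normalized activity in [switch, switch + window) per stimulus switch.

    The default 10-s window is overridable per neuron because integration
    times are neuron-specific (response kinetics vary widely between neuron
    classes); pass ``per_neuron_overrides={'AWA': 15.0, ...}``.
    """
    window = float(window_s)
    if per_neuron_overrides and trace.neuron_id in per_neuron_overrides:
        window = float(per_neuron_overrides[trace.neuron_id])
    if not window > 0:
        raise ValueError("integration window must be positive")
    out: list[ResponseWindow] = []
    t_end = float(trace.time[-1])
    for i, sw in enumerate(schedule.switch_times):
        if sw + window > t_end + 1e-9:
            raise ValueError(
                f"integration window [{sw}, {sw + window}) for switch {i} "
                f"exceeds the recording (ends at {t_end} s)"
            )
        mask = (trace.time >= sw) & (trace.time < sw + window)
        out.append(
            ResponseWindow(
                start=float(sw),
                duration=window,
                integrated_activity=float(np.sum(trace.values[mask])),
                switch_index=i,
            )
        )
    return out


def bin_and_znorm(values: np.ndarray, kernel_frames: int = 20) -> np.ndarray:
    """Bin into non-overlapping ``kernel_frames``-frame means, then z-score.

    The trailing partial bin is dropped.  Z-scoring uses the population SD
    (n divisor); a zero-variance binned vector maps to all zeros.  This is
    the feature transform feeding the condition classifiers.
    """
    values = np.asarray(values, dtype=float)
    k = int(kernel_frames)
    n_bins = values.size // k
    if n_bins < 1:
        raise ValueError(
            f"trace of {values.size} frames is shorter than one {k}-frame bin"
        )
    binned = values[: n_bins * k].reshape(n_bins, k).mean(axis=1)
    sd = float(np.std(binned))
    if sd == 0.0:
        return np.zeros_like(binned)
    return (binned - float(np.mean(binned))) / sd
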