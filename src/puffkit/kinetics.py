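"""Per-event kinetic metrics and per-cell summaries.

The four event metrics follow the standard conventions for local Ca2+
transients: amplitude is baseline-to-peak on the F/F0 scale, rise time runs
from the last upward 20%-of-amplitude crossing to the peak, decay time from
the peak to the first downward 20% crossing, and duration is the time above
half-maximal amplitude.  All crossing times are linearly interpolated
between samples, so metrics are reported with sub-frame resolution.

Events with a sustained plateau near peak ('square' events, reflecting
long-lasting channel openings) have ill-defined rise times because noise
during the plateau shifts the discrete peak; they are flagged and excluded
from kinetic averages while still counting toward event frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticMetrics",
    "CellSummary",
    "measure_kinetics",
    "flag_square",
    "summarize_cell",
    "estimate_obscured_time",
]


@dataclass
class KineticMetrics:
    amplitude_dFF0: float
    rise_ms: float
    decay_ms: float
    duration_ms: float
    baseline_level: float
    peak_index: int
    flags: list[str] = field(default_factory=list)


@dataclass
class CellSummary:
    n_events: int
    frequency_hz: float
    latency_s: float | None
    recording_interval_s: float | None
    mean_amplitude_dFF0: float | None
    mean_rise_ms: float | None
    mean_decay_ms: float | None
    mean_duration_ms: float | None
    n_square_excluded: int


def _cross_up_before(trace, level, peak_idx, lo=0):
    """Interpolated time (frames) of the last upward crossing of ``level`` before the peak."""
    for i in range(peak_idx - 1, lo - 1, -1):
        if trace[i] < level <= trace[i + 1]:
            return i + (level - trace[i]) / (trace[i + 1] - trace[i])
    return None


def _cross_down_after(trace, level, peak_idx):
    """Interpolated time (frames) of the first downward crossing of ``level`` after the peak."""
    for i in range(peak_idx, len(trace) - 1):
        if trace[i] >= level > trace[i + 1]:
            return i + (trace[i] - level) / (trace[i] - trace[i + 1])
    return None


def measure_kinetics(trace: np.ndarray, event_window: tuple[int, int],
                     frame_interval_s: float, baseline_window: int = 20,
                     min_frame: int = 0) -> KineticMetrics:
    """Amplitude, rise, decay and duration of one event on an F/F0 trace.

    ``event_window`` gives (start, end) frame indices of the detected event in
    the trace; the peak is the maximum sample within it.  The local baseline
    is the mean of up to ``baseline_window`` frames immediately before the
    start (never earlier than ``min_frame``, e.g. the flash).  A decay that
    never falls back to 20% within the trace is flagged right-censored and
    reported as NaN.
    """
    trace = np.asarray(trace, float)
    start, end = event_window
    if not (0 <= start <= end < len(trace)):
        raise ValueError("event window outside the trace")
    dt_ms = frame_interval_s * 1e3
    flags: list[str] = []

    b0 = max(min_frame, start - baseline_window)
    if b0 < start:
        baseline = float(trace[b0:start].mean())
    else:
        baseline = 1.0
        flags.append("no_baseline_window")

    peak_idx = start + int(np.argmax(trace[start:end + 1]))
    peak = float(trace[peak_idx])
    amplitude = peak - baseline
    if amplitude <= 0:
        return KineticMetrics(0.0, math.nan, math.nan, math.nan, baseline,
                              peak_idx, flags + ["non_positive_amplitude"])

    l20 = baseline + 0.2 * amplitude
    l50 = baseline + 0.5 * amplitude

    t_up20 = _cross_up_before(trace, l20, peak_idx)
    if t_up20 is None:
        rise_ms = math.nan
        flags.append("rise_uncrossed")
    else:
        rise_ms = (peak_idx - t_up20) * dt_ms

    t_dn20 = _cross_down_after(trace, l20, peak_idx)
    if t_dn20 is None:
        decay_ms = math.nan
        flags.append("decay_right_censored")
    else:
        decay_ms = (t_dn20 - peak_idx) * dt_ms

    t_up50 = _cross_up_before(trace, l50, peak_idx)
    t_dn50 = _cross_down_after(trace, l50, peak_idx)
    if t_up50 is None or t_dn50 is None:
        duration_ms = math.nan
        flags.append("duration_censored")
    else:
        duration_ms = (t_dn50 - t_up50) * dt_ms

    return KineticMetrics(amplitude, rise_ms, decay_ms, duration_ms,
                          baseline, peak_idx, flags)


def flag_square(trace: np.ndarray, metrics: KineticMetrics, frame_interval_s: float,
                event_window: tuple[int, int] | None = None,
                plateau_frac: float = 0.9, plateau_min_ms: float = 50.0,
                pad_frames: int = 20) -> bool:
    """True when the trace dwells near peak long enough to count as a square event.

    The dwell time is the interpolated total time the trace spends at or
    above ``baseline + plateau_frac * amplitude`` within the event window
    (padded by ``pad_frames`` to cover the decay); exceeding
    ``plateau_min_ms`` flags the event.
    """
    trace = np.asarray(trace, float)
    if metrics.amplitude_dFF0 <= 0:
        return False
    level = metrics.baseline_level + plateau_frac * metrics.amplitude_dFF0
    if event_window is None:
        w0, w1 = 0, len(trace) - 1
    else:
        w0 = max(0, event_window[0] - pad_frames)
        w1 = min(len(trace) - 1, event_window[1] + pad_frames)
    seg = trace[w0:w1 + 1]
    dt_ms = frame_interval_s * 1e3
    above = seg >= level
    total_ms = 0.0
    i = 0
    n = len(seg)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        t_left = float(i)
        if i > 0:
            t_left = i - (seg[i] - level) / (seg[i] - seg[i - 1]) if seg[i] != seg[i - 1] else float(i)
            t_left = max(t_left, i - 1.0)
        t_right = float(j)
        if j + 1 < n:
            t_right = j + (seg[j] - level) / (seg[j] - seg[j + 1]) if seg[j] != seg[j + 1] else float(j)
            t_right = min(t_right, j + 1.0)
        total_ms += (t_right - t_left) * dt_ms
        i = j + 1
    return bool(total_ms > plateau_min_ms)


def summarize_cell(events, flash_time_s: float, stack_end_s: float,
                   obscured_time_s: float | None = None) -> CellSummary:
    """Per-cell event frequency, latency and mean kinetics.

    The recording interval runs from the first event's peak time to the end
    of the recording or, if supplied, the earlier time at which a global
    fluorescence rise made events unresolvable.  Square events count toward
    frequency but are excluded from the kinetic means, as are censored
    (NaN) metrics.
    """
    events = list(events)
    n = len(events)
    if n == 0:
        return CellSummary(0, 0.0, None, None, None, None, None, None, 0)
    peak_times = [e.peak_time_s for e in events]
    if any(t is None for t in peak_times):
        raise ValueError("all events need peak_time_s set")
    first = min(peak_times)
    end = stack_end_s if obscured_time_s is None else min(stack_end_s, obscured_time_s)
    if end < first:
        raise ValueError("obscured/end time precedes the first event")
    interval = end - first
    freq = n / interval if interval > 0 else math.nan
    latency = first - flash_time_s

    kin = [e for e in events if not e.is_square]

    def _mean(attr):
        vals = [getattr(e, attr) for e in kin]
        vals = [v for v in vals if v is not None and not math.isnan(v)]
        return float(np.mean(vals)) if vals else None

    return CellSummary(
        n_events=n,
        frequency_hz=freq,
        latency_s=latency,
        recording_interval_s=interval,
        mean_amplitude_dFF0=_mean("amplitude_dFF0"),
        mean_rise_ms=_mean("rise_ms"),
        mean_decay_ms=_mean("decay_ms"),
        mean_duration_ms=_mean("duration_ms"),
        n_square_excluded=sum(1 for e in events if e.is_square),
    )


def estimate_obscured_time(ratio_stack, level: float = 1.5) -> float | None:
    """First acquisition time at which the field-median F/F0 exceeds ``level``.

    Used to truncate the recording interval when a global Ca2+ rise obscures
    local events.  Returns None if the median never exceeds the level.
    """
    med = np.median(ratio_stack.data.reshape(ratio_stack.n_frames, -1), axis=1)
    above = np.flatnonzero(med > level)
    if above.size == 0:
        return None
    return float(ratio_stack.frame_time_s(int(above[0])))
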