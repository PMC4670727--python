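"""Per-trajectory quantifications of ERK activity time courses.

Implements the standard single-cell readouts for this assay class:
fold-change normalization to the pre-stimulus baseline, first-peak
amplitude and half-maximum duration, late (40-min) activity and the
transient/sustained classification, per-pulse maxima and their long-term
decay ratio, the time-integrated ERK activity (ERK^INT), and the
peak-versus-late Spearman correlation across cells.

Amplitude is the change from the value at stimulus onset to the highest
activity of the first response; duration is measured between the last
sample below half-maximum on the ascending phase and the first sample
below half-maximum on the descending phase (sample points, no
interpolation, unless ``interpolate=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .simulate import Trajectory
from .stimulus import StimulusProtocol

__all__ = [
    "TrajectoryMetrics",
    "normalize_baseline",
    "peak_amplitude",
    "peak_window",
    "peak_duration",
    "classify_response",
    "pulse_maxima_decay",
    "erk_integral",
    "correlate_peak_vs_late",
    "compute_metrics",
    "count_peaks",
]


@dataclass
class TrajectoryMetrics:
    baseline_value: float
    peak_amplitude: float
    peak_time: float
    peak_duration: float
    duration_censored: bool
    activity_at_40: float
    erk_int: float
    response_class: str
    pulse_maxima: list | None = None
    decay_ratio: float | None = None


def _index_at(t: np.ndarray, time: float) -> int:
    """Index of the first sample at or after ``time``."""
    i = int(np.searchsorted(t, time - 1e-9))
    if i >= len(t):
        raise ValueError(f"time {time:g} beyond trace support [{t[0]:g}, {t[-1]:g}]")
    return i


def normalize_baseline(traj: Trajectory, stim_start: float,
                       n_points: int = 5) -> Trajectory:
    """Divide the trace by the mean of the ``n_points`` samples immediately
    preceding ``stim_start`` (fold-change normalization of ratiometric data)."""
    i0 = int(np.searchsorted(traj.t, stim_start - 1e-9))
    if i0 < n_points:
        raise ValueError(
            f"need >= {n_points} pre-stimulus samples, have {i0}")
    base = float(np.mean(traj.erk[i0 - n_points:i0]))
    if base <= 0:
        raise ValueError(f"non-positive pre-stimulus baseline ({base:g})")
    out = traj.copy_with(traj.erk / base)
    out.meta["baseline_value"] = base
    return out


def peak_window(values: np.ndarray, t: np.ndarray, stim_start: float) -> tuple[int, int, int]:
    """(onset index, peak index, end index) of the first response.

    The window runs from stimulus onset to the first local minimum after
    the global early maximum, or to the trace end.
    """
    i0 = _index_at(t, stim_start)
    seg = values[i0:]
    if len(seg) == 0:
        raise ValueError("empty response window")
    m = i0 + int(np.argmax(seg))
    end = len(values) - 1
    for j in range(m + 1, len(values) - 1):
        if values[j] <= values[j - 1] and values[j] < values[j + 1]:
            end = j
            break
    return i0, m, end


def peak_amplitude(traj: Trajectory, stim_start: float) -> float:
    """Change from the value at stimulus onset to the first-response maximum."""
    i0, m, _ = peak_window(traj.erk, traj.t, stim_start)
    return float(max(traj.erk[m] - traj.erk[i0], 0.0))


def peak_duration(traj: Trajectory, stim_start: float,
                  interpolate: bool = False) -> tuple[float, bool]:
    """Half-maximum width of the first peak, in minutes.

    Returns ``(duration, censored)``; ``censored`` is True when the trace
    never falls back below half-maximum (duration then extends to the
    trace end).
    """
    v, t = traj.erk, traj.t
    i0, m, _ = peak_window(v, t, stim_start)
    amp = v[m] - v[i0]
    if amp <= 0:
        raise ValueError("no peak (non-positive amplitude)")
    half = v[i0] + 0.5 * amp

    i_before = i0
    for j in range(m, i0 - 1, -1):
        if v[j] < half:
            i_before = j
            break
    t_before = t[i_before]
    t_after, censored = t[-1], True
    i_after = len(v) - 1
    for j in range(m + 1, len(v)):
        if v[j] < half:
            t_after, censored, i_after = t[j], False, j
            break
    if interpolate and not censored:
        # linear crossings refine the sample-point rule
        if v[i_before + 1] != v[i_before]:
            t_before = t[i_before] + (half - v[i_before]) / (v[i_before + 1] - v[i_before]) \
                * (t[i_before + 1] - t[i_before])
        if v[i_after] != v[i_after - 1]:
            t_after = t[i_after - 1] + (half - v[i_after - 1]) / (v[i_after] - v[i_after - 1]) \
                * (t[i_after] - t[i_after - 1])
    return float(t_after - t_before), censored


def classify_response(traj: Trajectory, stim_start: float,
                      late_t: float = 40.0, frac: float = 0.5) -> str:
    """``"sustained"`` iff the activity excess at ``stim_start + late_t``
    is at least ``frac`` of the first-peak amplitude, else ``"transient"``."""
    v, t = traj.erk, traj.t
    i0 = _index_at(t, stim_start)
    i40 = _index_at(t, stim_start + late_t)
    amp = peak_amplitude(traj, stim_start)
    if amp <= 0:
        return "transient"
    return "sustained" if (v[i40] - v[i0]) >= frac * amp else "transient"


def pulse_maxima_decay(traj: Trajectory, protocol: StimulusProtocol
                       ) -> tuple[list[float], float]:
    """Per-pulse ERK maxima and their last/first excess ratio.

    For each ON segment the maximum over ``[pulse_start, next_pulse_start)``
    is taken; the decay ratio divides the last maximum's excess over
    baseline by the first's.
    """
    starts = traj_starts = protocol.pulse_starts()
    if len(starts) < 2:
        raise ValueError("need >= 2 pulses for a decay ratio")
    v, t = traj.erk, traj.t
    i_base = _index_at(t, starts[0])
    base = v[i_base]
    maxima = []
    bounds = list(starts[1:]) + [t[-1] + traj.dt]
    for s, e in zip(starts, bounds):
        sel = (t >= s - 1e-9) & (t < e - 1e-9)
        if not np.any(sel):
            raise ValueError(f"no samples in pulse window starting {s:g} min")
        maxima.append(float(np.max(v[sel])))
    first, last = maxima[0] - base, maxima[-1] - base
    if first <= 0:
        raise ValueError("first pulse has non-positive excess")
    return maxima, float(last / first)


def erk_integral(traj: Trajectory, stim_start: float,
                 window_start: float, window_end: float) -> float:
    """Integrated ERK activity (ERK^INT): trapezoidal integral of the
    baseline-subtracted activity (floored at 0 per sample) over the window."""
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    v, t = traj.erk, traj.t
    if window_start < t[0] - 1e-9 or window_end > t[-1] + 1e-9:
        raise ValueError("window outside trace support")
    i0 = _index_at(t, stim_start)
    excess = np.clip(v - v[i0], 0.0, None)
    sel = (t >= window_start - 1e-9) & (t <= window_end + 1e-9)
    return float(np.trapezoid(excess[sel], t[sel]))


def correlate_peak_vs_late(trajectories: list[Trajectory], stim_start: float,
                           late_t: float = 40.0) -> tuple[float, float]:
    """Spearman rank correlation between first-peak amplitude and late
    activity excess across cells. Returns ``(rho, p)``; degenerate
    (constant) inputs yield ``rho = nan``."""
    if len(trajectories) < 3:
        raise ValueError("need >= 3 trajectories")
    peaks, lates = [], []
    for tr in trajectories:
        peaks.append(peak_amplitude(tr, stim_start))
        i0 = _index_at(tr.t, stim_start)
        i40 = _index_at(tr.t, stim_start + late_t)
        lates.append(tr.erk[i40] - tr.erk[i0])
    peaks, lates = np.asarray(peaks), np.asarray(lates)
    if np.ptp(peaks) == 0 or np.ptp(lates) == 0:
        return float("nan"), float("nan")
    rho, p = spearmanr(peaks, lates)
    return float(rho), float(p)


def count_peaks(traj: Trajectory, stim_start: float,
                min_prominence: float = 0.1) -> int:
    """Number of resolvable activity peaks after stimulus onset.

    A peak is a local maximum whose rise above the deepest minimum
    separating it from the previous peak exceeds ``min_prominence`` times
    the global excess range.
    """
    from scipy.signal import find_peaks

    i0 = _index_at(traj.t, stim_start)
    v = traj.erk[i0:]
    rng = float(np.max(v) - np.min(v))
    if rng <= 0:
        return 0
    peaks, _ = find_peaks(v, prominence=min_prominence * rng)
    # a maximum at the trace start (monotone decay from an onset peak)
    # is not found by prominence search; count it when present
    if len(v) > 1 and v[0] > v[1]:
        peaks = np.r_[0, peaks]
    n = len(peaks)
    if n == 0 and rng > 0:
        n = 1  # single rise-and-fall entirely monotone within the window
    return n


def compute_metrics(traj: Trajectory, stim_start: float,
                    protocol: StimulusProtocol | None = None,
                    late_t: float = 40.0, frac: float = 0.5,
                    int_window: tuple[float, float] | None = None) -> TrajectoryMetrics:
    """All per-trajectory metrics in one record."""
    v, t = traj.erk, traj.t
    i0 = _index_at(t, stim_start)
    _, m, _ = peak_window(v, t, stim_start)
    amp = peak_amplitude(traj, stim_start)
    if amp > 0:
        dur, censored = peak_duration(traj, stim_start)
    else:
        dur, censored = 0.0, False
    late_time = stim_start + late_t
    late = v[_index_at(t, late_time)] - v[i0] if late_time <= t[-1] else float("nan")
    w0, w1 = int_window if int_window else (stim_start, float(t[-1]))
    maxima = ratio = None
    if protocol is not None and len(protocol.pulse_starts()) >= 2:
        maxima, ratio = pulse_maxima_decay(traj, protocol)
    cls = classify_response(traj, stim_start, late_t, frac) \
        if late_time <= t[-1] else "transient"
    return TrajectoryMetrics(
        baseline_value=float(traj.meta.get("baseline_value", v[i0])),
        peak_amplitude=amp, peak_time=float(t[m]),
        peak_duration=dur, duration_censored=censored,
        activity_at_40=float(late), erk_int=erk_integral(traj, stim_start, w0, w1),
        response_class=cls, pulse_maxima=maxima, decay_ratio=ratio)
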