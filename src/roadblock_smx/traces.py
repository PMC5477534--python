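"""Drift correction, smoothing, and pause timing for tether-extension traces.

A magnetic-tweezer transcription record is an extension-versus-time
series sampled uniformly (nominally 164 Hz).  Processing follows the
standard recipe: subtract mechanical drift measured on surface-stuck
reference beads (60-point moving average of their mean motion), abate
noise with a 200-point moving average, then time pauses with the
three-line construction — ordinary least-squares lines fitted to
(1) elongation before the pause, (2) the pause plateau, (3) elongation
after the pause; the pause duration is the distance between the
intersection abscissae of lines 1&2 and lines 2&3.

All moving averages are centered with symmetric shrink at the edges, so
a linear signal is reproduced exactly everywhere and intersection times
acquire no phase lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import FitError, ValidationError

__all__ = [
    "ExtensionTrace",
    "PauseEvent",
    "OutcomeLabel",
    "drift_correct",
    "smooth",
    "fit_three_lines",
    "detect_pauses",
    "classify_outcome",
    "pause_summary",
]


@dataclass
class ExtensionTrace:
    """Uniformly sampled extension-vs-time series for one bead.

    ``extension`` is in µm relative to the pre-NTP baseline, negative
    downward (tether shortening).  ``history`` records every processing
    step applied, including window sizes.
    """

    time: np.ndarray  # s
    extension: np.ndarray  # µm
    sample_rate: float  # Hz
    bead_id: str = ""
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.extension.shape:
            raise ValidationError("time and extension must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValidationError("trace needs at least 2 samples")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9))) + 1
            raise ValidationError(f"non-uniform sampling at index {bad}")

    def __len__(self) -> int:
        return self.time.size


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetric shrink at the edges.

    The effective window at index i is 2*min(window//2, i, n-1-i)+1
    samples, so the average of a linear signal is exact everywhere.
    """
    n = x.size
    h = window // 2
    i = np.arange(n)
    hw = np.minimum(h, np.minimum(i, n - 1 - i))
    cs = np.concatenate(([0.0], np.cumsum(x)))
    return (cs[i + hw + 1] - cs[i - hw]) / (2 * hw + 1)


def _check_aligned(a: ExtensionTrace, b: ExtensionTrace) -> None:
    if len(a) != len(b):
        raise ValidationError("traces have different lengths")
    if not np.allclose(a.time, b.time, rtol=1e-9, atol=1e-9):
        raise ValidationError("trace clocks are misaligned")


def drift_correct(
    trace: ExtensionTrace, stuck_beads: list[ExtensionTrace], window: int = 60
) -> ExtensionTrace:
    """Subtract the moving-averaged mean stuck-bead motion from ``trace``.

    ``window`` is the moving-average span in samples (default 60).  The
    stuck-bead traces must share the tether trace's clock.
    """
    if not stuck_beads:
        raise ValidationError("at least one stuck-bead trace is required")
    if window < 1:
        raise ValidationError("window must be >= 1")
    for sb in stuck_beads:
        _check_aligned(trace, sb)
    mean_stuck = np.mean([sb.extension for sb in stuck_beads], axis=0)
    drift = _centered_moving_average(mean_stuck, window)
    out = replace(
        trace,
        extension=trace.extension - drift,
        history=trace.history + [f"drift_correct(window={window}, n_stuck={len(stuck_beads)})"],
    )
    return out


def smooth(trace: ExtensionTrace, window: int = 200) -> ExtensionTrace:
    """Centered moving average of the trace (default 200 samples)."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    if window > len(trace):
        raise ValidationError(f"window {window} exceeds trace length {len(trace)}")
    return replace(
        trace,
        extension=_centered_moving_average(trace.extension, window),
        history=trace.history + [f"smooth(window={window})"],
    )


@dataclass
class PauseEvent:
    """One timed pause: the three fitted lines and their intersections."""

    t_start: float  # s, intersection of lines 1 & 2
    t_end: float  # s, intersection of lines 2 & 3
    duration: float  # s
    extension_at_pause: float  # µm, line 2 evaluated mid-pause
    line1: tuple[float, float]  # (slope µm/s, intercept µm)
    line2: tuple[float, float]
    line3: tuple[float, float]
    fit_windows: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    mark_um: float | None = None  # annotated expected extension mark, if any


@dataclass
class OutcomeLabel:
    outcome: str  # terminated | runoff | stalled | ambiguous
    final_extension: float  # µm


def _ols_line(t: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, x, 1)
    return float(slope), float(intercept)


def _intersection(l1: tuple[float, float], l2: tuple[float, float]) -> float:
    m1, b1 = l1
    m2, b2 = l2
    scale = max(abs(m1), abs(m2), 1e-12)
    if abs(m1 - m2) <= 1e-9 * scale:
        raise FitError(f"adjacent fitted lines are parallel (slopes {m1:g}, {m2:g})")
    return (b2 - b1) / (m1 - m2)


def fit_three_lines(
    trace: ExtensionTrace,
    sections: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    zero_slope_pause: bool = False,
) -> PauseEvent:
    """Time a pause from three user-chosen trace sections.

    ``sections`` are (t_lo, t_hi) windows, in order: pre-pause
    elongation, pause, post-pause elongation.  They must be disjoint and
    each contain at least 10 samples.  ``zero_slope_pause`` constrains
    line 2 to slope zero (the plateau mean) instead of fitting it.
    """
    if len(sections) != 3:
        raise ValidationError("exactly three sections are required")
    secs = [tuple(map(float, s)) for s in sections]
    for lo, hi in secs:
        if hi <= lo:
            raise ValidationError(f"empty section ({lo}, {hi})")
    for (l0, h0), (l1, h1) in zip(secs, secs[1:]):
        if l1 < h0:
            raise ValidationError("sections must be disjoint and time-ordered")
    lines = []
    for idx, (lo, hi) in enumerate(secs):
        sel = (trace.time >= lo) & (trace.time <= hi)
        if sel.sum() < 10:
            raise ValidationError(f"section {idx + 1} contains {int(sel.sum())} samples (< 10)")
        if idx == 1 and zero_slope_pause:
            lines.append((0.0, float(trace.extension[sel].mean())))
        else:
            lines.append(_ols_line(trace.time[sel], trace.extension[sel]))
    l1, l2, l3 = lines
    t_start = _intersection(l1, l2)
    t_end = _intersection(l2, l3)
    if t_end <= t_start:
        raise FitError(f"line intersections out of order (t_start={t_start:g}, t_end={t_end:g})")
    t_mid = 0.5 * (t_start + t_end)
    return PauseEvent(
        t_start=t_start,
        t_end=t_end,
        duration=t_end - t_start,
        extension_at_pause=l2[0] * t_mid + l2[1],
        line1=l1,
        line2=l2,
        line3=l3,
        fit_windows=tuple(secs),
    )


def _local_slope(t: np.ndarray, x: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window OLS slope via uniform filters (O(n))."""
    w = max(3, window | 1)  # odd
    mt = uniform_filter1d(t, w, mode="nearest")
    mx = uniform_filter1d(x, w, mode="nearest")
    mtx = uniform_filter1d(t * x, w, mode="nearest")
    mtt = uniform_filter1d(t * t, w, mode="nearest")
    var = mtt - mt * mt
    var = np.where(var <= 0, np.nan, var)
    return (mtx - mt * mx) / var


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_pauses(
    trace: ExtensionTrace,
    expected_marks: tuple[float, ...] = (),
    *,
    slope_window_s: float = 30.0,
    slope_frac: float = 0.2,
    min_dwell_s: float = 20.0,
    mark_tol_um: float = 0.03,
    line_window_s: float = 40.0,
    margin_s: float | None = None,
    zero_slope_pause: bool = False,
) -> list[PauseEvent]:
    """Find and time pause plateaus in a drift-corrected, smoothed trace.

    Candidate plateaus are stretches where the windowed local slope
    (``slope_window_s``) stays above ``slope_frac`` times the median
    elongation slope (which is negative) for at least ``min_dwell_s``.
    Each candidate is refined by :func:`fit_three_lines` with elongation
    windows of up to ``line_window_s`` on either side, offset from the
    plateau edges by ``margin_s`` (default: half the slope window plus
    2 s) to keep transition samples out of the line fits.  Events whose
    plateau extension lies within ``mark_tol_um`` of an entry of
    ``expected_marks`` are annotated with that mark.

    Detection depends only on slopes, so the output is invariant under a
    constant offset of the whole trace.  If no elongation is found the
    list is empty and a diagnostic warning is issued.
    """
    fs = trace.sample_rate
    w = int(round(slope_window_s * fs))
    slope = _local_slope(trace.time, trace.extension, w)
    s_min = np.nanmin(slope)
    if not np.isfinite(s_min) or s_min > -1e-4:
        warnings.warn("no elongation detected (median slope ~ 0); no pauses reported")
        return []
    elong = slope <= 0.5 * s_min
    med = float(np.median(slope[elong]))
    pause_mask = slope >= slope_frac * med
    e_idx = np.flatnonzero(elong)
    first_e, last_e = int(e_idx[0]), int(e_idx[-1])
    pause_mask[:first_e] = False
    pause_mask[last_e + 1 :] = False

    margin = int(round((margin_s if margin_s is not None else slope_window_s / 2 + 2.0) * fs))
    span = int(round(line_window_s * fs))
    min_dwell = int(round(min_dwell_s * fs))
    t = trace.time
    events: list[PauseEvent] = []
    runs = [(a, b) for a, b in _runs(pause_mask) if b - a >= min_dwell]
    prev_stop = first_e
    for i, (a, b) in enumerate(runs):
        m2 = min(margin, max(0, (b - a - 12) // 2))
        lo1 = max(prev_stop, a - margin - span)
        hi1 = a - margin
        lo3 = b + margin
        hi3 = min((runs[i + 1][0] - margin) if i + 1 < len(runs) else last_e, b + margin + span)
        prev_stop = b
        if hi1 - lo1 < 10 or hi3 - lo3 < 10:
            continue  # no clean elongation on both sides; not a timeable pause
        sections = ((t[lo1], t[hi1]), (t[a + m2], t[b - 1 - m2]), (t[lo3], t[hi3]))
        try:
            ev = fit_three_lines(trace, sections, zero_slope_pause=zero_slope_pause)
        except (FitError, ValidationError):
            continue
        for mark in expected_marks:
            if abs(ev.extension_at_pause - mark) <= mark_tol_um:
                ev.mark_um = float(mark)
                break
        events.append(ev)
    return events


def classify_outcome(
    trace: ExtensionTrace,
    terminator_mark: float = -0.35,
    runoff_mark: float = -0.5,
    tolerance: float = 0.03,
    plateau_s: float = 30.0,
    slope_tol_um_s: float = 1e-3,
) -> OutcomeLabel:
    """Label the end state of a trace from its final plateau.

    The mean extension of the last ``plateau_s`` seconds is compared
    with the terminator and runoff marks (µm, negative downward).  If
    the final stretch is still sloping (|slope| > ``slope_tol_um_s``)
    the trace is ``ambiguous``; a stable plateau away from both marks is
    ``stalled``.
    """
    n = int(round(plateau_s * trace.sample_rate))
    if n < 10 or n > len(trace):
        raise ValidationError("trace shorter than the plateau window")
    t, x = trace.time[-n:], trace.extension[-n:]
    slope, _ = _ols_line(t, x)
    final = float(x.mean())
    if abs(slope) > slope_tol_um_s:
        return OutcomeLabel("ambiguous", final)
    if final <= runoff_mark + tolerance:
        return OutcomeLabel("runoff", final)
    if abs(final - terminator_mark) <= tolerance:
        return OutcomeLabel("terminated", final)
    return OutcomeLabel("stalled", final)


def pause_summary(events: list[PauseEvent] | list[float]) -> tuple[float, float, int]:
    """Mean pause duration, standard error (sd/sqrt(n)), and n.

    Accepts PauseEvents or raw durations.  A single event yields se = 0
    (there is no spread to estimate)."""
    if not events:
        raise ValidationError("no pause events to summarize")
    durations = np.array(
        [e.duration if isinstance(e, PauseEvent) else float(e) for e in events], dtype=float
    )
    n = durations.size
    mean = float(durations.mean())
    se = float(durations.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    if n == 1:
        warnings.warn("single pause event: standard error reported as 0")
    return mean, se, n
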