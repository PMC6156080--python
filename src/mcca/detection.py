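"""Calcium-transient detection on ROI-averaged fluorescence traces.

The processing chain mirrors the standard in-vivo two-photon workflow:

1. normalise each raw trace to dF/F (%) against a quiet global baseline,
2. binomial (1,2,1)/4 smoothing, iterated, with reflecting boundaries,
3. high-pass drift removal (zero-phase running-median baseline subtraction),
4. peak candidates where the first derivative crosses zero from positive
   to negative with negative curvature,
5. amplitude gate: peak must exceed the local baseline mean by
   ``amplitude_sd_multiple`` (default 3) baseline-noise SDs; the baseline
   is the median of the nearest activity-free ``baseline_window_s``
   (default 10 s) span preceding the peak,
6. event refinement: foot and tail are the first samples on either side
   of the peak that fall within ``edge_sd_multiple`` (default 0.5) SD of
   the baseline; the area under the curve is the trapezoidal integral of
   (dF/F - baseline) between them.

Detection runs in two passes: a provisional pass with global trace
statistics marks active spans, and the definitive pass re-evaluates every
candidate against local, activity-free baseline statistics.  The
baseline-noise SD is estimated from the unsmoothed dF/F trace with the
first-difference estimator ``std(diff(x))/sqrt(2)``, which is insensitive
to slow drift and to the variance reduction introduced by smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("mcca.detection")

#: activity-class boundaries in transients/min; values on a boundary are "medium"
LOW_MEDIUM_BOUNDARY = 0.3
MEDIUM_HYPER_BOUNDARY = 3.0

ACTIVITY_CLASSES = ("silent", "low", "medium", "hyper")

#: shortest activity-free span trusted for local baseline statistics; anything
#: shorter falls back to whole-trace statistics
MIN_BASELINE_FRAMES = 5
CELL_KINDS = ("neuron", "astrocyte")


class DetectionError(ValueError):
    """Raised for invalid detection inputs or parameters."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable constants of the transient-detection chain.

    amplitude_sd_multiple
        peak acceptance threshold in baseline-noise SDs above the local mean.
    edge_sd_multiple
        foot/tail threshold in baseline-noise SDs around the local baseline.
    baseline_window_s
        length of the activity-free span preceding each peak over which the
        local baseline median/mean/SD are taken.
    smooth_iterations
        iterations of the (1,2,1)/4 binomial smoother (20-40 is customary).
    highpass_cutoff_hz
        drift-removal corner frequency; transients with seconds-scale decay
        sit well above the 0.02 Hz default.
    min_event_sep_s
        optional minimum separation between accepted peaks (0 disables).
    peak_merge_fraction
        adjacent accepted peaks are treated as one transient when the valley
        between them stays above this fraction of the smaller peak's height
        over baseline (slow transients carry noise wiggles on their decay
        that satisfy the peak criteria but are not separate events).
    astrocyte_duration_s
        cells whose median event duration (tail - foot) exceeds this are
        classified as astrocyte-like and excluded from network metrics.
    """

    amplitude_sd_multiple: float = 3.0
    edge_sd_multiple: float = 0.5
    baseline_window_s: float = 10.0
    smooth_iterations: int = 30
    highpass_cutoff_hz: float = 0.02
    min_event_sep_s: float = 0.0
    peak_merge_fraction: float = 0.8
    astrocyte_duration_s: float = 4.0
    global_baseline_span_s: float = 2.0
    global_baseline_search_s: float = 30.0

    def __post_init__(self) -> None:
        if self.amplitude_sd_multiple <= 0 or self.edge_sd_multiple <= 0:
            raise DetectionError("SD multiples must be positive")
        if self.baseline_window_s <= 0:
            raise DetectionError("baseline_window_s must be positive")
        if self.smooth_iterations < 0 or self.smooth_iterations != int(self.smooth_iterations):
            raise DetectionError("smooth_iterations must be a non-negative integer")
        if self.highpass_cutoff_hz <= 0:
            raise DetectionError("highpass_cutoff_hz must be positive")
        if self.min_event_sep_s < 0:
            raise DetectionError("min_event_sep_s must be non-negative")
        if not 0 <= self.peak_merge_fraction <= 1:
            raise DetectionError("peak_merge_fraction must lie in [0, 1]")


@dataclass
class TransientEvent:
    """One detected calcium transient."""

    peak_idx: int
    foot_idx: int
    tail_idx: int
    peak_time_s: float
    foot_time_s: float
    tail_time_s: float
    amplitude_dff_pct: float
    auc_dff_s: float
    baseline_dff_pct: float
    edge_clamped: bool = False

    def __post_init__(self) -> None:
        if not (self.foot_idx <= self.peak_idx <= self.tail_idx):
            raise DetectionError(
                f"event indices out of order: foot {self.foot_idx}, "
                f"peak {self.peak_idx}, tail {self.tail_idx}"
            )

    @property
    def duration_s(self) -> float:
        return self.tail_time_s - self.foot_time_s


@dataclass
class CellActivity:
    """Per-cell detection result."""

    cell_id: str
    events: list[TransientEvent]
    frequency_trans_per_min: float
    kind: str
    activity_class: str

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def mean_auc(self) -> float:
        if not self.events:
            return float("nan")
        return float(np.mean([e.auc_dff_s for e in self.events]))


# ---------------------------------------------------------------------------
# dF/F and preprocessing
# ---------------------------------------------------------------------------

def find_global_baseline_window(
    trace: np.ndarray, sampling_rate_hz: float,
    span_s: float = 2.0, search_s: float = 30.0,
) -> tuple[int, int]:
    """Locate the quietest ``span_s`` window in the first ``search_s`` seconds.

    The window with minimal variance stands in for the interactively chosen
    "silent period" that anchors the dF/F normalisation.  Returns half-open
    frame indices ``(start, stop)``.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    w = max(1, int(round(span_s * sampling_rate_hz)))
    limit = min(n, max(w, int(round(search_s * sampling_rate_hz))))
    if w >= limit:
        return 0, limit
    x = trace[:limit]
    c1 = np.cumsum(np.concatenate(([0.0], x)))
    c2 = np.cumsum(np.concatenate(([0.0], x * x)))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = s2 / w - (s1 / w) ** 2
    start = int(np.argmin(var))
    return start, start + w


def compute_dff(trace: np.ndarray, baseline_window: tuple[int, int]) -> np.ndarray:
    """Normalise a raw fluorescence trace to dF/F in percent.

    ``dff[t] = (trace[t] / mean(trace[window]) - 1) * 100`` where the window
    is a quiet stretch of the same trace (half-open frame indices).
    """
    trace = np.asarray(trace, dtype=float)
    start, stop = baseline_window
    if stop - start < 1:
        raise DetectionError("baseline window must span at least one frame")
    f0 = float(np.mean(trace[start:stop]))
    if not np.isfinite(f0) or f0 <= 0:
        raise DetectionError(f"baseline mean must be positive, got {f0!r}")
    return (trace / f0 - 1.0) * 100.0


def smooth_binomial(x: np.ndarray, iterations: int) -> np.ndarray:
    """Iterated (1,2,1)/4 binomial smoothing with reflecting boundaries.

    ``iterations`` passes approximate a Gaussian filter of SD sqrt(n/2)
    samples.  Works on 1-D traces or on a (frames x cells) matrix along
    axis 0.  ``iterations=0`` is the identity.
    """
    if iterations < 0:
        raise DetectionError("iterations must be non-negative")
    y = np.asarray(x, dtype=float).copy()
    if y.shape[0] < 2:
        return y
    for _ in range(int(iterations)):
        lo = np.concatenate((y[1:2], y[:-1]), axis=0)   # reflect at start
        hi = np.concatenate((y[1:], y[-2:-1]), axis=0)  # reflect at end
        y = 0.25 * lo + 0.5 * y + 0.25 * hi
    return y


def highpass(
    x: np.ndarray, cutoff_hz: float, sampling_rate_hz: float,
) -> np.ndarray:
    """Drift removal by zero-phase running-median baseline subtraction.

    The baseline is the median over a centred sliding window of half the
    cutoff period (``1 / (2 * cutoff_hz)`` seconds).  Content slower than
    the cutoff is tracked by the median and removed — a constant offset is
    rejected exactly, and a 120-s-period drift is attenuated by ~95% at the
    0.02 Hz default — while sparse seconds-scale transients occupy too
    little of the window to move a median and pass essentially unchanged
    (amplitude and foot-to-tail area preserved to ~1%).  A linear filter
    cannot do both: it necessarily redistributes part of each transient's
    area into an undershoot.  Works on 1-D traces or (frames x cells)
    matrices along axis 0.
    """
    if not 0 < cutoff_hz < sampling_rate_hz / 2:
        raise DetectionError(
            f"cutoff must lie in (0, Nyquist); got {cutoff_hz} at fs={sampling_rate_hz}"
        )
    x = np.asarray(x, dtype=float)
    w = int(round(sampling_rate_hz / (2.0 * cutoff_hz)))
    w = max(3, w | 1)  # odd, centred
    baseline = (
        pd.DataFrame(x.reshape(x.shape[0], -1))
        .rolling(w, center=True, min_periods=1)
        .median()
        .to_numpy()
        .reshape(x.shape)
    )
    return x - baseline


def noise_sd(x: np.ndarray) -> float:
    """Noise SD via the first-difference estimator std(diff(x))/sqrt(2)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.std(np.diff(x)) / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# local baselines
# ---------------------------------------------------------------------------

@dataclass
class LocalBaseline:
    baseline: float   # median of the window
    mean: float
    sd: float
    window: tuple[int, int]  # inclusive frame indices (start, end)


def _window_before(
    active: np.ndarray, idx: int, width: int,
) -> tuple[int, int] | None:
    """Nearest activity-free window of ``width`` frames ending before ``idx``.

    Falls back to the longest clean run before ``idx`` (if shorter than
    ``width``), then to the longest clean run anywhere.  Returns inclusive
    (start, end) or None when no clean run of >= 2 frames exists.
    """
    clean = ~np.asarray(active, dtype=bool)
    n = clean.size

    def runs_before(stop: int) -> tuple[int, int] | None:
        # longest clean run ending at index < stop; prefer the nearest on ties
        best = None
        run = 0
        for i in range(stop):
            run = run + 1 if clean[i] else 0
            if run >= MIN_BASELINE_FRAMES and (
                best is None or run >= best[1] - best[0] + 1
            ):
                best = (i - run + 1, i)
        return best

    # full-width window, nearest first
    run = 0
    latest = None
    for i in range(min(idx, n)):
        run = run + 1 if clean[i] else 0
        if run >= width:
            latest = (i - width + 1, i)
    if latest is not None:
        return latest
    best = runs_before(min(idx, n))
    if best is not None:
        return best
    return runs_before(n)


def estimate_local_baseline(
    dff: np.ndarray,
    peak_idx: int,
    window_s: float,
    sampling_rate_hz: float,
    active_mask: np.ndarray | None = None,
    noise_trace: np.ndarray | None = None,
) -> LocalBaseline:
    """Baseline statistics from the activity-free span preceding a peak.

    The baseline is the median over the nearest preceding ``window_s`` span
    containing no frames of previously detected events (``active_mask``);
    the mean is taken over the same span, and the SD is the first-difference
    noise estimate of ``noise_trace`` (default: ``dff`` itself) there.  When
    no clean full-width span precedes the peak, the longest available clean
    span is used; with no clean frames at all, whole-trace statistics.
    """
    dff = np.asarray(dff, dtype=float)
    noise = dff if noise_trace is None else np.asarray(noise_trace, dtype=float)
    n = dff.size
    if active_mask is None:
        active_mask = np.zeros(n, dtype=bool)
    width = max(2, int(round(window_s * sampling_rate_hz)))
    win = _window_before(active_mask, peak_idx, width)
    if win is None:
        seg = slice(0, n)
        win = (0, n - 1)
    else:
        seg = slice(win[0], win[1] + 1)
    return LocalBaseline(
        baseline=float(np.median(dff[seg])),
        mean=float(np.mean(dff[seg])),
        sd=noise_sd(noise[seg]),
        window=win,
    )


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _candidate_peaks(y: np.ndarray) -> np.ndarray:
    """Indices where the first difference crosses zero from + to - with
    negative second difference (interior samples only)."""
    d = np.diff(y)
    i = np.arange(1, y.size - 1)
    rising = d[:-1] > 0
    falling = d[1:] <= 0
    curvature = (y[2:] - 2 * y[1:-1] + y[:-2]) < 0
    return i[rising & falling & curvature]


def _walk_span(
    y: np.ndarray, peak: int, baseline: float, edge: float,
    lo: int = 0, hi: int | None = None,
) -> tuple[int, int, bool]:
    """Foot/tail of the event at ``peak``: first samples on either side whose
    deviation from ``baseline`` is within ``edge``.  The walk is clamped (and
    flagged) at the trace ends; ``lo``/``hi`` bound the search, e.g. at the
    peaks of adjacent events so overlapping transients keep distinct spans."""
    n = y.size
    if hi is None:
        hi = n - 1
    clamped = False
    foot = peak
    while foot > lo:
        foot -= 1
        if abs(y[foot] - baseline) <= edge:
            break
    if foot == 0 and abs(y[0] - baseline) > edge:
        clamped = True
    tail = peak
    while tail < hi:
        tail += 1
        if abs(y[tail] - baseline) <= edge:
            break
    if tail == n - 1 and abs(y[n - 1] - baseline) > edge:
        clamped = True
    return foot, tail, clamped


def detect_peaks(
    dff_processed: np.ndarray,
    params: DetectionParams,
    sampling_rate_hz: float,
    noise_trace: np.ndarray | None = None,
    return_details: bool = False,
):
    """Detect transient peaks on a preprocessed dF/F trace.

    Two passes: (1) candidates exceeding ``amplitude_sd_multiple`` noise SDs
    above the global mean mark provisional active spans via their 0.5-SD
    feet/tails; (2) every derivative/curvature candidate is re-tested against
    the mean of its local activity-free baseline window plus the same
    multiple of the local noise SD.  Returns the accepted peak indices
    (sorted); with ``return_details`` also a dict peak -> LocalBaseline.
    """
    y = np.asarray(dff_processed, dtype=float)
    if y.size < 5:
        raise DetectionError("trace must have at least 5 frames")
    noise = y if noise_trace is None else np.asarray(noise_trace, dtype=float)
    if noise.shape != y.shape:
        raise DetectionError("noise_trace must match the trace shape")
    k = params.amplitude_sd_multiple
    cand = _candidate_peaks(y)

    # pass 1: provisional peaks against global statistics
    sd_g = noise_sd(noise)
    mean_g = float(np.mean(y))
    med_g = float(np.median(y))
    provisional = cand[y[cand] > mean_g + k * sd_g]
    active = np.zeros(y.size, dtype=bool)
    for p in provisional:
        f, t, _ = _walk_span(y, int(p), med_g, params.edge_sd_multiple * sd_g)
        active[f : t + 1] = True

    # pass 2: local activity-free baselines (vectorised window lookup)
    width = max(2, int(round(params.baseline_window_s * sampling_rate_hz)))
    windows = _preceding_windows(active, cand, width)
    cy = np.cumsum(np.concatenate(([0.0], y)))
    d = np.diff(noise)
    cd1 = np.cumsum(np.concatenate(([0.0], d)))
    cd2 = np.cumsum(np.concatenate(([0.0], d * d)))

    accepted: list[int] = []
    details: dict[int, LocalBaseline] = {}
    for c, win in zip(cand, windows):
        if win is None:
            seg_mean = mean_g
            seg_sd = sd_g
            lb_win = (0, y.size - 1)
        else:
            f, e = win
            m = e - f + 1
            seg_mean = (cy[e + 1] - cy[f]) / m
            nd = e - f  # diffs inside [f, e]; window length >= MIN_BASELINE_FRAMES
            s1 = cd1[e] - cd1[f]
            s2 = cd2[e] - cd2[f]
            var = max(s2 / nd - (s1 / nd) ** 2, 0.0)
            seg_sd = float(np.sqrt(var / 2.0))
            lb_win = (f, e)
        if y[c] > seg_mean + k * seg_sd:
            ci = int(c)
            accepted.append(ci)
            if return_details:
                f, e = lb_win
                details[ci] = LocalBaseline(
                    baseline=float(np.median(y[f : e + 1])),
                    mean=float(seg_mean),
                    sd=float(seg_sd),
                    window=lb_win,
                )
    peaks = np.asarray(accepted, dtype=int)
    if return_details:
        return peaks, details
    return peaks


def _preceding_windows(
    active: np.ndarray, candidates: np.ndarray, width: int,
) -> list[tuple[int, int] | None]:
    """For each candidate, the nearest preceding clean window of ``width``
    frames, else the longest clean run before it, else the longest clean run
    anywhere (each at least MIN_BASELINE_FRAMES long), else None.  Matches
    :func:`_window_before`."""
    clean = ~np.asarray(active, dtype=bool)
    n = clean.size
    run = np.zeros(n, dtype=np.int64)
    acc = 0
    for i in range(n):
        acc = acc + 1 if clean[i] else 0
        run[i] = acc
    idx = np.arange(n, dtype=np.int64)
    full_end = np.where(run >= width, idx, -1)
    latest_full = np.maximum.accumulate(full_end)
    # longest run ending at or before i; nearest wins ties (larger index)
    key = np.where(run >= MIN_BASELINE_FRAMES, run * n + idx, -1)
    best_key = np.maximum.accumulate(key)

    global_best: tuple[int, int] | None = None
    if best_key[-1] >= 0:
        e = int(best_key[-1] % n)
        L = int(best_key[-1] // n)
        global_best = (e - L + 1, e)

    out: list[tuple[int, int] | None] = []
    for c in candidates:
        j = int(c) - 1
        if j < 0:
            out.append(global_best)
            continue
        if latest_full[j] >= 0:
            e = int(latest_full[j])
            out.append((e - width + 1, e))
        elif best_key[j] >= 0:
            e = int(best_key[j] % n)
            L = int(best_key[j] // n)
            out.append((e - L + 1, e))
        else:
            out.append(global_best)
    return out


# ---------------------------------------------------------------------------
# event refinement and per-cell summaries
# ---------------------------------------------------------------------------

def _hill_climb(y: np.ndarray, i: int) -> int:
    """Nearest local maximum of ``y`` from ``i`` by greedy ascent."""
    n = y.size
    while i + 1 < n and y[i + 1] > y[i]:
        i += 1
    while i - 1 >= 0 and y[i - 1] > y[i]:
        i -= 1
    return i


def refine_event(
    dff: np.ndarray,
    peak_idx: int,
    baseline: float,
    sd: float,
    params: DetectionParams,
    sampling_rate_hz: float,
    foot_limit: int = 0,
    tail_limit: int | None = None,
) -> TransientEvent:
    """Delimit one transient and integrate its area.

    The peak is first snapped to the nearest local maximum of ``dff`` by
    greedy hill-climbing (replacing interactive peak correction; a global
    arg-max over the event span could jump to an overlapping neighbouring
    transient).  The foot (tail) is then the first sample before (after)
    the peak within ``edge_sd_multiple * sd`` of the baseline; when the
    trace edge is hit first the event is clamped and flagged.  The AUC is
    the trapezoidal integral of (dF/F - baseline) over [foot, tail], in
    (dF/F %)*s.
    """
    y = np.asarray(dff, dtype=float)
    edge = params.edge_sd_multiple * sd
    peak = _hill_climb(y, int(peak_idx))
    foot, tail, clamped = _walk_span(y, peak, baseline, edge, lo=foot_limit,
                                     hi=tail_limit)
    seg = y[foot : tail + 1] - baseline
    auc = float(np.trapezoid(seg)) / sampling_rate_hz
    fs = sampling_rate_hz
    return TransientEvent(
        peak_idx=peak,
        foot_idx=foot,
        tail_idx=tail,
        peak_time_s=peak / fs,
        foot_time_s=foot / fs,
        tail_time_s=tail / fs,
        amplitude_dff_pct=float(y[peak] - baseline),
        auc_dff_s=max(auc, 0.0),
        baseline_dff_pct=float(baseline),
        edge_clamped=clamped,
    )


def compute_frequency(events: Sequence, duration_s: float) -> float:
    """Transient frequency in transients/min: 60 * count / duration."""
    if duration_s <= 0:
        raise DetectionError("duration must be positive")
    return 60.0 * len(events) / duration_s


def classify_activity(frequency: float, has_events: bool) -> str:
    """Assign the functional subgroup from the transient frequency.

    Cells without events are silent; active cells are 'low' below
    0.3 trans/min, 'medium' in [0.3, 3] inclusive, 'hyper' above 3.
    """
    if frequency < 0:
        raise DetectionError("frequency must be non-negative")
    if not has_events:
        return "silent"
    if frequency < LOW_MEDIUM_BOUNDARY:
        return "low"
    if frequency <= MEDIUM_HYPER_BOUNDARY:
        return "medium"
    return "hyper"


def classify_cell_kind(
    events: Sequence[TransientEvent],
    dff: np.ndarray | None = None,
    duration_threshold_s: float = 4.0,
) -> str:
    """Separate astrocyte-like slow-kinetics cells from neurons.

    A cell is astrocyte-like iff the median event duration (tail - foot)
    exceeds ``duration_threshold_s``; cells without events default to neuron.
    """
    if not events:
        return "neuron"
    med = float(np.median([e.duration_s for e in events]))
    return "astrocyte" if med > duration_threshold_s else "neuron"


def analyze_trace(
    raw_trace: np.ndarray,
    sampling_rate_hz: float,
    params: DetectionParams | None = None,
    baseline_window: tuple[int, int] | None = None,
) -> tuple[list[TransientEvent], np.ndarray]:
    """Full single-trace chain: dF/F, smoothing, high-pass, detection,
    refinement.  Returns the event list and the smoothed dF/F trace.

    Peak acceptance runs on the smoothed *and* high-pass-filtered trace;
    baselines, amplitudes and AUCs are then measured on the smoothed dF/F
    (without the high-pass), whose slow components the local median baseline
    already absorbs.
    """
    params = params or DetectionParams()
    fs = sampling_rate_hz
    if baseline_window is None:
        baseline_window = find_global_baseline_window(
            raw_trace, fs, params.global_baseline_span_s, params.global_baseline_search_s
        )
    dff = compute_dff(raw_trace, baseline_window)
    dff_s = smooth_binomial(dff, params.smooth_iterations)
    dff_p = highpass(dff_s, params.highpass_cutoff_hz, fs)
    peaks, details = detect_peaks(dff_p, params, fs, noise_trace=dff, return_details=True)

    peaks = _merge_shoulder_peaks(dff_s, sorted(peaks), details, params)
    events: list[TransientEvent] = []
    for k, p in enumerate(peaks):
        lb = details[p]
        f, e = lb.window
        baseline = float(np.median(dff_s[f : e + 1]))
        lo = int(peaks[k - 1]) if k > 0 else 0
        hi = int(peaks[k + 1]) if k + 1 < len(peaks) else None
        ev = refine_event(dff_s, p, baseline, lb.sd, params, fs,
                          foot_limit=lo, tail_limit=hi)
        events.append(ev)

    events = _dedupe_events(events)
    if params.min_event_sep_s > 0:
        events = _enforce_min_sep(events, params.min_event_sep_s)
    return events, dff_s


def _merge_shoulder_peaks(
    y: np.ndarray,
    peaks: list[int],
    details: dict[int, LocalBaseline],
    params: DetectionParams,
) -> list[int]:
    """Collapse runs of peaks that belong to one transient.

    Two adjacent accepted peaks are merged (keeping the taller) when the
    minimum of the smoothed trace between them stays above
    ``peak_merge_fraction`` of the smaller peak's height over its baseline:
    a genuine pair of closely spaced transients dips well below that, while
    decay-riding noise shoulders do not.
    """
    if len(peaks) < 2:
        return list(peaks)
    merged = [int(peaks[0])]
    for p in peaks[1:]:
        p = int(p)
        q = merged[-1]
        base = details[p].baseline
        valley = float(np.min(y[q : p + 1])) - base
        smaller = min(y[q], y[p]) - base
        if smaller > 0 and valley > params.peak_merge_fraction * smaller:
            if y[p] > y[q]:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


def _dedupe_events(events: list[TransientEvent]) -> list[TransientEvent]:
    """Drop duplicate events that collapsed onto the same corrected peak.

    Overlapping spans of *distinct* peaks are kept: closely spaced
    transients ride on each other's decay and legitimately share frames.
    """
    if not events:
        return events
    events = sorted(events, key=lambda e: e.peak_idx)
    kept: list[TransientEvent] = []
    for ev in events:
        if kept and ev.peak_idx == kept[-1].peak_idx:
            continue
        kept.append(ev)
    return kept


def _enforce_min_sep(events: list[TransientEvent], min_sep_s: float) -> list[TransientEvent]:
    kept: list[TransientEvent] = []
    for ev in sorted(events, key=lambda e: e.peak_time_s):
        if kept and ev.peak_time_s - kept[-1].peak_time_s < min_sep_s:
            if ev.amplitude_dff_pct > kept[-1].amplitude_dff_pct:
                kept[-1] = ev
        else:
            kept.append(ev)
    return kept


def analyze_recording(recording, params: DetectionParams | None = None) -> list[CellActivity]:
    """Run the detection chain on every cell of a Recording."""
    params = params or DetectionParams()
    fs = recording.sampling_rate_hz
    duration = recording.duration_s
    cells: list[CellActivity] = []
    for c, cell_id in enumerate(recording.cell_ids):
        events, _ = analyze_trace(recording.traces[:, c], fs, params)
        freq = compute_frequency(events, duration)
        kind = classify_cell_kind(events, duration_threshold_s=params.astrocyte_duration_s)
        cells.append(
            CellActivity(
                cell_id=cell_id,
                events=events,
                frequency_trans_per_min=freq,
                kind=kind,
                activity_class=classify_activity(freq, bool(events)),
            )
        )
    n_astro = sum(1 for c in cells if c.kind == "astrocyte")
    if n_astro:
        log.info("classified %d/%d cells as astrocyte-like", n_astro, len(cells))
    return cells
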