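"""Synchronisation, resampling and statistical comparison of surrogate traces.

The analysis chain mirrors the workflow used when two external respiratory
surrogates (an infrared marker block and a pneumatic bellows belt) record the
same breathing simultaneously during a 4D CT acquisition:

1. crop each channel to the X-RAY ON window and set its start as time zero
   (:func:`crop_to_beam_on`);
2. downsample the faster channel onto the slower channel's timestamps
   (:func:`resample_to`);
3. detect end-inhale peaks with a prominence/separation search, replacing
   flat (truncated or plateau) tops by the plateau's temporal midpoint
   (:func:`detect_end_inhale_peaks`);
4. normalise each channel to its maximum detected peak
   (:func:`normalize_to_max_peak`);
5. pair peaks across channels and summarise the signed time differences
   (latency) between them (:func:`pair_peaks`, :func:`latency_summary`);
6. compute per-trace amplitude statistics (mean, SD, %CV, breathing rate)
   and cross-channel agreement (Pearson r, Mann-Whitney U).

Sign convention: latency is positive when the marker-block (rpm) end-inhale
peak occurs *before* the bellows end-inhale peak, i.e. positive means the
rpm channel leads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .waveform_io import SurrogateTrace

__all__ = [
    "PeakSearchConfig",
    "PeakList",
    "LatencySummary",
    "TraceStats",
    "SynchronizationError",
    "ExtrapolationError",
    "NormalizationError",
    "InsufficientDataError",
    "crop_to_beam_on",
    "resample_to",
    "detect_end_inhale_peaks",
    "normalize_to_max_peak",
    "pair_peaks",
    "latency_summary",
    "trace_stats",
    "pearson_r",
    "mann_whitney_u",
]


class SynchronizationError(ValueError):
    """No beam-on samples: the trace cannot be synchronised to X-RAY ON."""


class ExtrapolationError(ValueError):
    """Requested resampling times fall outside the trace's span."""


class NormalizationError(ValueError):
    """Normalisation is undefined (no peaks, or zero peak amplitude)."""


class InsufficientDataError(ValueError):
    """Not enough samples/pairs for the requested statistic."""


@dataclass(frozen=True)
class PeakSearchConfig:
    """Parameters of the end-inhale peak search.

    min_prominence_frac
        Minimum peak prominence as a fraction of the trace's amplitude
        range.  0.10 rejects noise ripples while keeping shallow breaths.
    min_separation_s
        Minimum time between successive peaks.  1.5 s admits breathing up
        to 40 breaths/min, comfortably above the 7-22 BPM range the
        generator emulates.
    plateau_tolerance_frac
        Samples within this fraction of the amplitude range below a peak
        belong to its plateau run.
    plateau_min_duration_s
        A plateau run longer than this is reported as a single peak at the
        run's temporal midpoint (the truncated-top rule).
    """

    min_prominence_frac: float = 0.10
    min_separation_s: float = 1.5
    plateau_tolerance_frac: float = 0.02
    plateau_min_duration_s: float = 0.3


@dataclass
class PeakList:
    """Detected end-inhale peaks on a trace's (cropped) time axis."""

    peak_times: np.ndarray
    peak_kinds: List[str]  # "sharp" or "plateau_midpoint"
    search_config: PeakSearchConfig = field(default_factory=PeakSearchConfig)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if len(self.peak_times) != len(self.peak_kinds):
            raise ValueError("peak_times and peak_kinds must have equal length")
        if len(self.peak_times) > 1 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class LatencySummary:
    """Signed end-inhale time differences between two channels, in ms.

    Positive deltas mean the first (rpm) channel's peak occurred earlier.
    """

    pair_deltas_ms: np.ndarray
    mean_ms: float
    sd_ms: float
    min_ms: float
    max_ms: float
    hist_edges_ms: np.ndarray
    hist_counts: np.ndarray
    n_unmatched_a: int = 0
    n_unmatched_b: int = 0


@dataclass
class TraceStats:
    """Amplitude and rate statistics over the beam-on portion of a trace."""

    mean_amp: float
    sd_amp: float
    cv_percent: float
    bpm: float
    duration_s: float


def crop_to_beam_on(trace: SurrogateTrace) -> SurrogateTrace:
    """Restrict a trace to its first contiguous X-RAY ON interval.

    The first retained sample becomes time zero, giving both surrogate
    channels a mutual origin at the start of acquisition.
    """
    on = np.flatnonzero(trace.beam_on)
    if on.size == 0:
        raise SynchronizationError("trace has no beam-on samples")
    start = on[0]
    # end of the first contiguous run of beam-on samples
    run_breaks = np.flatnonzero(np.diff(on) > 1)
    stop = on[run_breaks[0]] if run_breaks.size else on[-1]
    sl = slice(start, stop + 1)
    return trace.copy_with(
        times=trace.times[sl] - trace.times[start],
        amplitudes=trace.amplitudes[sl].copy(),
        beam_on=trace.beam_on[sl].copy(),
        phase=None if trace.phase is None else trace.phase[sl].copy(),
    )


def resample_to(trace: SurrogateTrace, reference_times: Sequence[float]) -> SurrogateTrace:
    """Linearly interpolate a trace's amplitudes at *reference_times*.

    Used to downsample the ~38 Hz bellows channel onto the 30 Hz rpm
    timestamps.  The beam-on flag is taken from the nearest original
    sample.  Times outside the trace's span raise :class:`ExtrapolationError`.
    """
    ref = np.asarray(reference_times, dtype=float)
    if ref.size and (ref.min() < trace.times[0] - 1e-12 or ref.max() > trace.times[-1] + 1e-12):
        raise ExtrapolationError(
            f"reference times [{ref.min():.6g}, {ref.max():.6g}] exceed trace span "
            f"[{trace.times[0]:.6g}, {trace.times[-1]:.6g}]"
        )
    amps = np.interp(ref, trace.times, trace.amplitudes)
    # nearest-sample beam_on
    idx = np.searchsorted(trace.times, ref)
    idx = np.clip(idx, 1, len(trace.times) - 1)
    left_closer = (ref - trace.times[idx - 1]) <= (trace.times[idx] - ref)
    nearest = np.where(left_closer, idx - 1, idx)
    rate = (ref.size - 1) / (ref[-1] - ref[0]) if ref.size > 1 else trace.nominal_rate
    return trace.copy_with(
        times=ref,
        amplitudes=amps,
        beam_on=trace.beam_on[nearest].copy(),
        phase=None,
        nominal_rate=float(rate),
    )


def detect_end_inhale_peaks(
    trace: SurrogateTrace, cfg: PeakSearchConfig | None = None
) -> PeakList:
    """Find end-inhale peaks by prominence/separation search.

    Local maxima must clear ``min_prominence_frac`` of the amplitude range
    and be at least ``min_separation_s`` apart.  Around each maximum, the
    maximal run of consecutive samples within ``plateau_tolerance_frac`` of
    the peak value is inspected: if it lasts longer than
    ``plateau_min_duration_s`` the peak is reported at the run's temporal
    midpoint (kind ``plateau_midpoint``), otherwise at the sample itself
    (kind ``sharp``).  A monotone trace yields an empty list.
    """
    cfg = cfg or PeakSearchConfig()
    a = trace.amplitudes
    t = trace.times
    amp_range = float(a.max() - a.min())
    if amp_range == 0.0 or len(a) < 3:
        return PeakList(np.empty(0), [], cfg)
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(cfg.min_separation_s / dt)))
    idx, _props = _signal.find_peaks(
        a,
        prominence=cfg.min_prominence_frac * amp_range,
        distance=distance,
    )
    tol = cfg.plateau_tolerance_frac * amp_range
    times: List[float] = []
    kinds: List[str] = []
    for i in idx:
        thr = a[i] - tol
        lo = i
        while lo > 0 and a[lo - 1] >= thr:
            lo -= 1
        hi = i
        while hi < len(a) - 1 and a[hi + 1] >= thr:
            hi += 1
        if t[hi] - t[lo] > cfg.plateau_min_duration_s:
            times.append(0.5 * (t[lo] + t[hi]))
            kinds.append("plateau_midpoint")
        else:
            times.append(float(t[i]))
            kinds.append("sharp")
    # plateau midpoints of adjacent find_peaks hits can coincide; dedupe
    out_t: List[float] = []
    out_k: List[str] = []
    for tt, kk in zip(times, kinds):
        if out_t and tt <= out_t[-1] + 1e-9:
            continue
        out_t.append(tt)
        out_k.append(kk)
    return PeakList(np.array(out_t), out_k, cfg)


def normalize_to_max_peak(trace: SurrogateTrace, peaks: PeakList) -> SurrogateTrace:
    """Divide amplitudes by the largest amplitude attained at a detected peak.

    After normalisation the tallest end-inhale peak sits exactly at 1.0,
    which makes relative-amplitude comparison between a mm-scale and an
    arbitrary-pressure-unit channel meaningful.  Peak times are unchanged.
    """
    if len(peaks) == 0:
        raise NormalizationError("cannot normalise: no detected peaks")
    peak_amps = np.interp(peaks.peak_times, trace.times, trace.amplitudes)
    scale = float(peak_amps.max())
    if scale == 0.0:
        raise NormalizationError("cannot normalise: maximum peak amplitude is zero")
    return trace.copy_with(amplitudes=trace.amplitudes / scale)


def pair_peaks(
    a: PeakList | np.ndarray,
    b: PeakList | np.ndarray,
    max_offset_s: float,
) -> Tuple[List[Tuple[float, float]], int, int]:
    """Greedy nearest-neighbour matching of two sorted peak-time lists.

    Candidate pairs are considered in order of increasing |time difference|;
    each peak is used at most once and pairs farther apart than
    ``max_offset_s`` are discarded.  Returns ``(pairs, n_unmatched_a,
    n_unmatched_b)`` with pairs as ``(time_a, time_b)`` sorted by time_a.
    """
    ta = np.asarray(a.peak_times if isinstance(a, PeakList) else a, dtype=float)
    tb = np.asarray(b.peak_times if isinstance(b, PeakList) else b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        return [], int(ta.size), int(tb.size)
    diffs = np.abs(ta[:, None] - tb[None, :])
    order = np.argsort(diffs, axis=None, kind="stable")
    used_a = np.zeros(ta.size, dtype=bool)
    used_b = np.zeros(tb.size, dtype=bool)
    pairs: List[Tuple[float, float]] = []
    for flat in order:
        i, j = divmod(int(flat), tb.size)
        if diffs[i, j] > max_offset_s:
            break
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((float(ta[i]), float(tb[j])))
    pairs.sort(key=lambda p: p[0])
    return pairs, int((~used_a).sum()), int((~used_b).sum())


def latency_summary(
    pairs: Sequence[Tuple[float, float]],
    hist_bin_ms: float = 20.0,
    n_unmatched_a: int = 0,
    n_unmatched_b: int = 0,
) -> LatencySummary:
    """Summarise signed peak-time differences between paired channels.

    For a pair ``(t_rpm, t_bellows)`` the delta is ``(t_bellows - t_rpm)``
    in milliseconds, so a positive value means the rpm end-inhale occurred
    before the bellows end-inhale (rpm leads).  The histogram uses
    half-open ``(left, right]`` bins of width ``hist_bin_ms`` aligned to
    multiples of the bin width.
    """
    if len(pairs) == 0:
        raise InsufficientDataError("latency summary requires at least one peak pair")
    deltas = np.array([(tb - ta) * 1000.0 for ta, tb in pairs])
    w = float(hist_bin_ms)
    lo = w * (math.ceil(deltas.min() / w) - 1)
    hi = w * math.ceil(deltas.max() / w)
    if hi <= lo:
        hi = lo + w
    edges = np.arange(lo, hi + 0.5 * w, w)
    eps = 1e-9  # absorb float error for deltas landing exactly on an edge
    counts = np.array(
        [
            np.sum((deltas > edges[k] + eps) & (deltas <= edges[k + 1] + eps))
            for k in range(len(edges) - 1)
        ]
    )
    sd = float(np.std(deltas, ddof=1)) if deltas.size > 1 else 0.0
    return LatencySummary(
        pair_deltas_ms=deltas,
        mean_ms=float(deltas.mean()),
        sd_ms=sd,
        min_ms=float(deltas.min()),
        max_ms=float(deltas.max()),
        hist_edges_ms=edges,
        hist_counts=counts,
        n_unmatched_a=n_unmatched_a,
        n_unmatched_b=n_unmatched_b,
    )


def trace_stats(trace: SurrogateTrace, peaks: PeakList) -> TraceStats:
    """Amplitude mean/SD/%CV and breathing rate over a cropped trace.

    SD is the sample standard deviation (n-1).  %CV = SD / mean x 100
    quantifies breathing-amplitude irregularity; breathing rate is the
    detected peak count divided by the analysed duration, in breaths/min.
    """
    a = trace.amplitudes
    mean = float(a.mean())
    sd = float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    if mean == 0.0:
        raise InsufficientDataError("%CV undefined: mean amplitude is zero")
    duration = trace.duration
    bpm = len(peaks) / duration * 60.0 if duration > 0 else 0.0
    return TraceStats(
        mean_amp=mean,
        sd_amp=sd,
        cv_percent=sd / mean * 100.0,
        bpm=bpm,
        duration_s=duration,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("pearson_r requires equal-length sequences of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("pearson_r undefined for zero-variance input")
    return float(_stats.pearsonr(x, y).statistic)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the statistic for the first sample.  The
    p-value is exact (full enumeration of rank assignments) when the pooled
    sample has at most 20 observations and no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires two nonempty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = _stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
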