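"""Raw ECG to artifact-filtered normal-to-normal (NN) interval series.

Three stages: R-peak detection (a Pan–Tompkins-style energy detector),
conversion of peak times to interbeat intervals (IBIs), and artifact
filtering that drops physiologically implausible or locally deviant
intervals — "abnormal" beats are removed, not interpolated, so the
surviving intervals are normal-to-normal (NN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from dyadsync.errors import DetectionError, InputError

#: physiological band for an acceptable interbeat interval, ms
DEFAULT_IBI_BAND_MS = (300.0, 2000.0)
#: maximum relative deviation from the running median of recent accepted beats
DEFAULT_MAX_REL_DEVIATION = 0.30
#: how many previously accepted intervals feed the running median
DEFAULT_MEDIAN_WINDOW = 10
#: minimum spacing between detected R-peaks, s (absolute cardiac refractory)
REFRACTORY_S = 0.25


@dataclass
class ECGRecording:
    """Single-channel ECG for one participant.

    Parameters
    ----------
    participant_id : int
    sampling_rate : float
        Hz; must be positive.
    samples : ndarray
        Voltage in mV.
    class_id : int
        Classroom session the participant belongs to.
    start_offset_s : float
        Recording start relative to the common session clock.
    """

    participant_id: int
    sampling_rate: float
    samples: np.ndarray
    class_id: int = 0
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InputError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.samples.size == 0:
            raise InputError("ECG recording has no samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class BeatSeries:
    """Detected R-peak times for one participant, in seconds."""

    participant_id: int
    peak_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.size > 1 and np.any(np.diff(self.peak_times_s) <= 0):
            raise InputError(
                f"participant {self.participant_id}: peak times must be strictly increasing"
            )

    def __len__(self) -> int:
        return int(self.peak_times_s.size)


@dataclass
class RawIntervals:
    """Unfiltered interbeat intervals; each interval is stamped at its terminating beat."""

    participant_id: int
    intervals_ms: np.ndarray
    interval_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.interval_times_s = np.asarray(self.interval_times_s, dtype=float)


@dataclass
class NNSeries:
    """Artifact-filtered normal-to-normal intervals.

    ``rejected_count`` is the number of raw intervals that the artifact
    rule removed; accepted + rejected equals the raw interval count.
    """

    participant_id: int
    intervals_ms: np.ndarray
    interval_times_s: np.ndarray
    rejected_count: int = 0
    band_ms: tuple = field(default=DEFAULT_IBI_BAND_MS)

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.interval_times_s = np.asarray(self.interval_times_s, dtype=float)
        if self.intervals_ms.shape != self.interval_times_s.shape:
            raise InputError("intervals and times must have equal length")
        if self.interval_times_s.size > 1 and np.any(np.diff(self.interval_times_s) <= 0):
            raise InputError(
                f"participant {self.participant_id}: interval times must be strictly increasing"
            )

    def __len__(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def duration_s(self) -> float:
        if self.interval_times_s.size == 0:
            return 0.0
        return float(self.interval_times_s[-1])


def detect_r_peaks(
    rec: ECGRecording,
    *,
    refractory_s: float = REFRACTORY_S,
    refine_window_s: float = 0.040,
    on_flat: str = "empty",
) -> BeatSeries:
    """Detect R-peaks with a band-pass / differentiate / square / integrate chain.

    The QRS energy envelope is thresholded adaptively (per 10-s block,
    at 30% of the block's near-maximal envelope), candidate peaks are
    separated by at least ``refractory_s``, and every candidate is
    refined to the local maximum of the raw signal within
    ``±refine_window_s``.

    Parameters
    ----------
    on_flat : {"empty", "error"}
        What to do when the signal carries no QRS-like energy.
    """
    fs = rec.sampling_rate
    if fs < 100:
        raise DetectionError(
            f"participant {rec.participant_id}: sampling rate {fs} Hz < 100 Hz minimum"
        )
    if rec.duration_s < 10.0:
        raise DetectionError(
            f"participant {rec.participant_id}: recording of {rec.duration_s:.1f} s "
            "is shorter than the 10 s minimum"
        )
    x = rec.samples - np.mean(rec.samples)
    peak_to_peak = float(np.max(x) - np.min(x)) if x.size else 0.0
    if peak_to_peak < 1e-9:
        if on_flat == "error":
            raise DetectionError(
                f"participant {rec.participant_id}: flat signal (peak-to-peak "
                f"{peak_to_peak:.2e} mV), no beats detectable"
            )
        return BeatSeries(rec.participant_id, np.empty(0))

    # band-pass around QRS energy (5-30 Hz keeps the R wave, drops baseline and EMG)
    nyq = fs / 2.0
    hi = min(30.0, 0.9 * nyq)
    b, a = sps.butter(2, [5.0 / nyq, hi / nyq], btype="band")
    filtered = sps.filtfilt(b, a, x)
    envelope = np.convolve(
        np.gradient(filtered) ** 2,
        np.ones(max(1, int(round(0.150 * fs)))),
        mode="same",
    )

    # block-adaptive threshold: robust to slow amplitude drift
    block = max(1, int(round(10.0 * fs)))
    threshold = np.empty_like(envelope)
    for start in range(0, envelope.size, block):
        seg = envelope[start : start + block]
        threshold[start : start + block] = 0.30 * np.percentile(seg, 99.5)
    floor = 1e-3 * np.max(envelope)
    threshold = np.maximum(threshold, floor)

    candidates, _ = sps.find_peaks(
        envelope, height=threshold, distance=max(1, int(round(refractory_s * fs)))
    )
    if candidates.size == 0:
        if on_flat == "error":
            raise DetectionError(
                f"participant {rec.participant_id}: no QRS candidates above threshold"
            )
        return BeatSeries(rec.participant_id, np.empty(0))

    # refine to the raw-signal maximum near each candidate
    half = int(round(refine_window_s * fs))
    refined = np.empty(candidates.size, dtype=np.int64)
    for k, c in enumerate(candidates):
        lo = max(0, c - half)
        hi_i = min(x.size, c + half + 1)
        refined[k] = lo + int(np.argmax(x[lo:hi_i]))
    refined = np.unique(refined)
    # refinement may merge neighbours; re-impose the refractory spacing
    keep = [int(refined[0])]
    min_gap = refractory_s * fs
    for idx in refined[1:]:
        if idx - keep[-1] >= min_gap:
            keep.append(int(idx))
        elif x[idx] > x[keep[-1]]:
            keep[-1] = int(idx)
    times = rec.start_offset_s + np.asarray(keep, dtype=float) / fs
    return BeatSeries(rec.participant_id, times)


def peaks_to_ibi(beats: BeatSeries) -> RawIntervals:
    """Successive R-peak differences in ms, stamped at the terminating peak."""
    t = beats.peak_times_s
    if t.size < 2:
        return RawIntervals(beats.participant_id, np.empty(0), np.empty(0))
    return RawIntervals(beats.participant_id, 1000.0 * np.diff(t), t[1:])


def _accepts_everything(
    v: np.ndarray, lo: float, hi: float, max_rel_dev: float, median_window: int
) -> bool:
    """True iff the artifact rule, applied sequentially, rejects nothing."""
    if np.any((v < lo) | (v > hi)):
        return False
    n = v.size
    head = min(n, median_window + 1)
    # exact sequential medians for the short prefix
    for k in range(1, head):
        med = np.median(v[max(0, k - median_window) : k])
        if abs(v[k] - med) > max_rel_dev * med:
            return False
    if n <= median_window + 1:
        return True
    windows = np.lib.stride_tricks.sliding_window_view(v[:-1], median_window)
    meds = np.median(windows, axis=1)  # meds[k] = median of v[k : k+window]
    target = v[median_window:]
    return not np.any(np.abs(target - meds) > max_rel_dev * meds)


def filter_abnormal(
    raw: RawIntervals,
    *,
    band_ms: tuple = DEFAULT_IBI_BAND_MS,
    max_rel_deviation: float = DEFAULT_MAX_REL_DEVIATION,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
) -> NNSeries:
    """Drop abnormal intervals, yielding an NN series.

    An interval is rejected when it lies outside ``band_ms`` or deviates
    by more than ``max_rel_deviation`` from the running median of the
    previous ``median_window`` *accepted* intervals.  Rejected intervals
    are dropped, never interpolated; the count is recorded.  The rule is
    idempotent: every interval a pass accepts would be accepted again.
    """
    lo, hi = band_ms
    v_all = np.asarray(raw.intervals_ms, dtype=float)
    # fast path: when no interval would be rejected, accepted == raw and the
    # running medians can be computed vectorised over the raw series
    if v_all.size and _accepts_everything(v_all, lo, hi, max_rel_deviation, median_window):
        return NNSeries(
            raw.participant_id,
            v_all.copy(),
            np.asarray(raw.interval_times_s, dtype=float).copy(),
            rejected_count=0,
            band_ms=band_ms,
        )
    accepted_v: list[float] = []
    accepted_t: list[float] = []
    rejected = 0
    for v, t in zip(raw.intervals_ms, raw.interval_times_s):
        if not (lo <= v <= hi):
            rejected += 1
            continue
        recent = accepted_v[-median_window:]
        if recent:
            med = float(np.median(recent))
            if abs(v - med) > max_rel_deviation * med:
                rejected += 1
                continue
        accepted_v.append(float(v))
        accepted_t.append(float(t))
    return NNSeries(
        raw.participant_id,
        np.asarray(accepted_v),
        np.asarray(accepted_t),
        rejected_count=rejected,
        band_ms=band_ms,
    )


def ecg_to_nn(rec: ECGRecording, **filter_kwargs) -> NNSeries:
    """Convenience chain: detect peaks, form IBIs, filter artifacts."""
    return filter_abnormal(peaks_to_ibi(detect_r_peaks(rec)), **filter_kwargs)


def beats_to_nn(
    participant_id: int, beat_times_s: np.ndarray, **filter_kwargs
) -> NNSeries:
    """NN series straight from known beat times (e.g. simulator truth)."""
    beats = BeatSeries(participant_id, np.asarray(beat_times_s, dtype=float))
    return filter_abnormal(peaks_to_ibi(beats), **filter_kwargs)
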