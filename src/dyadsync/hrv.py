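"""Sliding-window time-domain HRV features and per-participant session trends.

For every participant the NN series is summarised in overlapping windows
by three features: HR (bpm, the inverse of the mean NN interval), SDNN
(ms, sample standard deviation of NN intervals) and rMSSD (ms, root mean
square of successive NN differences).  Windows advance by
``length − overlap`` with the overlap defaulting to one third of the
window length.  A window with too few beats is flagged invalid rather
than dropped, so vectors from different participants stay aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from dyadsync.ecg import NNSeries
from dyadsync.errors import ConfigurationError, InputError

FEATURES = ("HR", "SDNN", "rMSSD")

#: window lengths used throughout the analysis, s
DEFAULT_WINDOW_LENGTHS = (60, 100, 140, 180, 220, 260, 300)

#: tolerance (s) when deciding whether two accepted intervals are adjacent
_ADJACENCY_TOL_S = 1e-6


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    ``overlap_s`` defaults to one third of the window length, i.e. the
    window advances by two thirds of its length.  ``origin_s`` shifts
    the first window, e.g. to skip a baseline segment.
    """

    length_s: float = 300.0
    overlap_s: float | None = None
    origin_s: float = 0.0
    min_beats: int = 10

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ConfigurationError(f"window length must be positive, got {self.length_s}")
        if self.overlap_s is not None and not (0 <= self.overlap_s < self.length_s):
            raise ConfigurationError(
                f"overlap {self.overlap_s} must lie in [0, {self.length_s})"
            )

    @property
    def overlap(self) -> float:
        return self.length_s / 3.0 if self.overlap_s is None else self.overlap_s

    @property
    def step_s(self) -> float:
        return self.length_s - self.overlap


@dataclass
class FeatureVector:
    """One participant's windowed values of a single feature."""

    participant_id: int
    feature: str
    window_spec: WindowSpec
    window_starts_s: np.ndarray
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.window_starts_s = np.asarray(self.window_starts_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (len(self.values) == len(self.window_starts_s) == len(self.valid_mask)):
            raise InputError("window starts, values and validity mask must align")
        if self.feature not in FEATURES:
            raise InputError(f"unknown feature {self.feature!r}, expected one of {FEATURES}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class TrendFit:
    """OLS slope of a feature against window start time over one session."""

    participant_id: int
    feature: str
    slope: float  # feature units per second
    intercept: float
    n_windows: int


def make_windows(duration_s: float, spec: WindowSpec) -> np.ndarray:
    """Start times of all complete windows ``[start, start + length)``.

    Windows begin at ``origin_s`` and advance by ``spec.step_s``; only
    windows that fit entirely inside ``duration_s`` are produced.
    """
    if duration_s <= 0:
        raise InputError(f"duration must be positive, got {duration_s}")
    step = spec.step_s
    n = math.floor((duration_s - spec.length_s - spec.origin_s) / step) + 1
    if n <= 0:
        return np.empty(0)
    return spec.origin_s + step * np.arange(n)


def hr_feature(nn_ms: np.ndarray) -> float:
    """Heart rate in bpm: 60000 divided by the mean NN interval in ms."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    if nn_ms.size == 0:
        return np.nan
    return 60000.0 / float(np.mean(nn_ms))


def sdnn_feature(nn_ms: np.ndarray) -> float:
    """Sample standard deviation (ddof=1) of NN intervals, ms."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    if nn_ms.size < 2:
        return np.nan
    return float(np.std(nn_ms, ddof=1))


def rmssd_feature(nn_ms: np.ndarray, times_s: np.ndarray | None = None) -> float:
    """Root mean square of successive NN differences, ms.

    When interval times are supplied, differences are taken only between
    temporally adjacent accepted intervals — an artifact rejection breaks
    adjacency, so differences never straddle a removed beat.
    """
    nn_ms = np.asarray(nn_ms, dtype=float)
    if nn_ms.size < 2:
        return np.nan
    diffs = np.diff(nn_ms)
    if times_s is not None:
        times_s = np.asarray(times_s, dtype=float)
        # interval k spans (t_k - nn_k/1000, t_k]; adjacent iff the next
        # interval starts where this one ends
        starts = times_s[1:] - nn_ms[1:] / 1000.0
        adjacent = np.abs(starts - times_s[:-1]) < _ADJACENCY_TOL_S
        diffs = diffs[adjacent]
    if diffs.size == 0:
        return np.nan
    return float(np.sqrt(np.mean(diffs**2)))


def feature_matrix(nn: NNSeries, spec: WindowSpec) -> dict[str, FeatureVector]:
    """All three feature vectors for one participant on a common window grid.

    The validity mask is shared across features: a window is valid iff
    it contains at least ``spec.min_beats`` accepted intervals.  Values
    in invalid windows are NaN and flagged, never silently dropped.
    """
    if len(nn) == 0:
        raise InputError(f"participant {nn.participant_id}: empty NN series")
    starts = make_windows(nn.duration_s, spec)
    if starts.size == 0:
        raise InputError(
            f"participant {nn.participant_id}: NN series of {nn.duration_s:.0f} s "
            f"does not span one {spec.length_s:.0f} s window"
        )
    t = nn.interval_times_s
    n_win = starts.size
    out = {f: np.full(n_win, np.nan) for f in FEATURES}
    valid = np.zeros(n_win, dtype=bool)
    lo_idx = np.searchsorted(t, starts, side="left")
    hi_idx = np.searchsorted(t, starts + spec.length_s, side="left")
    for w, (i, j) in enumerate(zip(lo_idx, hi_idx)):
        seg = nn.intervals_ms[i:j]
        if seg.size < spec.min_beats:
            continue
        valid[w] = True
        out["HR"][w] = hr_feature(seg)
        out["SDNN"][w] = sdnn_feature(seg)
        out["rMSSD"][w] = rmssd_feature(seg, t[i:j])
    return {
        f: FeatureVector(nn.participant_id, f, spec, starts, out[f], valid)
        for f in FEATURES
    }


def linear_trend(fv: FeatureVector) -> TrendFit:
    """OLS trend of the feature against window start time (valid windows only)."""
    m = fv.valid_mask
    if m.sum() < 3:
        raise InputError(
            f"participant {fv.participant_id}: {int(m.sum())} valid windows, "
            "need at least 3 for a trend fit"
        )
    slope, intercept = np.polyfit(fv.window_starts_s[m], fv.values[m], 1)
    return TrendFit(fv.participant_id, fv.feature, float(slope), float(intercept), int(m.sum()))


def with_origin(spec: WindowSpec, origin_s: float) -> WindowSpec:
    """Copy of a spec with the analysis origin shifted (e.g. past a baseline video)."""
    return replace(spec, origin_s=origin_s)
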