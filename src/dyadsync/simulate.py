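"""Synthetic classrooms of coupled dyadic beat series, ECG and self-reports.

The generator emulates the statistical structure the compliance
analysis assumes, on a ~90-minute session scale:

* each participant's interbeat intervals are a base IBI plus a slow
  heart-rate drift (shared classroom-wide by a configurable fraction of
  dyads, emulating gradual relaxation) plus white beat noise whose
  *dispersion* is modulated by a slow zero-mean latent process;
* within a dyad the dispersion latent is ``sqrt(k)*shared +
  sqrt(1-k)*private`` with coupling strength ``k`` in [0, 1] — coupling
  enters only through beat-to-beat dispersion, never the mean IBI, so
  SDNN compliance is pairing-specific while HR correlation is driven by
  the classroom-common drift regardless of pairing;
* self-reported temporal demand decreases with the dyad's coupling;
  the other items are independent of it.

One RNG stream, seeded from the config, drives everything; identical
configs reproduce identical classrooms bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from dyadsync.compliance import ClassroomLayout
from dyadsync.errors import ConfigurationError, InputError
from dyadsync.selfreport import SelfReport

#: population norms (mean, SD) of the self-report items on their 0-10 scale,
#: matching values typical of a demanding but manageable classroom session
ITEM_NORMS = {
    "MD": (6.0, 2.05),
    "TD": (6.0, 1.88),
    "Pe": (6.4, 2.50),
    "Ef": (6.3, 2.62),
    "Fr": (4.2, 2.91),
    "Na": (8.1, 1.69),
}

#: hard physiological clip on a generated IBI, ms (keeps series inside the
#: artifact-filter band by construction)
_IBI_CLIP_MS = (301.0, 1999.0)

#: largest analysis window the session must span, s
_MAX_WINDOW_S = 300.0


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the emulated study conditions.

    Parameters
    ----------
    n_dyads_per_class : list[int]
        Dyads per classroom session (four sessions of 5/5/5/4 dyads,
        38 participants, by default).
    session_length_s : float
        Recording length; ~90 minutes by default.
    base_ibi_ms : float
        Population mean interbeat interval (800 ms = 75 bpm).
    coupling : float | sequence | None
        Per-dyad coupling strength k in [0, 1].  A scalar applies to all
        dyads; None spreads dyads evenly over [0.1, 0.9].
    hr_trend_slope_bpm_per_min : float
        Classroom-common HR drift; negative means relaxation over the
        session (-0.05 bpm/min ~ -4.5 bpm over 90 min).
    trend_participation : float
        Fraction of dyads whose members express the common drift.
    sdnn_latent_timescale_s : float
        Autocorrelation timescale of the slow dispersion latent.
    noise_sd_ms : float
        Baseline beat-level white-noise SD.
    dispersion_log_gain : float
        Log-scale amplitude with which the latent modulates the local
        dispersion (0 disables modulation and hence all SDNN coupling).
    hr_baseline_sd_bpm : float
        Between-participant spread of resting HR.
    tlx_temporal_effect : float
        Slope of the expected dyad temporal-demand *sum* on k; negative
        reproduces "less temporal demand felt in better-coupled dyads".
    seed : int | None
        RNG seed; same seed, same classroom.
    """

    n_dyads_per_class: list[int] = field(default_factory=lambda: [5, 5, 5, 4])
    session_length_s: float = 5400.0
    base_ibi_ms: float = 800.0
    coupling: float | list[float] | None = None
    hr_trend_slope_bpm_per_min: float = -0.05
    trend_participation: float = 0.8
    sdnn_latent_timescale_s: float = 120.0
    noise_sd_ms: float = 15.0
    dispersion_log_gain: float = 0.5
    hr_baseline_sd_bpm: float = 3.0
    tlx_temporal_effect: float = -6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.n_dyads_per_class or any(n < 1 for n in self.n_dyads_per_class):
            raise ConfigurationError(
                f"n_dyads_per_class must be positive integers, got {self.n_dyads_per_class}"
            )
        if self.session_length_s <= _MAX_WINDOW_S:
            raise ConfigurationError(
                f"session_length_s={self.session_length_s} must exceed the largest "
                f"analysis window ({_MAX_WINDOW_S:.0f} s)"
            )
        if not (300.0 < self.base_ibi_ms < 2000.0):
            raise ConfigurationError(
                f"base_ibi_ms={self.base_ibi_ms} outside the physiological band (300, 2000)"
            )
        if not (0.0 <= self.trend_participation <= 1.0):
            raise ConfigurationError("trend_participation must lie in [0, 1]")
        for k in np.atleast_1d(self.coupling_per_dyad()):
            if not (0.0 <= k <= 1.0):
                raise ConfigurationError(f"coupling {k} outside [0, 1]")

    @property
    def n_dyads(self) -> int:
        return int(sum(self.n_dyads_per_class))

    @property
    def n_participants(self) -> int:
        return 2 * self.n_dyads

    def coupling_per_dyad(self) -> np.ndarray:
        """Resolve the coupling field to one k per dyad."""
        n = int(sum(self.n_dyads_per_class))
        if self.coupling is None:
            if n == 1:
                return np.array([0.5])
            return np.linspace(0.1, 0.9, n)
        arr = np.atleast_1d(np.asarray(self.coupling, dtype=float))
        if arr.size == 1:
            return np.full(n, float(arr[0]))
        if arr.size != n:
            raise ConfigurationError(
                f"coupling has {arr.size} entries for {n} dyads"
            )
        return arr

    def make_layout(self) -> ClassroomLayout:
        """(i, i + n_dyads) pairing with contiguous class blocks."""
        n = self.n_dyads
        dyads = [(d + 1, d + 1 + n) for d in range(n)]
        class_of: dict[int, int] = {}
        d = 0
        for cls, count in enumerate(self.n_dyads_per_class):
            for _ in range(count):
                class_of[d + 1] = cls
                class_of[d + 1 + n] = cls
                d += 1
        return ClassroomLayout(dyads, class_of)


@dataclass
class SyntheticClassroom:
    """Generator output: beat series, layout, reports and ground truth."""

    beat_series: dict[int, np.ndarray]
    layout: ClassroomLayout
    reports: dict[int, SelfReport]
    truth: dict
    config: SyntheticConfig
    ecg: dict[int, tuple[np.ndarray, float]] | None = None


def _ou_path(rng: np.random.Generator, n: int, tau_s: float) -> np.ndarray:
    """Stationary unit-variance Ornstein–Uhlenbeck path on a 1 s grid."""
    a = np.exp(-1.0 / tau_s)
    s = np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    if n == 1:
        return eps
    rest, _ = lfilter([s], [1.0, -a], eps[1:], zi=np.array([a * eps[0]]))
    return np.concatenate(([eps[0]], rest))


def _beat_loop(
    rng: np.random.Generator,
    session_length_s: float,
    sigma_grid_ms: np.ndarray,
    hr0_bpm: float,
    slope_bpm_per_min: float,
) -> np.ndarray:
    """Cumulative beat times for one participant."""
    lo, hi = _IBI_CLIP_MS
    n_max = int(session_length_s * 1000.0 / lo) + 16
    noise = rng.standard_normal(n_max)
    t = float(rng.uniform(0.0, 0.8))
    times = [t]
    g_last = sigma_grid_ms.size - 1
    k = 0
    while t < session_length_s:
        hr = hr0_bpm + slope_bpm_per_min * t / 60.0
        hr = min(180.0, max(30.0, hr))
        ibi = 60000.0 / hr + sigma_grid_ms[min(int(t), g_last)] * noise[k]
        ibi = min(hi, max(lo, ibi))
        t += ibi / 1000.0
        times.append(t)
        k += 1
    if times[-1] > session_length_s:
        times.pop()
    return np.asarray(times)


def generate_classroom(config: SyntheticConfig) -> SyntheticClassroom:
    """Draw one classroom: coupled beat series, layout and self-reports.

    The per-dyad dispersion latent is an exponentially smoothed Gaussian
    process evaluated on a 1 s grid and shared between members with
    weight sqrt(k); the classroom-common HR drift is expressed by a
    ``trend_participation`` fraction of dyads (both members together).
    """
    rng = np.random.default_rng(config.seed)
    layout = config.make_layout()
    kappa = config.coupling_per_dyad()
    n_grid = int(np.ceil(config.session_length_s)) + 1
    tau = config.sdnn_latent_timescale_s
    gain = config.dispersion_log_gain

    trend_dyads = rng.random(config.n_dyads) < config.trend_participation
    beat_series: dict[int, np.ndarray] = {}
    latents: dict[int, np.ndarray] = {}
    shared: dict[int, np.ndarray] = {}
    hr0s: dict[int, float] = {}
    base_hr = 60000.0 / config.base_ibi_ms

    for d, (i, j) in enumerate(layout.dyads):
        u = _ou_path(rng, n_grid, tau)
        shared[d] = u
        for pid in (i, j):
            v = _ou_path(rng, n_grid, tau)
            z = np.sqrt(kappa[d]) * u + np.sqrt(1.0 - kappa[d]) * v
            # exp-link keeps dispersion positive; -gain^2/2 preserves the mean
            sigma = config.noise_sd_ms * np.exp(gain * z - gain * gain / 2.0)
            hr0 = base_hr + config.hr_baseline_sd_bpm * rng.standard_normal()
            slope = config.hr_trend_slope_bpm_per_min if trend_dyads[d] else 0.0
            beat_series[pid] = _beat_loop(
                rng, config.session_length_s, sigma, hr0, slope
            )
            latents[pid] = z
            hr0s[pid] = hr0

    reports: dict[int, SelfReport] = {}
    kappa_centered = kappa - float(np.mean(kappa))
    for d, (i, j) in enumerate(layout.dyads):
        for pid in (i, j):
            scores = {}
            for item, (mean, sd) in ITEM_NORMS.items():
                mu = mean
                if item == "TD":
                    # half the dyad-sum effect lands on each member
                    mu = mean + 0.5 * config.tlx_temporal_effect * kappa_centered[d]
                raw = round(mu + sd * rng.standard_normal())
                scores[item] = int(min(10, max(0, raw)))
            reports[pid] = SelfReport(pid, **scores)

    truth = {
        "coupling": kappa,
        "trend_dyads": trend_dyads,
        "hr0_bpm": hr0s,
        "dispersion_latent": latents,
        "shared_latent": shared,
    }
    return SyntheticClassroom(beat_series, layout, reports, truth, config)


def synthesize_ecg(
    beat_times_s: np.ndarray,
    sampling_rate: float = 500.0,
    *,
    duration_s: float | None = None,
    qrs_amplitude_mv: float = 1.0,
    qrs_sigma_s: float = 0.010,
    noise_sd_mv: float = 0.02,
    wander_amplitude_mv: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, float]:
    """Minimal ECG-like waveform: a narrow positive deflection per beat.

    Each beat contributes a Gaussian bump (sigma ~10 ms, amplitude well
    above the baseline noise) centred at the beat time, on top of white
    noise and a slow baseline wander.  Returns ``(samples_mv,
    sampling_rate)``.  This is a peak-detection test substrate, not a
    physiological PQRST morphology.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if sampling_rate < 100:
        raise InputError(f"sampling_rate {sampling_rate} Hz < 100 Hz minimum")
    if beat_times_s.size > 1 and np.any(np.diff(beat_times_s) <= 0):
        raise InputError("beat times must be strictly increasing")
    rng = np.random.default_rng(rng)
    if duration_s is None:
        duration_s = (beat_times_s[-1] + 1.0) if beat_times_s.size else 10.0
    n = int(np.ceil(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    x = noise_sd_mv * rng.standard_normal(n)
    x += wander_amplitude_mv * np.sin(2.0 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    half = int(np.ceil(4.0 * qrs_sigma_s * sampling_rate))
    kernel_t = np.arange(-half, half + 1) / sampling_rate
    for tb in beat_times_s:
        c = int(round(tb * sampling_rate))
        lo = max(0, c - half)
        hi = min(n, c + half + 1)
        if lo >= hi:
            continue
        offs = t[lo:hi] - tb
        x[lo:hi] += qrs_amplitude_mv * np.exp(-0.5 * (offs / qrs_sigma_s) ** 2)
    return x, float(sampling_rate)
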