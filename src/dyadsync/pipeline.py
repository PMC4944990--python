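"""End-to-end composition: recordings → features → compliance → tests → regression."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dyadsync.compliance import (
    ClassroomLayout,
    ComplianceResult,
    compute_compliance,
)
from dyadsync.ecg import (
    DEFAULT_IBI_BAND_MS,
    DEFAULT_MAX_REL_DEVIATION,
    ECGRecording,
    NNSeries,
    beats_to_nn,
    ecg_to_nn,
)
from dyadsync.errors import ConfigurationError, InputError
from dyadsync.hrv import (
    DEFAULT_WINDOW_LENGTHS,
    FEATURES,
    FeatureVector,
    TrendFit,
    WindowSpec,
    feature_matrix,
    linear_trend,
)
from dyadsync.permutation import (
    DEFAULT_N_PERMUTATIONS,
    PermutationResult,
    adjust_family,
    run_permutation_test,
)
from dyadsync.selfreport import RegressionFit, SelfReport, dyad_sums, fit_spc_regression

log = logging.getLogger("dyadsync")


@dataclass
class PipelineConfig:
    """Settings shared by the whole analysis chain.

    ``seed`` governs every stochastic stage (permutation streams are
    namespaced per feature/window so results do not depend on execution
    order).  ``holm_family`` is either ``"per_window"`` (adjust the
    three features within each window length, the default) or
    ``"all"`` (one family across every feature × window test).
    """

    window_lengths: tuple = DEFAULT_WINDOW_LENGTHS
    overlap_s: float | None = None  # None = one third of the window length
    origin_s: float = 0.0
    min_beats: int = 10
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    seed: int = 0
    holm_family: str = "per_window"
    ibi_band_ms: tuple = DEFAULT_IBI_BAND_MS
    max_rel_deviation: float = DEFAULT_MAX_REL_DEVIATION
    regression_windows: tuple = (60, 300)

    def __post_init__(self) -> None:
        if not self.window_lengths or any(l < 60 for l in self.window_lengths):
            raise ConfigurationError(
                f"window lengths must all be >= 60 s, got {self.window_lengths}"
            )
        if self.n_permutations < 100:
            raise ConfigurationError(
                f"n_permutations={self.n_permutations} must be >= 100"
            )
        if self.holm_family not in ("per_window", "all"):
            raise ConfigurationError(f"unknown holm_family {self.holm_family!r}")

    def spec(self, length_s: float) -> WindowSpec:
        return WindowSpec(
            length_s=length_s,
            overlap_s=self.overlap_s,
            origin_s=self.origin_s,
            min_beats=self.min_beats,
        )


@dataclass
class PipelineResult:
    """All stage outputs keyed by (feature, window length)."""

    nn: dict[int, NNSeries]
    features: dict[tuple[str, float], dict[int, FeatureVector]]
    compliance: dict[tuple[str, float], ComplianceResult]
    permutation: dict[tuple[str, float], PermutationResult]
    regression: dict[tuple[str, float], RegressionFit]
    trends: dict[tuple[str, float], dict[int, TrendFit]] = field(default_factory=dict)


def _stage_seed(base: int, feature: str, length_s: float) -> int:
    """Stable per-(feature, window) substream below 2**31."""
    h = (base * 1_000_003 + FEATURES.index(feature) * 7919 + int(length_s)) % (2**31 - 1)
    return int(h)


def nn_from_inputs(
    beats: dict[int, np.ndarray] | None = None,
    recordings: dict[int, ECGRecording] | None = None,
    *,
    config: PipelineConfig,
) -> dict[int, NNSeries]:
    """NN series per participant, from beat times or raw ECG."""
    out: dict[int, NNSeries] = {}
    kw = dict(band_ms=config.ibi_band_ms, max_rel_deviation=config.max_rel_deviation)
    for pid, times in (beats or {}).items():
        out[pid] = beats_to_nn(pid, times, **kw)
    for pid, rec in (recordings or {}).items():
        if pid in out:
            continue
        out[pid] = ecg_to_nn(rec, **kw)
    for pid, nn in out.items():
        log.info(
            "participant %d: %d NN intervals, %d rejected", pid, len(nn), nn.rejected_count
        )
    return out


def run_pipeline(
    layout: ClassroomLayout,
    *,
    beats: dict[int, np.ndarray] | None = None,
    recordings: dict[int, ECGRecording] | None = None,
    nn: dict[int, NNSeries] | None = None,
    reports: dict[int, SelfReport] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage for every (feature, window length).

    Inputs may enter at any level: raw recordings, beat times, or
    prepared NN series.  Self-report regression runs only when reports
    are supplied, for the configured regression windows.
    """
    config = config or PipelineConfig()
    layout.validate()
    if nn is None:
        if not beats and not recordings:
            raise InputError("no input: supply beats, recordings or nn series")
        nn = nn_from_inputs(beats, recordings, config=config)
    missing = [p for p in layout.participants if p not in nn]
    if missing:
        raise InputError(f"layout references participants without data: {missing}")

    features: dict[tuple[str, float], dict[int, FeatureVector]] = {}
    compliance: dict[tuple[str, float], ComplianceResult] = {}
    permutation: dict[tuple[str, float], PermutationResult] = {}
    trends: dict[tuple[str, float], dict[int, TrendFit]] = {}

    for length in config.window_lengths:
        spec = config.spec(float(length))
        per_pid = {pid: feature_matrix(nn[pid], spec) for pid in layout.participants}
        for feat in FEATURES:
            key = (feat, float(length))
            fvs = {pid: per_pid[pid][feat] for pid in layout.participants}
            features[key] = fvs
            comp = compute_compliance(fvs, layout)
            compliance[key] = comp
            permutation[key] = run_permutation_test(
                fvs,
                layout,
                comp.mu_true,
                n_permutations=config.n_permutations,
                seed=_stage_seed(config.seed, feat, float(length)),
            )
            tr = {}
            for pid, fv in fvs.items():
                if fv.n_valid >= 3:
                    tr[pid] = linear_trend(fv)
            trends[key] = tr
            log.info(
                "feature %s window %gs: mu_true=%.4f p_raw=%.4f (%d dyads, %d excluded)",
                feat, length, comp.mu_true, permutation[key].p_raw,
                layout.n_dyads, comp.n_excluded,
            )

    # multiple-testing families
    if config.holm_family == "per_window":
        for length in config.window_lengths:
            adjust_family([permutation[(f, float(length))] for f in FEATURES])
    else:
        adjust_family(list(permutation.values()))

    regression: dict[tuple[str, float], RegressionFit] = {}
    if reports:
        sums = [
            dyad_sums(k, reports[i], reports[j])
            for k, (i, j) in enumerate(layout.dyads)
        ]
        for length in config.regression_windows:
            if float(length) not in [float(l) for l in config.window_lengths]:
                continue
            for feat in FEATURES:
                key = (feat, float(length))
                regression[key] = fit_spc_regression(sums, compliance[key])
    return PipelineResult(nn, features, compliance, permutation, regression, trends)


def write_results(result: PipelineResult, out_dir: Path) -> None:
    """Persist every stage's tables under ``out_dir``."""
    from dyadsync import io as dio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dio.write_nn_tsv(result.nn, out_dir / "nn.tsv")
    dio.write_feature_tsv(
        [fv for fvs in result.features.values() for fv in fvs.values()],
        out_dir / "features.tsv",
    )
    dio.write_compliance_tsv(list(result.compliance.values()), out_dir / "compliance.tsv")
    dio.write_summary_tsv(list(result.permutation.values()), out_dir / "summary.tsv")
    dio.write_permutation_json(list(result.permutation.values()), out_dir / "permutation.json")
    if result.regression:
        dio.write_regression_tsv(list(result.regression.values()), out_dir / "regression.tsv")


def negative_trend_fraction(
    trends: dict[int, TrendFit], layout: ClassroomLayout
) -> float:
    """Fraction of dyads in which *both* members show a negative fitted trend."""
    neg = {pid: tf.slope < 0 for pid, tf in trends.items()}
    both = [
        neg.get(i, False) and neg.get(j, False) for i, j in layout.dyads
    ]
    return float(np.mean(both))
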