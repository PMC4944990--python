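"""Readers and writers for the on-disk session formats.

A session directory holds:

* ``layout.csv`` — ``dyad_id,first_id,second_id,class_id``
* ``reports.csv`` — ``participant_id,MD,TD,Pe,Ef,Fr,Na``
* ``annotations.csv`` — ``label,start_s,end_s`` protocol segments
* per participant, one of
  ``beats_p<ID>.csv`` — ``beat_time_s`` (R-peak times, seconds), or
  ``ecg_p<ID>.csv`` — ``time_s,mv`` sampled waveform; EDF is accepted
  where an EDF reader (``mne``) is importable.

The synthetic generator writes exactly these formats, so simulated
sessions feed every downstream stage unchanged.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from dyadsync.compliance import ClassroomLayout, ComplianceResult
from dyadsync.ecg import ECGRecording, NNSeries
from dyadsync.errors import InputError, ParseError
from dyadsync.hrv import FeatureVector
from dyadsync.permutation import PermutationResult
from dyadsync.selfreport import ITEMS, RegressionFit, SelfReport
from dyadsync.simulate import SyntheticClassroom, synthesize_ecg

_BEATS_RE = re.compile(r"beats_p(\d+)\.csv$")
_ECG_RE = re.compile(r"ecg_p(\d+)\.(csv|edf)$")


# ---------------------------------------------------------------- writing

def write_layout(layout: ClassroomLayout, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dyad_id", "first_id", "second_id", "class_id"])
        for k, (a, b) in enumerate(layout.dyads):
            w.writerow([k, a, b, layout.class_of[a]])


def write_reports(reports: dict[int, SelfReport], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", *ITEMS])
        for pid in sorted(reports):
            r = reports[pid]
            w.writerow([pid, *(getattr(r, it) for it in ITEMS)])


def write_annotations(segments: list[tuple[str, float, float]], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "start_s", "end_s"])
        for label, s, e in segments:
            w.writerow([label, f"{s:.3f}", f"{e:.3f}"])


def default_protocol(session_length_s: float, swap_s: float = 420.0) -> list:
    """Baseline video then alternating 7-minute driver/navigator segments."""
    segments = [("baseline", 0.0, min(swap_s, session_length_s))]
    t, role = swap_s, 0
    while t < session_length_s:
        end = min(t + swap_s, session_length_s)
        segments.append((f"driving_{'AB'[role]}", t, end))
        t, role = end, 1 - role
    return segments


def write_classroom(
    classroom: SyntheticClassroom,
    out_dir: Path,
    *,
    write_ecg: bool = False,
    sampling_rate: float = 250.0,
) -> Path:
    """Persist a synthetic classroom in the pipeline's input formats.

    By default beat-time files are written (compact, exact); with
    ``write_ecg`` a sampled waveform is synthesised per participant so
    the R-peak detector runs too.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_layout(classroom.layout, out_dir / "layout.csv")
    write_reports(classroom.reports, out_dir / "reports.csv")
    write_annotations(
        default_protocol(classroom.config.session_length_s), out_dir / "annotations.csv"
    )
    seed = classroom.config.seed
    for pid, beats in classroom.beat_series.items():
        if write_ecg:
            samples, fs = synthesize_ecg(
                beats,
                sampling_rate,
                duration_s=classroom.config.session_length_s,
                rng=None if seed is None else seed * 100003 + pid,
            )
            write_ecg_csv(samples, fs, out_dir / f"ecg_p{pid}.csv")
        else:
            with open(out_dir / f"beats_p{pid}.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["beat_time_s"])
                for t in beats:
                    w.writerow([f"{t:.6f}"])
    return out_dir


def write_ecg_csv(samples_mv: np.ndarray, sampling_rate: float, path: Path) -> None:
    t = np.arange(len(samples_mv)) / sampling_rate
    df = pd.DataFrame({"time_s": np.round(t, 6), "mv": np.round(samples_mv, 5)})
    df.to_csv(path, index=False)


def write_nn_tsv(series: dict[int, NNSeries], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["participant_id", "time_s", "nn_ms"])
        for pid in sorted(series):
            nn = series[pid]
            for t, v in zip(nn.interval_times_s, nn.intervals_ms):
                w.writerow([pid, f"{t:.6f}", f"{v:.6f}"])


def write_feature_tsv(features: list[FeatureVector], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["participant_id", "feature", "window_len_s", "window_start_s", "value", "valid"]
        )
        for fv in features:
            for start, val, ok in zip(fv.window_starts_s, fv.values, fv.valid_mask):
                w.writerow(
                    [
                        fv.participant_id,
                        fv.feature,
                        f"{fv.window_spec.length_s:g}",
                        f"{start:g}",
                        "nan" if np.isnan(val) else f"{val:.17g}",
                        int(ok),
                    ]
                )


def write_compliance_tsv(results: list[ComplianceResult], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["feature", "window_len_s", "dyad_index", "r", "n_windows"])
        for res in results:
            for k, (r, n) in enumerate(zip(res.per_dyad_r, res.n_windows_used)):
                w.writerow(
                    [res.feature, f"{res.window_length_s:g}", k,
                     "nan" if np.isnan(r) else f"{r:.17g}", n]
                )


def write_summary_tsv(results: list[PermutationResult], path: Path) -> None:
    """Per (window, feature): null CI bounds, mean dyad correlation, adjusted p."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["window_len_s", "feature", "null_2.5%", "null_97.5%", "mean_cor", "p_adj"]
        )
        for r in results:
            w.writerow(
                [
                    f"{r.window_length_s:g}",
                    r.feature,
                    f"{r.ci_95[0]:.6f}",
                    f"{r.ci_95[1]:.6f}",
                    f"{r.mu_true:.6f}",
                    "" if r.p_adjusted is None else f"{r.p_adjusted:.6f}",
                ]
            )


def write_permutation_json(results: list[PermutationResult], path: Path) -> None:
    payload = [
        {
            "feature": r.feature,
            "window_length_s": r.window_length_s,
            "mu_true": r.mu_true,
            "ci_95": list(r.ci_95),
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "n_permutations": r.n_permutations,
            "seed": r.seed,
            "n_undefined_draws": r.n_undefined_draws,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_regression_tsv(fits: list[RegressionFit], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["window_len_s", "feature", "adj_r2", "term", "estimate", "std_err",
             "ci_2.5%", "ci_97.5%"]
        )
        for fit in fits:
            for term, beta in fit.beta.items():
                lo, hi = fit.ci_95[term]
                w.writerow(
                    [
                        f"{fit.window_length_s:g}",
                        fit.feature,
                        f"{fit.adjusted_r2:.6f}",
                        term,
                        f"{beta:.6f}",
                        f"{fit.se[term]:.6f}",
                        f"{lo:.6f}",
                        f"{hi:.6f}",
                    ]
                )


# ---------------------------------------------------------------- reading

def read_feature_tsv(path: Path) -> dict[tuple[str, float], dict[int, FeatureVector]]:
    """Inverse of :func:`write_feature_tsv`, keyed by (feature, window length)."""
    from dyadsync.hrv import WindowSpec

    df = _read_table(path, ["participant_id", "feature", "window_len_s",
                            "window_start_s", "value", "valid"], sep="\t")
    pid = _numeric(df, "participant_id", path).astype(int)
    length = _numeric(df, "window_len_s", path)
    start = _numeric(df, "window_start_s", path)
    value = np.array([float(x) for x in df["value"]])
    valid = _numeric(df, "valid", path).astype(bool)
    out: dict[tuple[str, float], dict[int, FeatureVector]] = {}
    frame = pd.DataFrame(
        {"pid": pid, "feature": df["feature"], "length": length,
         "start": start, "value": value, "valid": valid}
    )
    for (feat, L), grp in frame.groupby(["feature", "length"], sort=True):
        spec = WindowSpec(length_s=float(L))
        per: dict[int, FeatureVector] = {}
        for p, sub in grp.groupby("pid"):
            sub = sub.sort_values("start")
            per[int(p)] = FeatureVector(
                int(p), str(feat), spec,
                sub["start"].to_numpy(), sub["value"].to_numpy(),
                sub["valid"].to_numpy(),
            )
        out[(str(feat), float(L))] = per
    return out


def read_compliance_tsv(path: Path) -> dict[tuple[str, float], ComplianceResult]:
    """Inverse of :func:`write_compliance_tsv`."""
    from dyadsync.compliance import mean_dyad_correlation

    df = _read_table(path, ["feature", "window_len_s", "dyad_index", "r", "n_windows"],
                     sep="\t")
    length = _numeric(df, "window_len_s", path)
    idx = _numeric(df, "dyad_index", path).astype(int)
    r = np.array([float(x) for x in df["r"]])
    n = _numeric(df, "n_windows", path).astype(int)
    frame = pd.DataFrame(
        {"feature": df["feature"], "length": length, "idx": idx, "r": r, "n": n}
    )
    out: dict[tuple[str, float], ComplianceResult] = {}
    for (feat, L), grp in frame.groupby(["feature", "length"], sort=True):
        grp = grp.sort_values("idx")
        rs = grp["r"].to_numpy()
        out[(str(feat), float(L))] = ComplianceResult(
            feature=str(feat),
            window_length_s=float(L),
            per_dyad_r=rs,
            mu_true=mean_dyad_correlation(rs),
            n_windows_used=grp["n"].to_numpy(),
            n_excluded=int(np.isnan(rs).sum()),
        )
    return out



def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ParseError(
            f"{path}: line {line}: non-numeric value {df[col][bad.idxmax()]!r} "
            f"in column {col!r}"
        )
    if coerced.isna().any():
        line = int(coerced.isna().idxmax()) + 2
        raise ParseError(f"{path}: line {line}: missing value in column {col!r}")
    # python's float() is correctly rounded, so %.17g output round-trips bitwise
    return np.array([float(x) for x in df[col]])


def _read_table(path: Path, required: list[str], sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing input file: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df


def read_layout(path: Path) -> ClassroomLayout:
    df = _read_table(path, ["dyad_id", "first_id", "second_id", "class_id"])
    first = _numeric(df, "first_id", path).astype(int)
    second = _numeric(df, "second_id", path).astype(int)
    cls = _numeric(df, "class_id", path).astype(int)
    class_of = {}
    for a, b, c in zip(first, second, cls):
        class_of[int(a)] = int(c)
        class_of[int(b)] = int(c)
    return ClassroomLayout(list(zip(first, second)), class_of)


def read_reports(path: Path) -> dict[int, SelfReport]:
    df = _read_table(path, ["participant_id", *ITEMS])
    pids = _numeric(df, "participant_id", path).astype(int)
    cols = {it: _numeric(df, it, path).astype(int) for it in ITEMS}
    return {
        int(pid): SelfReport(int(pid), **{it: int(cols[it][k]) for it in ITEMS})
        for k, pid in enumerate(pids)
    }


def read_annotations(path: Path) -> list[tuple[str, float, float]]:
    df = _read_table(path, ["label", "start_s", "end_s"])
    starts = _numeric(df, "start_s", path)
    ends = _numeric(df, "end_s", path)
    return [(str(l), float(s), float(e)) for l, s, e in zip(df["label"], starts, ends)]


def read_beats_csv(path: Path, participant_id: int) -> np.ndarray:
    df = _read_table(path, ["beat_time_s"])
    return _numeric(df, "beat_time_s", path)


def read_ecg_csv(path: Path, participant_id: int, class_id: int = 0) -> ECGRecording:
    df = _read_table(path, ["time_s", "mv"])
    t = _numeric(df, "time_s", path)
    mv = _numeric(df, "mv", path)
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 samples to infer the sampling rate")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-4:
        raise ParseError(f"{path}: time_s must increase on a uniform grid")
    fs = 1.0 / float(np.mean(dt))
    return ECGRecording(participant_id, fs, mv, class_id=class_id, start_offset_s=float(t[0]))


def read_ecg_edf(path: Path, participant_id: int, class_id: int = 0) -> ECGRecording:
    """Read a single-channel EDF recording (requires the optional ``mne`` reader)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise InputError(
            f"{path}: EDF input requires the optional 'mne' package; "
            "convert to ECG CSV (time_s,mv) instead"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[0] * 1000.0  # V -> mV
    return ECGRecording(participant_id, float(raw.info["sfreq"]), data, class_id=class_id)


def read_session(in_dir: Path) -> dict:
    """Load a full session directory.

    Returns a dict with ``layout``, ``reports``, ``annotations`` and
    either ``beats`` (participant -> beat times) or ``recordings``
    (participant -> ECGRecording), validated against the layout.
    """
    in_dir = Path(in_dir)
    layout = read_layout(in_dir / "layout.csv")
    reports = read_reports(in_dir / "reports.csv")
    ann_path = in_dir / "annotations.csv"
    annotations = read_annotations(ann_path) if ann_path.exists() else []

    beats: dict[int, np.ndarray] = {}
    recordings: dict[int, ECGRecording] = {}
    for path in sorted(in_dir.iterdir()):
        m = _BEATS_RE.match(path.name)
        if m:
            pid = int(m.group(1))
            beats[pid] = read_beats_csv(path, pid)
            continue
        m = _ECG_RE.match(path.name)
        if m:
            pid = int(m.group(1))
            cls = layout.class_of.get(pid, 0)
            if path.suffix == ".csv":
                recordings[pid] = read_ecg_csv(path, pid, cls)
            else:
                recordings[pid] = read_ecg_edf(path, pid, cls)

    have = set(beats) | set(recordings)
    missing = [p for p in layout.participants if p not in have]
    if missing:
        raise InputError(
            f"{in_dir}: layout references participants without recordings: {missing}"
        )
    missing_reports = [p for p in layout.participants if p not in reports]
    if missing_reports:
        raise InputError(
            f"{in_dir}: layout references participants without reports: {missing_reports}"
        )
    return {
        "layout": layout,
        "reports": reports,
        "annotations": annotations,
        "beats": beats,
        "recordings": recordings,
    }
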