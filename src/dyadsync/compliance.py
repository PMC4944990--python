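"""Within-dyad Pearson compliance and the classroom mean statistic μ_true.

Social psychophysiological compliance (SPC) is measured as the Pearson
product-moment correlation between the two dyad members' windowed
feature vectors; the classroom-level statistic is the arithmetic mean of
the per-dyad correlations.  Windows invalid for either member are
dropped pairwise (no imputation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from dyadsync.errors import InputError, LayoutError
from dyadsync.hrv import FeatureVector

#: minimum jointly valid windows for a defined dyad correlation
MIN_JOINT_WINDOWS = 3


@dataclass
class ClassroomLayout:
    """Dyad pairings and class membership.

    Each dyad is an ordered pair ``(first_member_id, second_member_id)``
    — in the field protocol the two members alternate driver/navigator
    roles, and the permutation null re-pairs first members with second
    members of the same class, so the ordering matters.
    """

    dyads: list[tuple[int, int]]
    class_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dyads = [(int(a), int(b)) for a, b in self.dyads]
        if not self.class_of:
            self.class_of = {p: 0 for pair in self.dyads for p in pair}
        self.validate()

    def validate(self) -> None:
        seen: set[int] = set()
        for a, b in self.dyads:
            if a in seen or b in seen or a == b:
                raise LayoutError(f"participant appears in more than one dyad slot: ({a}, {b})")
            seen.update((a, b))
            if a not in self.class_of or b not in self.class_of:
                missing = a if a not in self.class_of else b
                raise LayoutError(f"participant {missing} has no class assignment")
            if self.class_of[a] != self.class_of[b]:
                raise LayoutError(
                    f"dyad ({a}, {b}) spans classes "
                    f"{self.class_of[a]} and {self.class_of[b]}"
                )
        if not self.dyads:
            raise LayoutError("layout contains no dyads")

    @property
    def n_dyads(self) -> int:
        return len(self.dyads)

    @property
    def participants(self) -> list[int]:
        return [p for pair in self.dyads for p in pair]

    def dyads_by_class(self) -> dict[int, list[int]]:
        """Class id -> indices into ``dyads`` (the permutation blocks)."""
        blocks: dict[int, list[int]] = {}
        for k, (a, _) in enumerate(self.dyads):
            blocks.setdefault(self.class_of[a], []).append(k)
        return blocks


@dataclass
class ComplianceResult:
    """Per-dyad correlations and their mean for one (feature, window length)."""

    feature: str
    window_length_s: float
    per_dyad_r: np.ndarray  # NaN where undefined
    mu_true: float
    n_windows_used: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.per_dyad_r = np.asarray(self.per_dyad_r, dtype=float)
        self.n_windows_used = np.asarray(self.n_windows_used, dtype=int)


def _joint_support(xA: FeatureVector, xB: FeatureVector):
    """Align two feature vectors on shared window starts, pairwise-valid only."""
    if xA.feature != xB.feature:
        raise InputError(f"feature mismatch: {xA.feature} vs {xB.feature}")
    if xA.window_spec != xB.window_spec:
        raise InputError(
            f"window spec mismatch between participants {xA.participant_id} "
            f"and {xB.participant_id}"
        )
    common, ia, ib = np.intersect1d(
        xA.window_starts_s, xB.window_starts_s, return_indices=True
    )
    joint = xA.valid_mask[ia] & xB.valid_mask[ib]
    return xA.values[ia][joint], xB.values[ib][joint]


def dyad_correlation(xA: FeatureVector, xB: FeatureVector) -> tuple[float, int]:
    """Pearson r over the dyad's pairwise-valid windows.

    Returns ``(r, n_windows)``; r is NaN (with a warning) when fewer
    than three windows are jointly valid or either series is constant
    over the joint support.
    """
    a, b = _joint_support(xA, xB)
    n = int(a.size)
    if n < MIN_JOINT_WINDOWS:
        warnings.warn(
            f"dyad ({xA.participant_id}, {xB.participant_id}): only {n} jointly "
            "valid windows, correlation undefined",
            stacklevel=2,
        )
        return np.nan, n
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            f"dyad ({xA.participant_id}, {xB.participant_id}): constant feature "
            "vector, correlation undefined",
            stacklevel=2,
        )
        return np.nan, n
    a = a - a.mean()
    b = b - b.mean()
    r = float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
    return min(1.0, max(-1.0, r)), n


def mean_dyad_correlation(rs) -> float:
    """Arithmetic mean of the defined per-dyad correlations (μ)."""
    rs = np.asarray(rs, dtype=float)
    defined = rs[~np.isnan(rs)]
    if defined.size == 0:
        raise InputError("all dyad correlations undefined; no mean available")
    return float(np.mean(defined))


def compute_compliance(
    features_by_pid: dict[int, FeatureVector], layout: ClassroomLayout
) -> ComplianceResult:
    """μ_true and per-dyad correlations for one feature on the true pairing."""
    rs = np.empty(layout.n_dyads)
    ns = np.empty(layout.n_dyads, dtype=int)
    for k, (i, j) in enumerate(layout.dyads):
        for p in (i, j):
            if p not in features_by_pid:
                raise InputError(f"no feature vector for laid-out participant {p}")
        rs[k], ns[k] = dyad_correlation(features_by_pid[i], features_by_pid[j])
    fv = features_by_pid[layout.dyads[0][0]]
    return ComplianceResult(
        feature=fv.feature,
        window_length_s=fv.window_spec.length_s,
        per_dyad_r=rs,
        mu_true=mean_dyad_correlation(rs),
        n_windows_used=ns,
        n_excluded=int(np.isnan(rs).sum()),
    )


def cross_correlation_matrices(
    features_by_pid: dict[int, FeatureVector], layout: ClassroomLayout
) -> dict[int, np.ndarray]:
    """Per-class matrix C[a, b] = r(first member of dyad a, second member of dyad b).

    Every admissible re-pairing under the class-restricted permutation
    null is an entry of one of these matrices, so the 10000-draw null
    only ever indexes into them.  The diagonal holds the true pairings.
    """
    out: dict[int, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cls, idxs in layout.dyads_by_class().items():
            n = len(idxs)
            C = np.empty((n, n))
            for a, ka in enumerate(idxs):
                for b, kb in enumerate(idxs):
                    i = layout.dyads[ka][0]
                    j = layout.dyads[kb][1]
                    C[a, b], _ = dyad_correlation(features_by_pid[i], features_by_pid[j])
            out[cls] = C
    return out
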