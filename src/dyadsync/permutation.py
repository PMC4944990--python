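"""Class-restricted permutation null for the mean dyad correlation μ.

The null hypothesis is that compliance does not depend on who actually
sat together: second members are re-paired with first members uniformly
at random *within each class*, preserving the driver/navigator role
structure and the shared classroom environment.  Each draw yields one
μ_r, the mean correlation over the shuffled pairs; 10000 draws form the
null distribution from which percentile CIs and two-tailed p-values are
read.  p-values across the feature family are Holm–Bonferroni adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dyadsync.compliance import ClassroomLayout, cross_correlation_matrices
from dyadsync.errors import InputError
from dyadsync.hrv import FeatureVector

DEFAULT_N_PERMUTATIONS = 10_000


@dataclass
class PermutationResult:
    """Null distribution summary for one (feature, window length)."""

    feature: str
    window_length_s: float
    mu_true: float
    mu_samples: np.ndarray
    ci_95: tuple[float, float]
    p_raw: float
    n_permutations: int
    seed: int | None = None
    p_adjusted: float | None = None
    n_undefined_draws: int = 0

    def __post_init__(self) -> None:
        self.mu_samples = np.asarray(self.mu_samples, dtype=float)


def sample_pairing(layout: ClassroomLayout, rng: np.random.Generator) -> list[tuple[int, int]]:
    """One admissible re-pairing: second members permuted within each class.

    First members stay fixed; the true pairing remains in the support
    (the draw is uniform over all block permutations, with no
    exclusion).
    """
    blocks = layout.dyads_by_class()
    paired: dict[int, int] = {}
    for idxs in blocks.values():
        perm = rng.permutation(len(idxs))
        for slot, src in zip(idxs, (idxs[p] for p in perm)):
            paired[slot] = src
    return [
        (layout.dyads[k][0], layout.dyads[paired[k]][1])
        for k in range(layout.n_dyads)
    ]


def null_distribution(
    features_by_pid: dict[int, FeatureVector],
    layout: ClassroomLayout,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, int]:
    """Draws of μ_r under the class-restricted null.

    Correlations for every admissible (first, second) pair are computed
    once; each permutation then only gathers precomputed entries, so
    10000 draws cost a few milliseconds.  Pairs with undefined
    correlations are excluded from a draw's mean and counted.

    Returns ``(mu_samples, n_draws_with_undefined_pairs)``.
    """
    if n_permutations < 1:
        raise InputError("need at least one permutation")
    rng = np.random.default_rng(rng)
    mats = [cross_correlation_matrices(features_by_pid, layout)[c]
            for c in sorted(layout.dyads_by_class())]
    draws = np.empty((n_permutations, layout.n_dyads))
    col = 0
    for C in mats:
        n = C.shape[0]
        # perms[d] = permutation of the block's second members for draw d
        perms = np.argsort(rng.random((n_permutations, n)), axis=1)
        draws[:, col : col + n] = C[np.arange(n)[None, :], perms]
        col += n
    undefined = np.isnan(draws)
    mu = np.nanmean(np.where(undefined, np.nan, draws), axis=1)
    if np.any(np.all(undefined, axis=1)):
        raise InputError("a permutation draw had no defined correlations")
    return mu, int(np.any(undefined, axis=1).sum())


def percentile_ci(mu_samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval (linear-interpolation percentiles)."""
    mu_samples = np.asarray(mu_samples, dtype=float)
    if mu_samples.size < 100:
        raise InputError(f"{mu_samples.size} samples; need at least 100 for a CI")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(mu_samples, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def two_tailed_p(mu_true: float, mu_samples: np.ndarray) -> float:
    """Two-tailed Monte-Carlo p with +1 smoothing (never exactly zero)."""
    mu_samples = np.asarray(mu_samples, dtype=float)
    if mu_samples.size == 0:
        raise InputError("empty null sample")
    n = mu_samples.size
    upper = (1 + np.sum(mu_samples >= mu_true)) / (n + 1)
    lower = (1 + np.sum(mu_samples <= mu_true)) / (n + 1)
    return float(min(1.0, 2.0 * min(upper, lower)))


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm's step-down familywise adjustment.

    The k-th smallest p is multiplied by (m − k + 1); a cumulative
    maximum enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise InputError(f"p-values must lie in (0, 1]: {p}")
    order = np.argsort(p, kind="stable")
    m = p.size
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_permutation_test(
    features_by_pid: dict[int, FeatureVector],
    layout: ClassroomLayout,
    mu_true: float,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> PermutationResult:
    """Full null construction for one feature: μ_r draws, 95% CI, raw p."""
    mu_samples, n_undef = null_distribution(
        features_by_pid, layout, n_permutations, np.random.default_rng(seed)
    )
    fv = next(iter(features_by_pid.values()))
    return PermutationResult(
        feature=fv.feature,
        window_length_s=fv.window_spec.length_s,
        mu_true=mu_true,
        mu_samples=mu_samples,
        ci_95=percentile_ci(mu_samples),
        p_raw=two_tailed_p(mu_true, mu_samples),
        n_permutations=n_permutations,
        seed=seed,
        n_undefined_draws=n_undef,
    )


def adjust_family(results: list[PermutationResult]) -> None:
    """Holm-adjust raw p-values across one declared family, in place."""
    adj = holm_bonferroni([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)


def enumerate_null(
    features_by_pid: dict[int, FeatureVector], layout: ClassroomLayout
) -> np.ndarray:
    """Exact null: μ_r for every block permutation (small layouts only).

    Feasible when each class has at most ~5 dyads; used as the
    enumeration oracle the Monte-Carlo null converges to.
    """
    from itertools import permutations, product

    mats = [cross_correlation_matrices(features_by_pid, layout)[c]
            for c in sorted(layout.dyads_by_class())]
    per_class: list[list[tuple[float, int]]] = []
    for C in mats:
        n = C.shape[0]
        sums = []
        for perm in permutations(range(n)):
            vals = C[np.arange(n), perm]
            sums.append((float(np.nansum(vals)), int(np.sum(~np.isnan(vals)))))
        per_class.append(sums)
    out = []
    for combo in product(*per_class):
        total = sum(s for s, _ in combo)
        count = sum(c for _, c in combo)
        if count == 0:
            raise InputError("enumerated draw had no defined correlations")
        out.append(total / count)
    return np.asarray(out)
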