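"""Regression of dyad compliance on summed self-reported task load.

Each participant rates the session on five NASA-TLX items — mental
demand (MD), temporal demand (TD), performance (Pe), effort (Ef),
frustration (Fr) — plus a navigating-concentration item (Na), all on
0–10 integer scales (the physical-demand TLX item is not collected, as
irrelevant to seated programming).  Items are summed within each dyad
and the per-dyad compliance correlation is modelled as

    r_dyad ~ b0 + bm*MD + bt*TD + bp*Pe + be*Ef + bf*Fr + bn*Na

by ordinary least squares, with t-based 95% CIs on n_dyads − 7 degrees
of freedom and the adjusted R² of the standard linear-model summary.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import statsmodels.api as sm

from dyadsync.compliance import ComplianceResult
from dyadsync.errors import InputError

ITEMS = ("MD", "TD", "Pe", "Ef", "Fr", "Na")

#: model terms in reporting order, mapping coefficient name -> item
TERMS = {
    "Intercept": None,
    "Mental": "MD",
    "Temporal": "TD",
    "Performance": "Pe",
    "Effort": "Ef",
    "Frustration": "Fr",
    "Navigating": "Na",
}


@dataclass(frozen=True)
class SelfReport:
    """One participant's item scores, each an integer in [0, 10]."""

    participant_id: int
    MD: int
    TD: int
    Pe: int
    Ef: int
    Fr: int
    Na: int

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "participant_id":
                continue
            v = getattr(self, f.name)
            if v is None:
                raise InputError(
                    f"participant {self.participant_id}: missing item {f.name}"
                )
            if not (0 <= v <= 10):
                raise InputError(
                    f"participant {self.participant_id}: item {f.name}={v} "
                    "outside the 0-10 scale"
                )


@dataclass(frozen=True)
class DyadSums:
    """Itemwise sums of the two members' scores (each in [0, 20])."""

    dyad_id: int
    MD: int
    TD: int
    Pe: int
    Ef: int
    Fr: int
    Na: int


@dataclass
class RegressionFit:
    """OLS fit of dyad compliance on the six item sums."""

    feature: str
    window_length_s: float
    beta: dict[str, float]
    se: dict[str, float]
    ci_95: dict[str, tuple[float, float]]
    adjusted_r2: float
    n_dyads: int

    @property
    def df_resid(self) -> int:
        return self.n_dyads - 7


def dyad_sums(dyad_id: int, a: SelfReport, b: SelfReport) -> DyadSums:
    """Itemwise sum of two members' reports."""
    return DyadSums(dyad_id, *(getattr(a, it) + getattr(b, it) for it in ITEMS))


def sums_frame(sums: list[DyadSums]) -> pd.DataFrame:
    """Dyad-by-item DataFrame of the summed scores."""
    return pd.DataFrame(
        [{"dyad_id": s.dyad_id, **{it: getattr(s, it) for it in ITEMS}} for s in sums]
    ).set_index("dyad_id")


def fit_spc_regression(
    sums: list[DyadSums] | pd.DataFrame,
    compliance: ComplianceResult | np.ndarray,
    feature: str = "",
    window_length_s: float = float("nan"),
) -> RegressionFit:
    """OLS of per-dyad compliance r on the six summed self-report items.

    Accepts either domain objects or a prepared DataFrame/array pair.
    Requires at least 8 dyads (one residual degree of freedom) and a
    full-rank design.
    """
    X = sums if isinstance(sums, pd.DataFrame) else sums_frame(sums)
    X = X[list(ITEMS)].astype(float)
    if isinstance(compliance, ComplianceResult):
        y = np.asarray(compliance.per_dyad_r, dtype=float)
        feature = feature or compliance.feature
        window_length_s = (
            compliance.window_length_s if np.isnan(window_length_s) else window_length_s
        )
    else:
        y = np.asarray(compliance, dtype=float)
    if len(y) != len(X):
        raise InputError(f"{len(y)} responses for {len(X)} dyads")
    keep = ~np.isnan(y)
    X, y = X[keep], y[keep]
    n = len(y)
    if n < 8:
        raise InputError(f"{n} dyads with defined compliance; need >= 8 (df >= 1)")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise InputError(
            "collinear self-report sums: design rank "
            f"{rank} < {design.shape[1]} columns"
        )
    res = sm.OLS(y, design).fit()
    name_of = {"const": "Intercept", **{v: k for k, v in TERMS.items() if v}}
    ci = res.conf_int(alpha=0.05)
    return RegressionFit(
        feature=feature,
        window_length_s=float(window_length_s),
        beta={name_of[k]: float(v) for k, v in res.params.items()},
        se={name_of[k]: float(v) for k, v in res.bse.items()},
        ci_95={name_of[k]: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in res.params.index},
        adjusted_r2=float(res.rsquared_adj),
        n_dyads=n,
    )


def population_item_mean(sums: list[DyadSums] | pd.DataFrame, item: str) -> float:
    """Per-participant mean of one item from the dyad sums.

    Each sum covers two participants, so the mean is the total divided
    by twice the number of dyads.
    """
    if item not in ITEMS:
        raise InputError(f"unknown item {item!r}, expected one of {ITEMS}")
    X = sums if isinstance(sums, pd.DataFrame) else sums_frame(sums)
    if len(X) == 0:
        raise InputError("no dyads")
    return float(X[item].sum() / (2 * len(X)))
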