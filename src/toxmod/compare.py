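"""Cross-condition comparison: ranking, concordance, and risk calls.

Within a condition, injury modules are ranked by z-score from the most to
the least likely injury endpoint, with p < 0.01 (permutation p) marking
significant activation.  Across two conditions — e.g. an in vivo tissue
and its in vitro cell model — concordance is the squared Pearson
correlation of the shared modules' z-scores; the regression slope is
reported alongside because R^2 alone cannot distinguish concordant from
anti-concordant activation.  For a compound profiled under several
dose/time conditions, each module keeps its maximum activation score over
conditions, and the compound is flagged high-risk when the target injury
module (e.g. fibrosis) is significant in that maximized table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ActivationResult

__all__ = [
    "RankedCondition",
    "CrossConditionCorrelation",
    "RiskCall",
    "rank_modules",
    "correlate_conditions",
    "max_over_conditions",
    "classify_risk",
]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class RankedCondition:
    """Modules of one condition ordered from most to least activated.

    ``table`` columns: set_name, score, p_perm, z, p_fisher, n_measured,
    rank (1..K), significant (p_perm < alpha).
    """

    condition_id: str
    table: pd.DataFrame
    alpha: float = DEFAULT_ALPHA


@dataclass(frozen=True)
class CrossConditionCorrelation:
    condition_a: str
    condition_b: str
    n_shared: int
    r_squared: float | None
    slope: float | None


@dataclass(frozen=True)
class RiskCall:
    compound_id: str
    target_module: str
    max_score_condition: str | None
    max_z: float
    p_perm: float
    significant: bool
    call: str  # "high_risk" | "low_risk"


def rank_modules(
    results: Sequence[ActivationResult],
    alpha: float = DEFAULT_ALPHA,
    condition_id: str | None = None,
) -> RankedCondition:
    """Rank by descending z; ties broken by ascending p_perm, then name.

    Unmeasured (NaN-scored) modules sink to the bottom and are never
    significant.
    """
    if not results:
        raise ValueError("no results to rank")
    names = [r.set_name for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names in results")
    if condition_id is None:
        conds = {r.condition_id for r in results if r.condition_id is not None}
        condition_id = conds.pop() if len(conds) == 1 else "condition"
    df = pd.DataFrame(
        {
            "set_name": names,
            "score": [r.score for r in results],
            "p_perm": [r.p_perm for r in results],
            "z": [r.z for r in results],
            "p_fisher": [r.p_fisher for r in results],
            "n_measured": [r.n_measured for r in results],
            "flag": [r.flag for r in results],
        }
    )
    df = df.sort_values(
        by=["z", "p_perm", "set_name"],
        ascending=[False, True, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["significant"] = (df["p_perm"] < alpha) & df["z"].notna()
    return RankedCondition(condition_id=condition_id, table=df, alpha=alpha)


def correlate_conditions(a: RankedCondition, b: RankedCondition) -> CrossConditionCorrelation:
    """Squared Pearson correlation of z-scores over shared modules.

    Requires >=3 shared module names; a constant z-vector on either side
    makes the correlation undefined and it is reported absent.  The slope
    is the least-squares fit of b's z on a's z.
    """
    za = a.table.set_index("set_name")["z"]
    zb = b.table.set_index("set_name")["z"]
    shared = sorted(set(za.index) & set(zb.index))
    shared = [s for s in shared if np.isfinite(za[s]) and np.isfinite(zb[s])]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared modules, got {len(shared)}")
    x, y = za[shared].to_numpy(), zb[shared].to_numpy()
    r2 = slope = None
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        fit = stats.linregress(x, y)
        r2, slope = float(fit.rvalue**2), float(fit.slope)
    return CrossConditionCorrelation(
        condition_a=a.condition_id, condition_b=b.condition_id,
        n_shared=len(shared), r_squared=r2, slope=slope,
    )


def max_over_conditions(
    per_condition: Mapping[str, Sequence[ActivationResult]],
) -> list[ActivationResult]:
    """Per module, keep the condition with the maximum activation score.

    Every condition must have scored the same module collection.  The
    winning row is returned whole — its z and p belong to the same
    condition as the maximal score — with the provenance condition
    recorded on the result.  Ties go to the lexicographically first
    condition for determinism.
    """
    if not per_condition:
        raise ValueError("no conditions given")
    name_sets = {cond: {r.set_name for r in results}
                 for cond, results in per_condition.items()}
    reference = next(iter(name_sets.values()))
    for cond, names in name_sets.items():
        if names != reference:
            raise ValueError(
                f"condition {cond!r} scored a different module set "
                f"(symmetric difference: {sorted(names ^ reference)[:5]})"
            )
    maxed = []
    for name in sorted(reference):
        best = None
        for cond in sorted(per_condition):
            row = next(r for r in per_condition[cond] if r.set_name == name)
            score = row.score if np.isfinite(row.score) else -np.inf
            if best is None or score > (best.score if np.isfinite(best.score) else -np.inf):
                best = replace(row, condition_id=cond)
        maxed.append(best)
    return maxed


def classify_risk(
    maxed: Sequence[ActivationResult],
    target_module: str,
    alpha: float = DEFAULT_ALPHA,
    compound_id: str = "compound",
) -> RiskCall:
    """High-risk call when the target injury module is significant.

    Operates on the condition-maximized table: the compound is high-risk
    iff the target module's permutation p-value beats alpha there.
    """
    try:
        row = next(r for r in maxed if r.set_name == target_module)
    except StopIteration:
        raise KeyError(f"target module {target_module!r} not in results") from None
    significant = bool(row.p_perm < alpha)
    return RiskCall(
        compound_id=compound_id,
        target_module=target_module,
        max_score_condition=row.condition_id,
        max_z=row.z,
        p_perm=row.p_perm,
        significant=significant,
        call="high_risk" if significant else "low_risk",
    )
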