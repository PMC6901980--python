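"""Per-gene differential-expression statistics.

The fold change of a gene is the difference of mean log-transformed
expression between the treatment and control cohorts of one condition
(a natural-log fold change when the input is ln-scale).  Significance per
gene is a pooled-variance two-sample Student's t-test; genome-wide FDR
control is Benjamini-Hochberg.  A gene is called differentially expressed
when q <= 0.05 and |beta| >= 0.41, the natural-log bound corresponding to a
1.5-fold change (ln 1.5 = 0.405, printed as 0.41).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = [
    "DEFAULT_Q_MAX",
    "DEFAULT_BETA_MIN",
    "OverlapSummary",
    "compute_fold_changes",
    "call_degs",
    "deg_overlap",
]

log = logging.getLogger(__name__)

DEFAULT_Q_MAX = 0.05
#: natural-log effect-size bound for a 1.5-fold change, two decimals
DEFAULT_BETA_MIN = 0.41

#: smallest representable positive p, assigned to zero-variance unequal-mean genes
TINY_P = np.nextafter(0.0, 1.0)


def compute_fold_changes(matrix: ExpressionMatrix, condition: str) -> pd.DataFrame:
    """Fold change and t-test per gene for one condition.

    Returns a DataFrame indexed by gene with columns:

    ``fc``
        mean(treatment) - mean(control) on the log scale.
    ``t``
        pooled-variance Student's t statistic.
    ``p``
        two-sided t-test p-value in (0, 1].

    Genes with zero variance in both cohorts get t = 0, p = 1 when the
    means agree and p = smallest positive float (with a warning) when they
    differ, so degenerate genes never crash the permutation machinery
    downstream.
    """
    trt = matrix.cohort_values(condition, "treatment").to_numpy()
    ctl = matrix.cohort_values(condition, "control").to_numpy()
    n1, n0 = trt.shape[1], ctl.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"condition {condition!r} needs >=2 samples per cohort, "
            f"got {n1} treatment / {n0} control"
        )

    fc = trt.mean(axis=1) - ctl.mean(axis=1)
    v1 = trt.var(axis=1, ddof=1)
    v0 = ctl.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(trt, ctl, axis=1, equal_var=True)

    degenerate = pooled == 0.0
    if degenerate.any():
        equal = degenerate & (fc == 0.0)
        unequal = degenerate & (fc != 0.0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        if unequal.any():
            log.warning(
                "%d gene(s) have zero within-cohort variance but unequal means; "
                "p set to smallest positive float", int(unequal.sum()),
            )
            t = np.where(unequal, np.sign(fc) * np.inf, t)
            p = np.where(unequal, TINY_P, p)

    return pd.DataFrame(
        {"fc": fc, "t": t, "p": np.clip(p, TINY_P, 1.0)},
        index=pd.Index(matrix.genes, name="gene"),
    )


def call_degs(
    fct: pd.DataFrame,
    q_max: float = DEFAULT_Q_MAX,
    beta_min: float = DEFAULT_BETA_MIN,
) -> pd.DataFrame:
    """Flag differentially expressed genes.

    Adds Benjamini-Hochberg ``q`` over all genes in ``fct`` and the effect
    size ``beta`` (the fold change on the natural-log scale), then flags
    ``is_deg`` = (q <= q_max) & (|beta| >= beta_min).  Every gene is
    returned with its flag, not only the DEGs.
    """
    if fct.empty:
        raise ValueError("fold-change table is empty")
    if not 0.0 <= q_max <= 1.0:
        raise ValueError(f"q_max must be in [0, 1], got {q_max}")
    if beta_min < 0.0:
        raise ValueError(f"beta_min must be >= 0, got {beta_min}")
    q = multipletests(fct["p"].to_numpy(), method="fdr_bh")[1]
    out = fct.copy()
    out["beta"] = out["fc"]
    out["q"] = q
    out["is_deg"] = (q <= q_max) & (out["beta"].abs() >= beta_min)
    return out


@dataclass(frozen=True)
class OverlapSummary:
    """DEG overlap between two conditions, with fold-change concordance.

    ``r_squared`` is the squared Pearson correlation of fold changes over
    the shared DEGs, None when fewer than 3 genes are shared (or either
    fold-change vector is constant); ``slope`` carries the sign that R^2
    discards.
    """

    n_intersection: int
    n_a_only: int
    n_b_only: int
    r_squared: float | None
    slope: float | None


def deg_overlap(a: pd.DataFrame, b: pd.DataFrame) -> OverlapSummary:
    """Compare the DEG calls of two conditions over a shared gene universe."""
    degs_a = set(a.index[a["is_deg"]])
    degs_b = set(b.index[b["is_deg"]])
    shared = sorted(degs_a & degs_b)
    r2 = slope = None
    if len(shared) >= 3:
        x = a.loc[shared, "fc"].to_numpy()
        y = b.loc[shared, "fc"].to_numpy()
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            fit = stats.linregress(x, y)
            r2 = float(fit.rvalue**2)
            slope = float(fit.slope)
    return OverlapSummary(
        n_intersection=len(shared),
        n_a_only=len(degs_a - degs_b),
        n_b_only=len(degs_b - degs_a),
        r_squared=r2,
        slope=slope,
    )
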