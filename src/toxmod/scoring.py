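"""Gene-set scoring: signed AFC pathway scores and absolute AAFC module
activation scores with random-gene-set permutation nulls.

Two statistics over the per-gene log fold changes of one condition:

* **AFC** (aggregated fold change) — the signed sum of fold changes over a
  set's measured genes.  Its sign is the direction of regulation; its
  one-sided permutation p-value asks whether random same-size gene sets
  score as extreme in the observed direction.  Up- and down-shifts cancel,
  which is exactly the statistic's blind spot.

* **AAFC** (aggregate absolute fold change) — the mean of |fold change|
  over the set's measured genes.  Because it aggregates magnitudes it
  detects modules whose genes move in mixed directions.  Each set gets a
  permutation p-value, a z-score (standard deviations separating the
  observed score from the null mean), and a Fisher's-method combined
  p-value over the set's per-gene t-test p-values as a robustness
  indicator.

The null distribution draws gene subsets of the same size uniformly
without replacement from the measured universe — by default 10,000 draws,
or exhaustive enumeration of all C(N, k) subsets on small instances.
Internally both statistics are computed per-gene-averaged, so z-scores and
permutation p-values are identical whether scores are reported as sums or
means (set size is fixed in the null); ``aggregate="sum"`` only rescales
the reported score.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, GeneSetCollection

__all__ = [
    "NullEngine",
    "PathwayResult",
    "ActivationResult",
    "fisher_combined",
    "afc_score",
    "aafc_score",
    "score_collection",
    "results_to_frame",
]

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_MIN_COVERAGE = 0.5

#: chunk cap on permutation-index matrices, elements
_CHUNK_ELEMENTS = 20_000_000


@dataclass(frozen=True)
class NullEngine:
    """Configuration of the random-gene-set null.

    ``montecarlo`` draws ``n_perm`` subsets without replacement;
    ``exhaustive`` enumerates every C(N, k) subset (only allowed while the
    count stays below ``exhaustive_cap``).
    """

    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    mode: Literal["montecarlo", "exhaustive"] = "montecarlo"
    exhaustive_cap: int = 500_000

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.mode not in ("montecarlo", "exhaustive"):
            raise ValueError(f"unknown null mode {self.mode!r}")


@dataclass(frozen=True)
class PathwayResult:
    """Signed AFC score for one gene set.

    ``z`` locates the observed signed score in the permutation null (it is
    near 0 when up- and down-shifts cancel, which is what the absolute-value
    statistic is for).
    """

    set_name: str
    score: float
    direction: Literal["up", "down", "none"]
    p_perm: float
    p_plain: float
    z: float
    n_measured: int
    n_set: int
    degenerate: bool = False
    flag: str = ""
    condition_id: str | None = None

    @property
    def coverage(self) -> float:
        return self.n_measured / self.n_set


@dataclass(frozen=True)
class ActivationResult:
    """Absolute-value AAFC activation score for one gene set."""

    set_name: str
    score: float
    p_perm: float
    p_plain: float
    z: float
    p_fisher: float
    n_measured: int
    n_set: int
    degenerate: bool = False
    flag: str = ""
    condition_id: str | None = None

    @property
    def coverage(self) -> float:
        return self.n_measured / self.n_set


def fisher_combined(pvals: Sequence[float]) -> float:
    """Combine independent p-values by Fisher's method.

    X = -2 * sum(ln p_i) is referred to a chi-square distribution with 2k
    degrees of freedom; the upper-tail probability is returned.  A p of
    exactly 0 is clamped to the smallest positive float with a warning;
    values outside (0, 1] otherwise raise.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combined needs at least one p-value")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        log.warning("clamping %d zero p-value(s) for Fisher's method", int((p == 0).sum()))
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    x = -2.0 * np.log(p).sum()
    # survival function can underflow to 0; keep the result in (0, 1]
    return float(max(stats.chi2.sf(x, df=2 * p.size), np.nextafter(0.0, 1.0)))


def _measured_genes(fct: pd.DataFrame, gs: GeneSet, min_coverage: float) -> tuple[list[str], str]:
    """Set genes present in the fold-change table, plus a coverage flag."""
    index = fct.index
    measured = [g for g in gs.genes if g in index]
    if not measured:
        raise ValueError(f"gene set {gs.name!r} shares no genes with the matrix")
    if len(measured) == len(index):
        raise ValueError(
            f"gene set {gs.name!r} covers the whole measured universe; "
            "the random-subset null is degenerate"
        )
    flag = ""
    coverage = len(measured) / len(gs)
    if min_coverage <= 0:
        raise ValueError("min_coverage must be > 0")
    if coverage < min_coverage:
        flag = "low_coverage"
        log.warning(
            "gene set %s: only %d/%d genes measured (coverage %.2f < %.2f)",
            gs.name, len(measured), len(gs), coverage, min_coverage,
        )
    return measured, flag


def _null_means(values: np.ndarray, k: int, null: NullEngine,
                rng: np.random.Generator | None) -> np.ndarray:
    """Null distribution of the mean of ``values`` over size-k gene subsets.

    Subsets are drawn without replacement from the measured universe
    (Monte Carlo) or enumerated exhaustively.
    """
    n = values.size
    if null.mode == "exhaustive":
        total = math.comb(n, k)
        if total > null.exhaustive_cap:
            raise ValueError(
                f"exhaustive null needs {total} subsets, above cap {null.exhaustive_cap}"
            )
        out = np.empty(total)
        for i, idx in enumerate(combinations(range(n), k)):
            out[i] = values[list(idx)].mean()
        return out
    if rng is None:
        rng = np.random.default_rng(null.seed)
    out = np.empty(null.n_perm)
    # rank k smallest random keys per row -> uniform subset without replacement
    rows_per_chunk = max(1, _CHUNK_ELEMENTS // n)
    start = 0
    while start < null.n_perm:
        stop = min(start + rows_per_chunk, null.n_perm)
        keys = rng.random((stop - start, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[start:stop] = values[idx].mean(axis=1)
        start = stop
    return out


def _perm_pvalues(null_stats: np.ndarray, observed: float, upper: bool) -> tuple[float, float]:
    """(add-one corrected, plain proportion) one-sided permutation p-values.

    Null values exactly equal to the observed statistic count as
    as-or-more extreme.
    """
    if upper:
        hits = int((null_stats >= observed).sum())
    else:
        hits = int((null_stats <= observed).sum())
    n = null_stats.size
    return (1 + hits) / (n + 1), hits / n


def afc_score(
    fct: pd.DataFrame,
    gs: GeneSet,
    null: NullEngine,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    rng: np.random.Generator | None = None,
    aggregate: Literal["sum", "mean"] = "sum",
) -> PathwayResult:
    """Signed pathway score: total fold change over the set's measured genes.

    The permutation p-value is one-sided in the direction of the observed
    sign (upper tail when the score is >= 0), with add-one correction; the
    plain proportion is reported alongside for exhaustive-null work.
    """
    measured, flag = _measured_genes(fct, gs, min_coverage)
    fc = fct["fc"].to_numpy()
    mean_obs = float(fct.loc[measured, "fc"].mean())
    k = len(measured)
    null_stats = _null_means(fc, k, null, rng)
    p_perm, p_plain = _perm_pvalues(null_stats, mean_obs, upper=mean_obs >= 0)
    null_sd = float(null_stats.std(ddof=1)) if null_stats.size > 1 else 0.0
    degenerate = null_sd == 0.0
    if degenerate:
        z, p_perm = 0.0, 1.0
    else:
        z = (mean_obs - float(null_stats.mean())) / null_sd
    score = mean_obs * k if aggregate == "sum" else mean_obs
    direction = "none" if score == 0 else ("up" if score > 0 else "down")
    return PathwayResult(
        set_name=gs.name, score=score, direction=direction,
        p_perm=p_perm, p_plain=p_plain, z=float(z),
        n_measured=k, n_set=len(gs), degenerate=degenerate, flag=flag,
    )


def aafc_score(
    fct: pd.DataFrame,
    gs: GeneSet,
    null: NullEngine,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    rng: np.random.Generator | None = None,
    aggregate: Literal["mean", "sum"] = "mean",
) -> ActivationResult:
    """Module activation score: aggregate |fold change| over measured genes.

    The null is the same statistic on random same-size gene subsets; the
    z-score is (observed - null mean) / null sd.  A zero-spread null is
    flagged degenerate with z = 0 and p_perm = 1.  The Fisher combined
    p-value pools the set's per-gene t-test p-values.
    """
    measured, flag = _measured_genes(fct, gs, min_coverage)
    absfc = fct["fc"].abs().to_numpy()
    mean_obs = float(fct.loc[measured, "fc"].abs().mean())
    k = len(measured)
    null_stats = _null_means(absfc, k, null, rng)
    p_perm, p_plain = _perm_pvalues(null_stats, mean_obs, upper=True)
    null_sd = float(null_stats.std(ddof=1)) if null_stats.size > 1 else 0.0
    degenerate = null_sd == 0.0
    if degenerate:
        z, p_perm = 0.0, 1.0
    else:
        z = (mean_obs - float(null_stats.mean())) / null_sd
    p_fisher = fisher_combined(fct.loc[measured, "p"].to_numpy())
    score = mean_obs * k if aggregate == "sum" else mean_obs
    return ActivationResult(
        set_name=gs.name, score=score, p_perm=p_perm, p_plain=p_plain,
        z=float(z), p_fisher=p_fisher,
        n_measured=k, n_set=len(gs), degenerate=degenerate, flag=flag,
    )


def _set_rng(base_seed: int, set_name: str) -> np.random.Generator:
    """Deterministic per-set stream keyed by (root seed, set name).

    Keying by name (CRC32, stable across runs and platforms) makes each
    set's result invariant to the collection's ordering.
    """
    return np.random.default_rng(
        np.random.SeedSequence([base_seed, zlib.crc32(set_name.encode("utf-8"))])
    )


def score_collection(
    fct: pd.DataFrame,
    gsc: GeneSetCollection,
    statistic: Literal["afc", "aafc"],
    null: NullEngine,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    condition_id: str | None = None,
) -> list[PathwayResult] | list[ActivationResult]:
    """Score every set in a collection with independent per-set sub-seeds.

    Sets sharing no gene with the matrix produce a flagged NaN row rather
    than a silent drop (or a crash that would lose the other sets).
    """
    if len(gsc) == 0:
        raise ValueError("empty gene set collection")
    results = []
    for gs in gsc:
        rng = _set_rng(null.seed, gs.name)
        try:
            if statistic == "afc":
                res = afc_score(fct, gs, null, min_coverage, rng)
            elif statistic == "aafc":
                res = aafc_score(fct, gs, null, min_coverage, rng)
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
        except ValueError as exc:
            if "shares no genes" not in str(exc):
                raise
            log.warning("gene set %s not measured; emitting flagged row", gs.name)
            if statistic == "afc":
                res = PathwayResult(gs.name, float("nan"), "none", 1.0, 1.0,
                                    float("nan"), 0, len(gs), degenerate=True,
                                    flag="not_measured")
            else:
                res = ActivationResult(gs.name, float("nan"), 1.0, 1.0,
                                       float("nan"), 1.0, 0, len(gs),
                                       degenerate=True, flag="not_measured")
        results.append(replace(res, condition_id=condition_id))
    return results


def results_to_frame(results: Sequence[PathwayResult | ActivationResult]) -> pd.DataFrame:
    """Tabulate results, one row per gene set."""
    rows = []
    for r in results:
        row = {"set_name": r.set_name, "n_measured": r.n_measured,
               "n_set": r.n_set, "score": r.score}
        if isinstance(r, PathwayResult):
            row["direction"] = r.direction
        row["p_perm"] = r.p_perm
        row["z"] = r.z
        if isinstance(r, ActivationResult):
            row["p_fisher"] = r.p_fisher
        row["degenerate"] = r.degenerate
        row["flag"] = r.flag
        if r.condition_id is not None:
            row["condition_id"] = r.condition_id
        rows.append(row)
    return pd.DataFrame(rows)
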