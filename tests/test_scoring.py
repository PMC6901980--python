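"""AFC/AAFC gene-set statistics against independent enumeration oracles."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from toxmod import (GeneSet, GeneSetCollection, NullEngine, aafc_score,
                    afc_score, fisher_combined, score_collection)


def _fct(fc, p=None, genes=None):
    fc = list(fc)
    genes = genes or [f"g{i}" for i in range(1, len(fc) + 1)]
    p = p if p is not None else [0.5] * len(fc)
    return pd.DataFrame({"fc": fc, "t": 0.0, "p": p},
                        index=pd.Index(genes, name="gene"))


EXH = NullEngine(n_perm=1, seed=0, mode="exhaustive")


# ------------------------------------------------------------ Fisher's method


def test_fisher_single_p_is_identity():
    assert fisher_combined([0.37]) == pytest.approx(0.37)


def test_fisher_all_ones_is_one():
    assert fisher_combined([1.0, 1.0, 1.0]) == pytest.approx(1.0)


def test_fisher_two_nominal_p_matches_chi_square_closed_form():
    """X = -4 ln 0.05 = 11.98 on chi^2(4) -> ~0.0175."""
    combined = fisher_combined([0.05, 0.05])
    assert combined == pytest.approx(0.0175, abs=5e-4)
    # independent route: scipy's own Fisher combination
    _, p_scipy = stats.combine_pvalues([0.05, 0.05], method="fisher")
    assert combined == pytest.approx(p_scipy, rel=1e-12)


def test_fisher_rejects_bad_input():
    with pytest.raises(ValueError):
        fisher_combined([])
    with pytest.raises(ValueError):
        fisher_combined([0.5, 1.5])
    with pytest.raises(ValueError):
        fisher_combined([-0.1])


def test_fisher_zero_clamped_not_crashed():
    assert 0 < fisher_combined([0.0, 0.5]) < 1


# ------------------------------------------------------- worked-example oracle


def test_afc_worked_example_exhaustive(worked_fct, top_pair_set):
    """Universe fc {0.1..0.5}, set {0.4, 0.5}: score 0.9; of the C(5,2)=10
    subset sums only {0.4,0.5} itself reaches 0.9 -> plain p = 1/10."""
    res = afc_score(worked_fct, top_pair_set, EXH)
    assert res.score == pytest.approx(0.9)
    assert res.direction == "up"
    assert res.p_plain == pytest.approx(1 / 10)
    assert res.p_perm == pytest.approx(2 / 11)


def test_aafc_worked_example_exhaustive(worked_fct, top_pair_set):
    """Same universe: mean |fc| of the set is 0.45; z checked against an
    in-test enumeration of all 10 subset means."""
    res = aafc_score(worked_fct, top_pair_set, EXH)
    assert res.score == pytest.approx(0.45)
    assert res.p_plain == pytest.approx(1 / 10)
    null = [np.mean(pair) for pair in combinations([0.1, 0.2, 0.3, 0.4, 0.5], 2)]
    z_expected = (0.45 - np.mean(null)) / np.std(null, ddof=1)
    assert res.z == pytest.approx(z_expected, rel=1e-12)
    assert res.p_fisher == pytest.approx(fisher_combined([0.5, 0.5]))


def test_afc_cancellation_gives_direction_none():
    fct = _fct([0.5, -0.5, 0.1, -0.2])
    res = afc_score(fct, GeneSet("S", "d", ("g1", "g2")), EXH)
    assert res.score == pytest.approx(0.0)
    assert res.direction == "none"


def test_aafc_degenerate_null_flagged():
    fct = _fct([0.3, -0.3, 0.3, -0.3])
    res = aafc_score(fct, GeneSet("S", "d", ("g1", "g2")), EXH)
    assert res.score == pytest.approx(0.3)
    assert res.degenerate
    assert res.z == 0.0
    assert res.p_perm == 1.0


# ----------------------------------------------------------------- invariance


@pytest.fixture
def random_fct():
    rng = np.random.default_rng(11)
    return _fct(rng.normal(0, 0.6, 40), p=rng.uniform(0.01, 1, 40))


@pytest.fixture
def random_set():
    return GeneSet("S", "d", tuple(f"g{i}" for i in (3, 7, 12, 25, 38)))


def test_z_identical_under_sum_vs_mean_aggregation(random_fct, random_set):
    ne = NullEngine(n_perm=500, seed=4)
    a = aafc_score(random_fct, random_set, ne, aggregate="mean")
    b = aafc_score(random_fct, random_set, ne, aggregate="sum")
    assert b.score == pytest.approx(a.score * 5, rel=1e-12)
    assert b.z == a.z  # exact: set size is fixed in the null
    assert b.p_perm == a.p_perm


def test_z_and_p_invariant_under_log_base_rescaling(random_fct, random_set):
    """Multiplying every fold change by 1/ln 2 (ln -> log2) leaves z and the
    permutation p-value unchanged."""
    ne = NullEngine(n_perm=500, seed=4)
    a = aafc_score(random_fct, random_set, ne)
    scaled = random_fct.copy()
    scaled["fc"] = scaled["fc"] / math.log(2)
    b = aafc_score(scaled, random_set, ne)
    assert b.p_perm == a.p_perm
    assert b.p_plain == a.p_plain
    assert b.z == pytest.approx(a.z, rel=1e-9)
    c = afc_score(scaled, random_set, ne)
    d = afc_score(random_fct, random_set, ne)
    assert c.p_perm == d.p_perm
    assert c.direction == d.direction


@settings(max_examples=40, deadline=None, derandomize=True)
@given(signs=st.lists(st.sampled_from([-1.0, 1.0]), min_size=8, max_size=8))
def test_aafc_invariant_to_sign_pattern(signs):
    """Flipping any subset of fold-change signs inside the set leaves the
    AAFC score and z unchanged; the signed AFC score does move."""
    base = [0.5, 0.4, 0.3, 0.6, 0.2, 0.1, 0.45, 0.35]
    flipped = [s * v for s, v in zip(signs, base)]
    gs = GeneSet("S", "d", ("g1", "g2", "g3"))
    ne = NullEngine(n_perm=200, seed=7)
    a = aafc_score(_fct(base), gs, ne)
    b = aafc_score(_fct(flipped), gs, ne)
    assert b.score == a.score
    assert b.z == a.z
    assert b.p_perm == a.p_perm


def test_afc_not_invariant_to_sign_pattern():
    gs = GeneSet("S", "d", ("g1", "g2"))
    a = afc_score(_fct([0.5, 0.4, 0.1, 0.2]), gs, EXH)
    b = afc_score(_fct([0.5, -0.4, 0.1, 0.2]), gs, EXH)
    assert a.score != b.score


# ------------------------------------------------- Monte Carlo vs exhaustive


@pytest.mark.parametrize("statistic", ["afc", "aafc"])
def test_montecarlo_matches_exhaustive_within_3_se(statistic):
    """On a 12-gene universe with a 3-gene set, the Monte-Carlo plain
    proportion sits within 3 binomial standard errors of the exact
    exhaustive p (C(12,3) = 220 subsets)."""
    rng = np.random.default_rng(2)
    fct = _fct(rng.normal(0.1, 0.5, 12))
    gs = GeneSet("S", "d", ("g2", "g5", "g11"))
    fn = afc_score if statistic == "afc" else aafc_score
    exact = fn(fct, gs, EXH).p_plain
    n_perm = 20_000
    mc = fn(fct, gs, NullEngine(n_perm=n_perm, seed=3)).p_plain
    se = math.sqrt(exact * (1 - exact) / n_perm)
    assert abs(mc - exact) <= 3 * se + 1e-12


# ------------------------------------------------------------ degenerate input


def test_empty_intersection_is_an_error(worked_fct):
    with pytest.raises(ValueError, match="shares no genes"):
        aafc_score(worked_fct, GeneSet("S", "d", ("zz",)), EXH)


def test_whole_universe_set_is_an_error(worked_fct):
    gs = GeneSet("ALL", "d", tuple(worked_fct.index))
    with pytest.raises(ValueError, match="degenerate"):
        aafc_score(worked_fct, gs, EXH)


def test_low_coverage_flagged_not_dropped(worked_fct):
    gs = GeneSet("S", "d", ("g4", "g5", "zz1", "zz2", "zz3"))
    res = aafc_score(worked_fct, gs, EXH)
    assert res.flag == "low_coverage"
    assert res.n_measured == 2 and res.n_set == 5
    assert res.score == pytest.approx(0.45)


# ------------------------------------------------------------- collections


@pytest.fixture
def sim_universe_fct():
    rng = np.random.default_rng(5)
    return _fct(rng.normal(0, 0.5, 60), p=rng.uniform(0.001, 1, 60))


def _collection(names_and_genes):
    return GeneSetCollection(
        sets=tuple(GeneSet(n, "d", tuple(g)) for n, g in names_and_genes)
    )


def test_score_collection_one_row_per_set_and_deterministic(sim_universe_fct):
    gsc = _collection([("A", ["g1", "g2", "g3"]), ("B", ["g10", "g20"]),
                       ("C", ["g30", "g31", "g32", "g33"])])
    ne = NullEngine(n_perm=300, seed=9)
    r1 = score_collection(sim_universe_fct, gsc, "aafc", ne)
    r2 = score_collection(sim_universe_fct, gsc, "aafc", ne)
    assert len(r1) == 3
    assert [(r.p_perm, r.z) for r in r1] == [(r.p_perm, r.z) for r in r2]


def test_score_collection_order_invariant(sim_universe_fct):
    """Per-set sub-seeds are keyed by set name, so shuffling the collection
    cannot change any set's p or z."""
    sets = [("A", ["g1", "g2", "g3"]), ("B", ["g10", "g20"]), ("C", ["g30", "g31"])]
    ne = NullEngine(n_perm=300, seed=9)
    fwd = score_collection(sim_universe_fct, _collection(sets), "aafc", ne)
    rev = score_collection(sim_universe_fct, _collection(sets[::-1]), "aafc", ne)
    by_name_fwd = {r.set_name: (r.p_perm, r.z) for r in fwd}
    by_name_rev = {r.set_name: (r.p_perm, r.z) for r in rev}
    assert by_name_fwd == by_name_rev


def test_score_collection_unmeasured_set_flagged(sim_universe_fct):
    gsc = _collection([("A", ["g1", "g2"]), ("GONE", ["zz1", "zz2"])])
    results = score_collection(sim_universe_fct, gsc, "aafc",
                               NullEngine(n_perm=100, seed=0))
    gone = next(r for r in results if r.set_name == "GONE")
    assert gone.flag == "not_measured"
    assert math.isnan(gone.score)


def test_score_collection_empty_error(sim_universe_fct):
    with pytest.raises(ValueError, match="empty"):
        score_collection(sim_universe_fct, GeneSetCollection(sets=()), "aafc",
                         NullEngine(n_perm=10, seed=0))


def test_permutation_p_never_zero(sim_universe_fct):
    """Add-one correction keeps p_perm in (0, 1] even for extreme scores."""
    fct = sim_universe_fct.copy()
    fct.loc[["g1", "g2", "g3"], "fc"] = 50.0
    res = aafc_score(fct, GeneSet("S", "d", ("g1", "g2", "g3")),
                     NullEngine(n_perm=500, seed=1))
    assert res.p_perm == pytest.approx(1 / 501)
    assert res.p_perm > 0
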