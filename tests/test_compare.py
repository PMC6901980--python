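"""Ranking, cross-condition concordance, max-aggregation, and risk calls."""

from __future__ import annotations

import numpy as np
import pytest

from toxmod import (ActivationResult, NullEngine, classify_risk,
                    compute_fold_changes, correlate_conditions,
                    make_planted_config, max_over_conditions, rank_modules,
                    score_collection, simulate_experiment)

LN2 = np.log(2.0)


def _res(name, z, p=0.5, score=None, cond=None):
    return ActivationResult(
        set_name=name, score=z if score is None else score, p_perm=p,
        p_plain=p, z=z, p_fisher=0.5, n_measured=10, n_set=10,
        condition_id=cond,
    )


# -------------------------------------------------------------------- ranking


def test_rank_orders_by_z_then_p_then_name():
    results = [_res("c", -1.0, 0.8), _res("b", 3.1, 0.004), _res("a", 3.1, 0.001)]
    ranked = rank_modules(results, alpha=0.01)
    assert ranked.table["set_name"].tolist() == ["a", "b", "c"]
    assert ranked.table["rank"].tolist() == [1, 2, 3]
    assert ranked.table["significant"].tolist() == [True, True, False]


def test_rank_no_significant_when_all_p_above_alpha():
    ranked = rank_modules([_res("a", 5.0, 0.02), _res("b", 1.0, 0.5)], alpha=0.01)
    assert not ranked.table["significant"].any()


def test_rank_duplicate_names_error():
    with pytest.raises(ValueError, match="duplicate"):
        rank_modules([_res("a", 1.0), _res("a", 2.0)])


def test_rank_name_breaks_exact_ties():
    results = [_res("zz", 2.0, 0.01), _res("aa", 2.0, 0.01)]
    assert rank_modules(results).table["set_name"].tolist() == ["aa", "zz"]


# ---------------------------------------------------------------- correlation


def _ranked(zs, cond):
    return rank_modules([_res(f"m{i}", z) for i, z in enumerate(zs)],
                        condition_id=cond)


def test_correlation_identity():
    a = _ranked([1.0, 2.0, 3.0, 4.0], "a")
    b = _ranked([1.0, 2.0, 3.0, 4.0], "b")
    corr = correlate_conditions(a, b)
    assert corr.r_squared == pytest.approx(1.0)
    assert corr.slope == pytest.approx(1.0)
    assert corr.n_shared == 4


def test_correlation_negation_keeps_r2_flips_slope():
    a = _ranked([1.0, 2.0, 3.0, 4.0], "a")
    b = _ranked([-1.0, -2.0, -3.0, -4.0], "b")
    corr = correlate_conditions(a, b)
    assert corr.r_squared == pytest.approx(1.0)
    assert corr.slope == pytest.approx(-1.0)


def test_correlation_matches_closed_form_pearson():
    """r = S_xy / sqrt(S_xx S_yy), computed from raw sums independently."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.1, 1.9, 3.2, 3.8])
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    r2_hand = sxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    corr = correlate_conditions(_ranked(x, "a"), _ranked(y, "b"))
    assert corr.r_squared == pytest.approx(r2_hand, rel=1e-12)


def test_correlation_symmetric_in_r2():
    a = _ranked([0.3, -1.2, 2.5, 0.7, 1.1], "a")
    b = _ranked([1.0, 0.2, 2.0, -0.5, 0.9], "b")
    assert correlate_conditions(a, b).r_squared == pytest.approx(
        correlate_conditions(b, a).r_squared, rel=1e-12
    )


def test_correlation_needs_three_shared_modules():
    with pytest.raises(ValueError, match=">=3"):
        correlate_conditions(_ranked([1.0, 2.0], "a"), _ranked([1.0, 2.0], "b"))


def test_correlation_zero_variance_reported_absent():
    corr = correlate_conditions(_ranked([1.0, 1.0, 1.0], "a"),
                                _ranked([1.0, 2.0, 3.0], "b"))
    assert corr.r_squared is None


# ------------------------------------------------------------ max aggregation


def test_max_single_condition_is_identity():
    results = [_res("a", 1.0, score=0.2), _res("b", 2.0, score=0.4)]
    maxed = max_over_conditions({"only": results})
    assert {r.set_name: r.score for r in maxed} == {"a": 0.2, "b": 0.4}
    assert all(r.condition_id == "only" for r in maxed)


def test_max_picks_row_with_maximal_score():
    per_cond = {
        "d1": [_res("m", 1.2, score=0.3)],
        "d2": [_res("m", 4.5, score=0.9)],
        "d3": [_res("m", 0.3, score=0.1)],
    }
    maxed = max_over_conditions(per_cond)
    assert len(maxed) == 1
    assert maxed[0].condition_id == "d2"
    assert maxed[0].z == 4.5  # z travels with the winning row


def test_max_score_dominates_every_condition():
    rng = np.random.default_rng(3)
    per_cond = {
        f"c{j}": [_res(f"m{i}", rng.normal(), score=float(rng.uniform()))
                  for i in range(5)]
        for j in range(9)  # 3 doses x 3 times layout
    }
    maxed = max_over_conditions(per_cond)
    assert len(maxed) == 5
    for r in maxed:
        for cond, results in per_cond.items():
            other = next(x for x in results if x.set_name == r.set_name)
            assert r.score >= other.score


def test_max_inconsistent_module_sets_error():
    with pytest.raises(ValueError, match="different module set"):
        max_over_conditions({"a": [_res("m1", 1.0)], "b": [_res("m2", 1.0)]})


# ------------------------------------------------------------------ risk call


def test_classify_missing_module_error():
    with pytest.raises(KeyError, match="fibrosis"):
        classify_risk([_res("necrosis", 1.0)], "fibrosis")


def test_alpha_zero_always_low_risk():
    call = classify_risk([_res("fibrosis", 50.0, p=1e-4)], "fibrosis", alpha=0.0)
    assert call.call == "low_risk"


def test_planted_fibrosis_is_called_high_risk():
    """A compound whose fibrosis module carries a 2-fold planted effect is
    flagged high-risk from the condition-maximized table."""
    per_cond = {}
    for cond, seed in (("low_24h", 21), ("high_24h", 22)):
        cfg, gsc = make_planted_config(
            800, [15] * 5, [LN2, 0, 0, 0, 0], seed=seed,
            names=["fibrosis", "necrosis", "infiltration", "dilation", "casts"],
            condition_id=cond,
        )
        matrix, _ = simulate_experiment(cfg)
        fct = compute_fold_changes(matrix, cond)
        per_cond[cond] = score_collection(
            fct, gsc, "aafc", NullEngine(n_perm=500, seed=seed),
            condition_id=cond,
        )
    maxed = max_over_conditions(per_cond)
    call = classify_risk(maxed, "fibrosis", alpha=0.01, compound_id="toxicant")
    assert call.call == "high_risk"
    assert call.significant


def test_null_compound_is_called_low_risk():
    cfg, gsc = make_planted_config(800, [15] * 5, [0.0] * 5, seed=30,
                                   names=["fibrosis", "a", "b", "c", "d"])
    matrix, _ = simulate_experiment(cfg)
    fct = compute_fold_changes(matrix, "sim")
    results = score_collection(fct, gsc, "aafc", NullEngine(n_perm=500, seed=30))
    call = classify_risk(max_over_conditions({"sim": results}), "fibrosis")
    assert call.call == "low_risk"
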