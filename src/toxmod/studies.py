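"""Replicated simulation studies that characterize the scoring method.

Three desk-scale studies, each a loop of independent synthetic experiments
over the generator's default study conditions (n = 5 per cohort, Gaussian
log-scale noise of sd 0.5, size-20 modules in a 2,000-gene universe):

* **null calibration** — no planted effect anywhere; checks that the
  per-gene t-test rejects at its nominal rate and that module permutation
  p-values are super-uniform with mean z near 0.
* **recovery** — one module planted at a known delta among decoys; checks
  that it ranks first by AAFC z and that, with a half-up/half-down
  direction mix, the absolute-value statistic sees what the signed one
  cancels away.
* **concordance** — two independent experiments share the same planted
  pattern (the desk-scale analogue of profiling one toxicant in vivo and
  in vitro); checks that their module z-vectors correlate with R^2 above
  0.6.

All replicate seeds are derived from one root seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import correlate_conditions, rank_modules
from .diffexp import compute_fold_changes
from .scoring import NullEngine, score_collection
from .simulate import make_planted_config, simulate_experiment

__all__ = [
    "StudyDesign",
    "null_calibration_study",
    "recovery_study",
    "concordance_study",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class StudyDesign:
    """Shared scale of the simulation studies."""

    n_genes: int = 2000
    n_modules: int = 9  # 1 planted + 8 decoys unless overridden
    module_size: int = 20
    n_per_cohort: int = 5
    noise_sd: float = 0.5
    n_perm: int = 1000


def _replicate_seeds(seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([seed, tag])
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep below 2**31


def null_calibration_study(
    seed: int,
    n_replicates: int = 200,
    design: StudyDesign = StudyDesign(n_modules=11),
) -> dict:
    """Delta = 0 everywhere: t-test and permutation-null calibration.

    Returns the pooled per-gene t-test p-values, per-module permutation
    p-values, and per-module z-scores over all replicates.
    """
    gene_p, module_p, module_z = [], [], []
    for rep_seed in _replicate_seeds(seed, n_replicates, tag=0xCA1):
        cfg, gsc = make_planted_config(
            design.n_genes, [design.module_size] * design.n_modules,
            [0.0] * design.n_modules, seed=rep_seed,
            n_per_cohort=design.n_per_cohort, noise_sd=design.noise_sd,
        )
        matrix, _ = simulate_experiment(cfg)
        fct = compute_fold_changes(matrix, cfg.condition_id)
        gene_p.append(fct["p"].to_numpy())
        results = score_collection(
            fct, gsc, "aafc", NullEngine(n_perm=design.n_perm, seed=rep_seed)
        )
        module_p += [r.p_perm for r in results]
        module_z += [r.z for r in results]
    return {
        "gene_p": np.concatenate(gene_p),
        "module_p": np.array(module_p),
        "module_z": np.array(module_z),
    }


def recovery_study(
    seed: int,
    n_replicates: int = 100,
    delta: float = LN2,
    direction_mix: float = 0.5,
    responder_fraction: float = 1.0,
    design: StudyDesign = StudyDesign(),
) -> dict:
    """One planted module among decoys: rank recovery and AAFC-vs-AFC.

    Per replicate, records whether the planted module is AAFC-rank 1, its
    AAFC z, and its signed-AFC z (near 0 when the direction mix cancels).
    """
    rank1, aafc_z, afc_z = [], [], []
    effect_sizes = [delta] + [0.0] * (design.n_modules - 1)
    for rep_seed in _replicate_seeds(seed, n_replicates, tag=0x4EC):
        cfg, gsc = make_planted_config(
            design.n_genes, [design.module_size] * design.n_modules,
            effect_sizes, seed=rep_seed,
            responder_fraction=responder_fraction, direction_mix=direction_mix,
            n_per_cohort=design.n_per_cohort, noise_sd=design.noise_sd,
        )
        planted = gsc.names[0]
        matrix, _ = simulate_experiment(cfg)
        fct = compute_fold_changes(matrix, cfg.condition_id)
        null = NullEngine(n_perm=design.n_perm, seed=rep_seed)
        act = score_collection(fct, gsc, "aafc", null)
        ranked = rank_modules(act)
        top = ranked.table.iloc[0]["set_name"]
        rank1.append(top == planted)
        aafc_z.append(next(r.z for r in act if r.set_name == planted))
        path = score_collection(fct, gsc, "afc", null)
        afc_z.append(next(r.z for r in path if r.set_name == planted))
    return {
        "rank1_fraction": float(np.mean(rank1)),
        "aafc_z": np.array(aafc_z),
        "afc_z": np.array(afc_z),
    }


def concordance_study(
    seed: int,
    n_pairs: int = 100,
    delta: float = LN2,
    direction_mix: float = 0.5,
    design: StudyDesign = StudyDesign(),
) -> dict:
    """Paired independent experiments with the same planted pattern.

    Each pair shares the module collection and planted pattern but has
    independent noise and cohorts (the in vivo / in vitro analogue); the
    squared Pearson correlation of module z-vectors is recorded per pair.
    """
    r_squared = []
    effect_sizes = [delta] + [0.0] * (design.n_modules - 1)
    for rep_seed in _replicate_seeds(seed, n_pairs, tag=0xC04):
        cfg_a, gsc = make_planted_config(
            design.n_genes, [design.module_size] * design.n_modules,
            effect_sizes, seed=rep_seed, direction_mix=direction_mix,
            n_per_cohort=design.n_per_cohort, noise_sd=design.noise_sd,
            condition_id="in_vivo",
        )
        # same universe/pattern, independent cohorts: different noise seed
        cfg_b = type(cfg_a)(
            n_genes=cfg_a.n_genes, modules=cfg_a.modules,
            n_per_cohort=cfg_a.n_per_cohort, baseline_mean=cfg_a.baseline_mean,
            noise_sd=cfg_a.noise_sd, seed=rep_seed + 1_000_003,
            condition_id="in_vitro",
        )
        ranked = {}
        for cfg in (cfg_a, cfg_b):
            matrix, _ = simulate_experiment(cfg)
            fct = compute_fold_changes(matrix, cfg.condition_id)
            results = score_collection(
                fct, gsc, "aafc",
                NullEngine(n_perm=design.n_perm, seed=cfg.seed),
                condition_id=cfg.condition_id,
            )
            ranked[cfg.condition_id] = rank_modules(results)
        corr = correlate_conditions(ranked["in_vivo"], ranked["in_vitro"])
        r_squared.append(corr.r_squared if corr.r_squared is not None else 0.0)
    r_squared = np.array(r_squared)
    return {
        "r_squared": r_squared,
        "fraction_above_0.6": float(np.mean(r_squared >= 0.6)),
    }
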