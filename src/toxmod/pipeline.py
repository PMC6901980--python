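"""End-to-end pipeline: simulate or load, fold changes, DEGs, scores, ranking.

A run is described by one YAML/JSON config with a single root seed; every
random sub-stream (simulation, per-set permutation nulls) is derived from
it deterministically, so rerunning a config reproduces every output table
byte for byte.  Outputs are plain TSV/JSON plus a manifest echoing the
config, seed, library versions, and per-stage row counts.
"""

from __future__ import annotations

import difflib
import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import DEFAULT_ALPHA, rank_modules
from .diffexp import DEFAULT_BETA_MIN, DEFAULT_Q_MAX, call_degs, compute_fold_changes
from .io import (ExpressionMatrix, GeneSetCollection, read_expression, read_gmt,
                 write_expression, write_gmt, write_json)
from .scoring import (DEFAULT_MIN_COVERAGE, DEFAULT_N_PERM, NullEngine,
                      results_to_frame, score_collection)
from .simulate import (DEFAULT_BASELINE_MEAN, DEFAULT_N_PER_COHORT,
                       DEFAULT_NOISE_SD, PlantedModule, SimulationConfig,
                       generate_universe, simulate_experiment)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed", "n_perm", "alpha", "q_max", "beta_min", "statistic",
    "min_coverage", "output_dir", "simulate", "inputs",
}
_SIM_KEYS = {
    "n_genes", "n_per_cohort", "baseline_mean", "noise_sd", "condition_id",
    "modules",
}
_MODULE_KEYS = {"name", "size", "effect_size", "responder_fraction", "direction_mix"}
_INPUT_KEYS = {"matrix", "metadata", "gmt", "condition", "log_transform"}


class ConfigError(ValueError):
    """All schema violations of a run config, enumerated."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid run config:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class SimulateSpec:
    n_genes: int
    modules: tuple[dict, ...]
    n_per_cohort: int = DEFAULT_N_PER_COHORT
    baseline_mean: float = DEFAULT_BASELINE_MEAN
    noise_sd: float = DEFAULT_NOISE_SD
    condition_id: str = "sim"


@dataclass(frozen=True)
class InputSpec:
    matrix: str
    metadata: str
    gmt: str
    condition: str
    log_transform: str = "none"


@dataclass(frozen=True)
class RunConfig:
    """A fully-defaulted, validated pipeline run."""

    output_dir: str
    seed: int = 0
    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    q_max: float = DEFAULT_Q_MAX
    beta_min: float = DEFAULT_BETA_MIN
    statistic: str = "aafc"
    min_coverage: float = DEFAULT_MIN_COVERAGE
    simulate: SimulateSpec | None = None
    inputs: InputSpec | None = None


def _unknown_key_msgs(given: dict, allowed: set[str], where: str) -> list[str]:
    msgs = []
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f'; did you mean "{hint[0]}"?' if hint else ""
            msgs.append(f"{where}: unknown key {key!r}{suffix}")
    return msgs


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config, enumerating every problem."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])

    problems = _unknown_key_msgs(raw, _TOP_KEYS, str(path))

    def check(cond: bool, msg: str) -> None:
        if not cond:
            problems.append(msg)

    seed = raw.get("seed", 0)
    n_perm = raw.get("n_perm", DEFAULT_N_PERM)
    alpha = raw.get("alpha", DEFAULT_ALPHA)
    q_max = raw.get("q_max", DEFAULT_Q_MAX)
    beta_min = raw.get("beta_min", DEFAULT_BETA_MIN)
    statistic = raw.get("statistic", "aafc")
    min_coverage = raw.get("min_coverage", DEFAULT_MIN_COVERAGE)
    output_dir = raw.get("output_dir")

    check(isinstance(seed, int), f"seed must be an integer, got {seed!r}")
    check(isinstance(n_perm, int) and n_perm >= 1, f"n_perm must be >= 1, got {n_perm!r}")
    check(isinstance(alpha, (int, float)) and 0 < alpha <= 1, f"alpha must be in (0, 1], got {alpha!r}")
    check(isinstance(q_max, (int, float)) and 0 <= q_max <= 1, f"q_max must be in [0, 1], got {q_max!r}")
    check(isinstance(beta_min, (int, float)) and beta_min >= 0, f"beta_min must be >= 0, got {beta_min!r}")
    check(statistic in ("afc", "aafc"), f"statistic must be 'afc' or 'aafc', got {statistic!r}")
    check(isinstance(min_coverage, (int, float)) and 0 < min_coverage <= 1,
          f"min_coverage must be in (0, 1], got {min_coverage!r}")
    check(output_dir is not None, "output_dir is required")

    sim_raw, in_raw = raw.get("simulate"), raw.get("inputs")
    check(
        (sim_raw is None) != (in_raw is None),
        "exactly one of 'simulate' or 'inputs' must be given",
    )

    simulate = inputs = None
    if sim_raw is not None:
        if not isinstance(sim_raw, dict):
            problems.append("simulate: must be a mapping")
        else:
            problems += _unknown_key_msgs(sim_raw, _SIM_KEYS, "simulate")
            mods = sim_raw.get("modules", [])
            if not isinstance(mods, list) or not mods:
                problems.append("simulate.modules: a non-empty list is required")
                mods = []
            for i, m in enumerate(mods):
                if not isinstance(m, dict):
                    problems.append(f"simulate.modules[{i}]: must be a mapping")
                    continue
                problems += _unknown_key_msgs(m, _MODULE_KEYS, f"simulate.modules[{i}]")
                for req in ("size", "effect_size"):
                    if req not in m:
                        problems.append(f"simulate.modules[{i}]: missing {req!r}")
            if "n_genes" not in sim_raw:
                problems.append("simulate: missing 'n_genes'")
            elif not problems:
                simulate = SimulateSpec(
                    n_genes=sim_raw["n_genes"],
                    modules=tuple(mods),
                    n_per_cohort=sim_raw.get("n_per_cohort", DEFAULT_N_PER_COHORT),
                    baseline_mean=sim_raw.get("baseline_mean", DEFAULT_BASELINE_MEAN),
                    noise_sd=sim_raw.get("noise_sd", DEFAULT_NOISE_SD),
                    condition_id=sim_raw.get("condition_id", "sim"),
                )
    if in_raw is not None:
        if not isinstance(in_raw, dict):
            problems.append("inputs: must be a mapping")
        else:
            problems += _unknown_key_msgs(in_raw, _INPUT_KEYS, "inputs")
            missing = {"matrix", "metadata", "gmt", "condition"} - set(in_raw)
            if missing:
                problems.append(f"inputs: missing {sorted(missing)}")
            else:
                for key in ("matrix", "metadata", "gmt"):
                    if not Path(in_raw[key]).exists():
                        problems.append(f"inputs.{key}: no such file {in_raw[key]!r}")
                if not problems:
                    inputs = InputSpec(
                        matrix=in_raw["matrix"], metadata=in_raw["metadata"],
                        gmt=in_raw["gmt"], condition=in_raw["condition"],
                        log_transform=in_raw.get("log_transform", "none"),
                    )

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        output_dir=str(output_dir), seed=seed, n_perm=n_perm, alpha=alpha,
        q_max=q_max, beta_min=beta_min, statistic=statistic,
        min_coverage=min_coverage, simulate=simulate, inputs=inputs,
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False,
               index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Stages: acquire data (simulate or load) -> per-gene fold changes and
    t-tests -> DEG calls -> gene-set scores with permutation nulls ->
    within-condition ranking.  Any stage error propagates with the stage
    name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    files: list[str] = []

    def emit(df: pd.DataFrame, name: str, **kw) -> None:
        _write_tsv(df, out / name, **kw)
        files.append(name)

    stage = "acquire"
    try:
        if config.simulate is not None:
            spec = config.simulate
            sizes = [m["size"] for m in spec.modules]
            names = [m.get("name", f"M{i + 1:02d}") for i, m in enumerate(spec.modules)]
            gsc = generate_universe(spec.n_genes, sizes, seed=config.seed, names=names)
            planted = tuple(
                PlantedModule(
                    gene_set=gs,
                    effect_size=m["effect_size"],
                    responder_fraction=m.get("responder_fraction", 1.0),
                    direction_mix=m.get("direction_mix", 0.5),
                )
                for gs, m in zip(gsc, spec.modules)
            )
            sim = SimulationConfig(
                n_genes=spec.n_genes, modules=planted,
                n_per_cohort=spec.n_per_cohort, baseline_mean=spec.baseline_mean,
                noise_sd=spec.noise_sd, seed=config.seed,
                condition_id=spec.condition_id,
            )
            matrix, truth = simulate_experiment(sim)
            condition = spec.condition_id
            write_expression(matrix, out / "matrix.tsv", out / "metadata.tsv")
            files += ["matrix.tsv", "metadata.tsv"]
            write_gmt(gsc, out / "gene_sets.gmt")
            files.append("gene_sets.gmt")
            write_json(
                {"log_fc": {g: v for g, v in truth.log_fc.items() if v != 0.0},
                 "module_active": truth.module_active,
                 "module_delta": truth.module_delta},
                out / "truth.json",
            )
            files.append("truth.json")
        else:
            spec = config.inputs
            matrix = read_expression(spec.matrix, spec.metadata, spec.log_transform)
            gsc = read_gmt(spec.gmt)
            condition = spec.condition
        counts["genes"] = len(matrix.genes)
        counts["samples"] = matrix.values.shape[1]
        counts["gene_sets"] = len(gsc)
        log.info("stage %s: %d genes x %d samples, %d gene sets",
                 stage, counts["genes"], counts["samples"], counts["gene_sets"])

        stage = "fold_changes"
        fct = compute_fold_changes(matrix, condition)
        emit(fct.reset_index(), "fold_changes.tsv")
        counts["fold_change_rows"] = len(fct)
        log.info("stage %s: %d rows", stage, len(fct))

        stage = "degs"
        degs = call_degs(fct, q_max=config.q_max, beta_min=config.beta_min)
        emit(degs.reset_index(), "degs.tsv")
        counts["degs_flagged"] = int(degs["is_deg"].sum())
        log.info("stage %s: %d DEGs of %d genes", stage, counts["degs_flagged"], len(degs))

        stage = "scores"
        null = NullEngine(n_perm=config.n_perm, seed=config.seed)
        results = score_collection(
            fct, gsc, statistic=config.statistic, null=null,
            min_coverage=config.min_coverage, condition_id=condition,
        )
        emit(results_to_frame(results), "scores.tsv")
        counts["scored_sets"] = len(results)
        log.info("stage %s: %d sets scored (%s)", stage, len(results), config.statistic)

        stage = "rank"
        if config.statistic == "aafc":
            ranked = rank_modules(results, alpha=config.alpha, condition_id=condition)
            emit(ranked.table, "ranked.tsv")
            counts["significant_sets"] = int(ranked.table["significant"].sum())
            log.info("stage %s: %d significant at alpha=%g", stage,
                     counts["significant_sets"], config.alpha)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {
            "seed": config.seed, "n_perm": config.n_perm, "alpha": config.alpha,
            "q_max": config.q_max, "beta_min": config.beta_min,
            "statistic": config.statistic, "min_coverage": config.min_coverage,
            "mode": "simulate" if config.simulate is not None else "inputs",
            "condition": condition,
        },
        "versions": _versions(),
        "counts": counts,
        "files": files,
        "checksums": {f: _sha256(out / f) for f in files},
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def _versions() -> dict[str, str]:
    import numpy
    import scipy

    return {
        "toxmod": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
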