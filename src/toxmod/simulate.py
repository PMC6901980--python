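"""Synthetic replicated expression experiments with planted module activation.

The generator emulates the statistical structure the scoring pipeline
assumes: a treatment and a control cohort (default n = 5 each, the study
design the pipeline targets), i.i.d. Gaussian noise on the log-expression
scale, and gene sets ("modules") whose genes are shifted in the treatment
cohort by a known log fold change.  Each planted module controls its
effect size delta, the fraction of its genes that respond, and the
up/down split of the responders — the default half-up/half-down split is
the regime where signed aggregation cancels and only the absolute-value
statistic sees the activation.

Everything is driven by one root seed; sub-streams for truth assignment
and noise are derived deterministically, so a config reproduces its matrix
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "PlantedModule",
    "SimulationConfig",
    "SimulationTruth",
    "generate_universe",
    "simulate_experiment",
    "make_planted_config",
]

DEFAULT_N_PER_COHORT = 5
DEFAULT_NOISE_SD = 0.5
DEFAULT_BASELINE_MEAN = 5.0


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


@dataclass(frozen=True)
class PlantedModule:
    """A gene set with a planted treatment effect.

    ``effect_size`` is the mean log-FC magnitude delta applied to each
    responding gene; ``responder_fraction`` the fraction of the set's genes
    shifted; ``direction_mix`` the fraction of responders shifted up (the
    rest are shifted down).
    """

    gene_set: GeneSet
    effect_size: float
    responder_fraction: float = 1.0
    direction_mix: float = 0.5

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in (0, 1]")
        if not 0.0 <= self.direction_mix <= 1.0:
            raise ValueError("direction_mix must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated treatment/control experiment."""

    n_genes: int
    modules: tuple[PlantedModule, ...] = ()
    n_per_cohort: int = DEFAULT_N_PER_COHORT
    baseline_mean: float = DEFAULT_BASELINE_MEAN
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    condition_id: str = "sim"
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_per_cohort < 2:
            raise ValueError("n_per_cohort must be >= 2 (t-test needs variance)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        object.__setattr__(self, "modules", tuple(self.modules))
        universe = set(_gene_ids(self.n_genes))
        seen: set[str] = set()
        for pm in self.modules:
            extra = set(pm.gene_set.genes) - universe
            if extra:
                raise ValueError(
                    f"module {pm.gene_set.name!r} genes outside the "
                    f"simulated universe: {sorted(extra)[:5]}"
                )
            overlap = seen & set(pm.gene_set.genes)
            if overlap and not self.allow_overlap:
                raise ValueError(
                    f"module {pm.gene_set.name!r} overlaps earlier modules "
                    f"({sorted(overlap)[:5]}); set allow_overlap=True if intended"
                )
            seen |= set(pm.gene_set.genes)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated experiment.

    ``log_fc`` is the exact planted log fold change per gene (0 for every
    non-responder); ``module_active`` / ``module_delta`` record, per
    module, whether it carries any effect and the planted delta.
    """

    log_fc: pd.Series
    module_active: dict[str, bool]
    module_delta: dict[str, float]


def generate_universe(
    n_genes: int,
    sizes: list[int] | tuple[int, ...],
    seed: int = 0,
    names: list[str] | None = None,
) -> GeneSetCollection:
    """Draw disjoint gene sets from a synthetic universe g0001..gN.

    Module genes are sampled without replacement across all modules, so the
    returned sets are pairwise disjoint.  The same seed always yields the
    same collection.
    """
    if sum(sizes) > n_genes:
        raise ValueError(
            f"requested {sum(sizes)} module genes from a universe of {n_genes}"
        )
    if any(s < 1 for s in sizes):
        raise ValueError("module sizes must be positive")
    if names is None:
        names = [f"M{i + 1:02d}" for i in range(len(sizes))]
    if len(names) != len(sizes):
        raise ValueError("names and sizes must have equal length")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    universe = np.array(_gene_ids(n_genes))
    picked = rng.choice(n_genes, size=sum(sizes), replace=False)
    sets, start = [], 0
    for name, size in zip(names, sizes):
        idx = np.sort(picked[start:start + size])
        sets.append(GeneSet(name=name, description="synthetic module",
                            genes=tuple(universe[idx])))
        start += size
    return GeneSetCollection(sets=tuple(sets), source="synthetic")


def simulate_experiment(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate one replicated treatment/control experiment.

    Control samples are Normal(baseline_mean, noise_sd) per gene; in the
    treatment cohort, each responding gene's mean is shifted by its planted
    signed delta.  Responders and up/down assignment are drawn from a
    dedicated sub-stream so the truth is reproducible; overlapping modules
    (when allowed) contribute additive shifts.
    """
    genes = _gene_ids(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    root = np.random.SeedSequence([config.seed, 0x70AD])
    truth_rng, noise_rng = (np.random.default_rng(s) for s in root.spawn(2))

    log_fc = np.zeros(config.n_genes)
    module_active: dict[str, bool] = {}
    module_delta: dict[str, float] = {}
    for pm in config.modules:
        k = len(pm.gene_set)
        n_resp = int(round(pm.responder_fraction * k))
        members = np.array([gene_pos[g] for g in pm.gene_set.genes])
        responders = truth_rng.choice(members, size=n_resp, replace=False)
        n_up = int(round(pm.direction_mix * n_resp))
        shuffled = truth_rng.permutation(responders)
        log_fc[shuffled[:n_up]] += pm.effect_size
        log_fc[shuffled[n_up:]] -= pm.effect_size
        module_active[pm.gene_set.name] = pm.effect_size > 0 and n_resp > 0
        module_delta[pm.gene_set.name] = pm.effect_size

    n = config.n_per_cohort
    cond = config.condition_id
    ctl_ids = [f"{cond}_ctl_{i + 1}" for i in range(n)]
    trt_ids = [f"{cond}_trt_{i + 1}" for i in range(n)]
    noise = noise_rng.normal(0.0, config.noise_sd, size=(config.n_genes, 2 * n))
    values = np.empty((config.n_genes, 2 * n))
    values[:, :n] = config.baseline_mean + noise[:, :n]
    values[:, n:] = config.baseline_mean + log_fc[:, None] + noise[:, n:]

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                            columns=ctl_ids + trt_ids),
        metadata=pd.DataFrame(
            {"condition_id": cond,
             "cohort": ["control"] * n + ["treatment"] * n},
            index=pd.Index(ctl_ids + trt_ids, name="sample_id"),
        ),
    )
    truth = SimulationTruth(
        log_fc=pd.Series(log_fc, index=pd.Index(genes, name="gene"), name="true_log_fc"),
        module_active=module_active,
        module_delta=module_delta,
    )
    return matrix, truth


def make_planted_config(
    n_genes: int,
    module_sizes: list[int] | tuple[int, ...],
    effect_sizes: list[float] | tuple[float, ...],
    seed: int = 0,
    responder_fraction: float = 1.0,
    direction_mix: float = 0.5,
    names: list[str] | None = None,
    **kwargs,
) -> tuple[SimulationConfig, GeneSetCollection]:
    """Compose a disjoint module collection and a config planting it.

    Convenience wrapper: one module per size, with the matching effect
    size (0 makes a decoy).  Returns the config and the collection so the
    caller can score exactly the sets that were planted.
    """
    if len(module_sizes) != len(effect_sizes):
        raise ValueError("module_sizes and effect_sizes must align")
    gsc = generate_universe(n_genes, module_sizes, seed=seed, names=names)
    modules = tuple(
        PlantedModule(gene_set=gs, effect_size=delta,
                      responder_fraction=responder_fraction,
                      direction_mix=direction_mix)
        for gs, delta in zip(gsc, effect_sizes)
    )
    return SimulationConfig(n_genes=n_genes, modules=modules, seed=seed, **kwargs), gsc
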