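"""Shared fixtures: tiny fold-change tables, GMT files, simulated matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from toxmod import ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture
def worked_fct() -> pd.DataFrame:
    """Five-gene universe with fold changes 0.1..0.5 (hand-enumerable null)."""
    return pd.DataFrame(
        {"fc": [0.1, 0.2, 0.3, 0.4, 0.5], "t": 0.0, "p": [0.5] * 5},
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene"),
    )


@pytest.fixture
def top_pair_set() -> GeneSet:
    """The set holding the two largest fold changes of ``worked_fct``."""
    return GeneSet(name="TOP", description="top pair", genes=("g4", "g5"))


@pytest.fixture
def three_set_collection() -> GeneSetCollection:
    return GeneSetCollection(
        sets=(
            GeneSet("FIB", "fibrosis-like", ("g1", "g2", "g3")),
            GeneSet("NEC", "necrosis-like", ("g4", "g5")),
            GeneSet("INF", "infiltration-like", ("g2", "g6")),
        ),
        source="synthetic",
    )


def make_matrix(values: np.ndarray, genes: list[str], condition: str = "c1",
                n_control: int | None = None) -> ExpressionMatrix:
    """Wrap an array as an ExpressionMatrix, first half control samples."""
    n = values.shape[1]
    if n_control is None:
        n_control = n // 2
    samples = [f"s{i + 1}" for i in range(n)]
    meta = pd.DataFrame(
        {"condition_id": condition,
         "cohort": ["control"] * n_control + ["treatment"] * (n - n_control)},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                            columns=samples),
        metadata=meta,
    )


@pytest.fixture
def paired_cohort_matrix() -> ExpressionMatrix:
    """Four genes x 10 samples; gene g3 shifted up by ln 2 in treatment."""
    rng = np.random.default_rng(7)
    values = rng.normal(5.0, 0.4, size=(4, 10))
    values[2, 5:] += np.log(2.0)
    return make_matrix(values, ["g1", "g2", "g3", "g4"])
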