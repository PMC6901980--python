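"""Readers and writers for the plain-text formats the pipeline touches.

Gene sets travel as GMT (the Broad/MSigDB dialect: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``); expression data as a TSV
matrix (first column gene IDs, header row sample IDs) plus a sample-metadata
TSV with columns ``sample_id``, ``condition_id``, ``cohort``.  Gene
identifiers are opaque, case-sensitive strings — no symbol/Entrez mapping is
attempted; module and expression IDs are assumed pre-harmonized by the
caller.

Missing-value tokens (``NA``, ``.``, empty cells) are rejected rather than
imputed: every downstream statistic assumes a complete matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "FormatError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "write_json",
]

COHORTS = ("treatment", "control")


class FormatError(ValueError):
    """A file violated the expected dialect or an internal consistency rule."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (injury module or pathway).

    Genes are de-duplicated on construction, preserving first-occurrence
    order, so the non-empty/no-duplicate invariants hold everywhere.
    """

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set name must be non-empty")
        deduped = tuple(dict.fromkeys(self.genes))
        if not deduped:
            raise FormatError(f"gene set {self.name!r} has no genes")
        if any(g == "" for g in deduped):
            raise FormatError(f"gene set {self.name!r} contains an empty gene ID")
        object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of uniquely-named gene sets."""

    sets: tuple[GeneSet, ...]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise FormatError(f"duplicate gene set names: {sorted(dupes)}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample log-scale expression with sample metadata.

    ``values``: DataFrame indexed by gene ID, one column per sample.
    ``metadata``: DataFrame indexed by sample_id with columns
    ``condition_id`` and ``cohort`` (``treatment`` / ``control``).
    Every condition must carry at least two samples in each cohort so the
    per-gene t-test has a variance estimate.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        v, m = self.values, self.metadata
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dupes[:5]}")
        if not np.isfinite(v.to_numpy()).all():
            raise FormatError("expression matrix contains non-finite values")
        missing_meta = set(v.columns) - set(m.index)
        missing_mat = set(m.index) - set(v.columns)
        if missing_meta or missing_mat:
            raise FormatError(
                f"sample mismatch: {sorted(missing_meta)} absent from metadata, "
                f"{sorted(missing_mat)} absent from matrix"
            )
        bad = set(m["cohort"]) - set(COHORTS)
        if bad:
            raise FormatError(f"unknown cohort labels {sorted(bad)}; expected {COHORTS}")
        counts = m.groupby(["condition_id", "cohort"], observed=True).size()
        for cond in m["condition_id"].unique():
            for cohort in COHORTS:
                if counts.get((cond, cohort), 0) < 2:
                    raise FormatError(
                        f"condition {cond!r} has <2 {cohort} samples; "
                        "the per-gene t-test needs within-cohort variance"
                    )

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def conditions(self) -> list[str]:
        return sorted(self.metadata["condition_id"].unique())

    def cohort_values(self, condition: str, cohort: str) -> pd.DataFrame:
        """Sub-matrix of samples in one cohort of one condition."""
        m = self.metadata
        ids = m.index[(m["condition_id"] == condition) & (m["cohort"] == cohort)]
        if len(ids) == 0:
            raise FormatError(f"condition {condition!r} has no {cohort} samples")
        return self.values[list(ids)]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Duplicate genes within a set are dropped (order-preserving); duplicate
    set names and malformed lines raise :class:`FormatError` naming the
    offending line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g != ""]
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name!r} lists no genes")
            sets.append(GeneSet(name=name, description=description, genes=tuple(genes)))
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    try:
        return GeneSetCollection(sets=tuple(sets), source=str(path))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def _to_numeric(values: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Convert a string-typed matrix to float, naming the first bad cell."""
    out = {}
    for col in values.columns:
        converted = pd.to_numeric(values[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            gene = bad[0]
            raise FormatError(
                f"{path}: non-numeric value {values.at[gene, col]!r} "
                f"for gene {gene!r} in sample {col!r}"
            )
        out[col] = converted.astype(float)
    return pd.DataFrame(out, index=values.index)


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    log_transform: str = "none",
) -> ExpressionMatrix:
    """Load an expression matrix TSV and its sample-metadata TSV.

    Values are taken as already log-transformed; pass ``log_transform``
    ``"natural"`` or ``"log2"`` to apply ln(x+1) / log2(x+1) to count-like
    input at load time.  ``NA`` / ``.`` / empty cells are rejected.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    raw = pd.read_csv(
        matrix_path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    values = _to_numeric(raw, matrix_path)

    if log_transform not in ("none", "natural", "log2"):
        raise ValueError(f"unknown log_transform {log_transform!r}")
    if log_transform != "none":
        if (values.to_numpy() < 0).any():
            raise FormatError(f"{matrix_path}: negative values cannot be log-transformed")
        values = np.log(values + 1.0) if log_transform == "natural" else np.log2(values + 1.0)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "condition_id", "cohort"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{metadata_path}: missing columns {sorted(required - set(meta.columns))}"
        )
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{metadata_path}: duplicate sample_ids {dupes}")
    meta = meta.set_index("sample_id")[["condition_id", "cohort"]]
    return ExpressionMatrix(values=values, metadata=meta)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id",
                         float_format="%.10g")
    meta = matrix.metadata.reset_index()
    meta.columns = ["sample_id", "condition_id", "cohort"]
    meta.to_csv(metadata_path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    """Serialize results deterministically (sorted keys, stable floats)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
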