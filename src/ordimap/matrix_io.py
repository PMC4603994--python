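"""Containers and TSV I/O for expression matrices and auxiliary tables.

All on-disk formats are plain tab-separated UTF-8 text:

* expression matrix — first column ``gene_id``, header row of sample ids,
  log2 values;
* ``samples.tsv`` — ``sample_id``, ``condition`` (case|control), ``necrosis``
  (ordinal numeric, may be empty for controls);
* ``annotations.tsv`` — ``gene_id``, ``species`` (miRNA|mRNA),
  ``functional_class`` (may be empty), ``fold_change`` (may be empty);
* ``targets.tsv`` — ``mirna_id``, ``mrna_id``, ``mirsvr_score``, ``conserved``;
* ``seeds.tsv`` — ``mirna_id``, ``seed_sequence``.

Missing expression values are rejected rather than imputed: the downstream
rank correlations assume complete matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MIRNA = "miRNA"
MRNA = "mRNA"
SPECIES_TAGS = (MIRNA, MRNA)

#: significant digits used when writing float matrices (read∘write identity
#: holds to this precision)
FLOAT_DIGITS = 6


class MatrixIOError(ValueError):
    """Malformed input table (non-numeric cell, duplicate ids, ...)."""


class MatrixShapeError(ValueError):
    """Incompatible matrices (sample-set mismatch, unknown gene id, ...)."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes × samples, with a per-gene species tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns; all cells
        finite floats on the log2 scale.
    species
        Series mapping every gene id to ``"miRNA"`` or ``"mRNA"``.
    """

    values: pd.DataFrame
    species: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise MatrixIOError(f"duplicate gene ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise MatrixIOError(f"duplicate sample ids: {dup}")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise MatrixIOError(
                f"non-finite value at gene {idx[i]!r}, sample {self.values.columns[j]!r}"
            )
        self.species = self.species.reindex(idx)
        if self.species.isna().any():
            missing = self.species.index[self.species.isna()].tolist()
            raise MatrixIOError(f"missing species tag for genes: {missing}")
        bad = set(self.species.unique()) - set(SPECIES_TAGS)
        if bad:
            raise MatrixIOError(f"unknown species tags: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format=f"%.{FLOAT_DIGITS}g")


@dataclass
class SampleTable:
    """Per-sample condition label and ordinal necrosis grade."""

    table: pd.DataFrame  # index sample_id; columns condition, necrosis

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise MatrixIOError("duplicate sample ids in sample table")
        if not {"condition", "necrosis"} <= set(t.columns):
            raise MatrixIOError("sample table needs 'condition' and 'necrosis' columns")
        bad = set(t["condition"].unique()) - {"case", "control"}
        if bad:
            raise MatrixIOError(f"unknown condition labels: {sorted(bad)}")
        case = t[t["condition"] == "case"]
        if case["necrosis"].isna().any():
            missing = case.index[case["necrosis"].isna()].tolist()
            raise MatrixIOError(f"case samples without a necrosis grade: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def condition_labels(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        t = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        return t["condition"].to_numpy()

    def necrosis(self, sample_ids: Sequence[str]) -> np.ndarray:
        vals = self.table.loc[list(sample_ids), "necrosis"].to_numpy(dtype=float)
        return vals

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        t = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(t)


@dataclass
class GeneAnnotationTable:
    """Functional class (and optionally fold change) per gene.

    ``functional_class`` values, when present, must come from the controlled
    vocabulary (default: the study's nine liver functional classes).
    """

    table: pd.DataFrame  # index gene_id; columns species, functional_class, fold_change
    vocabulary: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise MatrixIOError("duplicate gene ids in annotation table")
        if self.vocabulary is not None:
            present = self.table["functional_class"].dropna()
            bad = set(present.unique()) - set(self.vocabulary)
            if bad:
                raise MatrixIOError(f"functional classes outside vocabulary: {sorted(bad)}")

    def species_series(self) -> pd.Series:
        return self.table["species"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, vocabulary: tuple[str, ...] | None = None) -> "GeneAnnotationTable":
        t = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(t, vocabulary=vocabulary)


@dataclass
class TargetTable:
    """Predicted miRNA→mRNA target pairs with mirSVR scores.

    More negative mirSVR scores indicate stronger predicted repression;
    good scores are ≤ −0.1 by the usual convention.
    """

    table: pd.DataFrame  # columns mirna_id, mrna_id, mirsvr_score, conserved

    def __post_init__(self) -> None:
        t = self.table
        needed = {"mirna_id", "mrna_id", "mirsvr_score", "conserved"}
        if not needed <= set(t.columns):
            raise MatrixIOError(f"target table needs columns {sorted(needed)}")
        if t.duplicated(subset=["mirna_id", "mrna_id"]).any():
            raise MatrixIOError("duplicate (mirna_id, mrna_id) pairs in target table")
        if (t["mirsvr_score"].to_numpy(dtype=float) > 0).any():
            raise MatrixIOError("mirSVR scores must be ≤ 0")

    def __len__(self) -> int:
        return len(self.table)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["mirna_id"], self.table["mrna_id"]))

    def good_pairs(self, mirsvr_cutoff: float = -0.1, conserved_only: bool = True) -> "TargetTable":
        """Subset to conserved pairs with mirSVR score ≤ cutoff."""
        t = self.table
        keep = t["mirsvr_score"] <= mirsvr_cutoff
        if conserved_only:
            keep &= t["conserved"].astype(bool)
        return TargetTable(t[keep].reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TargetTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class SeedTable:
    """Seed sequence (5' bases 2–8 of the mature miRNA) per miRNA."""

    table: pd.DataFrame  # columns mirna_id, seed_sequence

    def __post_init__(self) -> None:
        t = self.table
        if not {"mirna_id", "seed_sequence"} <= set(t.columns):
            raise MatrixIOError("seed table needs 'mirna_id' and 'seed_sequence' columns")
        lengths = {len(str(s)) for s in t["seed_sequence"]}
        if len(lengths) > 1:
            raise MatrixIOError(f"seed lengths not constant: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SeedTable":
        return cls(pd.read_csv(path, sep="\t"))


def read_expression(
    path: str | Path, species_tag: str | Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Read a genes × samples TSV into an :class:`ExpressionMatrix`.

    ``species_tag`` is either a single tag applied to every gene or a
    gene→tag mapping (e.g. from an annotation table, for merged matrices).
    Duplicate gene rows are averaged with a warning; non-numeric cells are
    rejected with their location.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.empty:
        raise MatrixIOError(f"{path}: empty expression file")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise MatrixIOError(f"{path}: duplicate sample ids {dup}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise MatrixIOError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise MatrixIOError(
            f"{path}: missing value at gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if numeric.index.duplicated().any():
        dup = numeric.index[numeric.index.duplicated()].unique().tolist()
        warnings.warn(f"{path}: duplicate gene rows averaged: {dup}", stacklevel=2)
        numeric = numeric.groupby(level=0, sort=False).mean()
    if isinstance(species_tag, str):
        species = pd.Series(species_tag, index=numeric.index)
    else:
        species = pd.Series(species_tag).reindex(numeric.index)
    return ExpressionMatrix(numeric.astype(float), species)


def merge_profiles(mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> ExpressionMatrix:
    """Stack miRNA and mRNA matrices (miRNAs first), aligning samples by id."""
    s1, s2 = set(mirna.sample_ids), set(mrna.sample_ids)
    if s1 != s2:
        only1 = sorted(s1 - s2)
        only2 = sorted(s2 - s1)
        raise MatrixShapeError(
            f"sample sets differ: only in miRNA matrix {only1}, only in mRNA matrix {only2}"
        )
    overlap = set(mirna.gene_ids) & set(mrna.gene_ids)
    if overlap:
        raise MatrixShapeError(f"gene ids present in both matrices: {sorted(overlap)}")
    aligned = mrna.values[mirna.sample_ids]
    values = pd.concat([mirna.values, aligned])
    species = pd.concat([mirna.species, mrna.species])
    return ExpressionMatrix(values, species)


def filter_rows(matrix: ExpressionMatrix, id_set: Iterable[str]) -> ExpressionMatrix:
    """Row-subset ``matrix`` to ``id_set``, in the order given."""
    ids = list(id_set)
    unknown = [g for g in ids if g not in matrix.values.index]
    if unknown:
        raise MatrixShapeError(f"unknown gene ids: {unknown}")
    return ExpressionMatrix(matrix.values.loc[ids], matrix.species.loc[ids])
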