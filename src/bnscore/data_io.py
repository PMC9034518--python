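"""Gene namespaces, gene sets and annotation/expression matrix I/O.

Gene identifiers are opaque, case-sensitive strings; no symbol/ID mapping
is attempted.  All tabular formats are plain TSV (UTF-8, "." decimal
separator) with a header row and the gene identifier in the first column;
an empty cell means "missing".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "GeneUniverse",
    "GeneSet",
    "BinaryAnnotationMatrix",
    "ContinuousAnnotationMatrix",
    "ExpressionMatrix",
    "read_gene_set",
    "write_gene_set",
    "read_annotation_matrix",
    "write_annotation_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "sample_background",
]

Role = Literal["seed", "background", "benchmark", "candidate"]


@dataclass(frozen=True)
class GeneUniverse:
    """An ordered, duplicate-free gene namespace."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 3:
            raise ValueError("a gene universe needs at least 3 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    @property
    def index(self) -> dict[str, int]:
        # cached lazily on the instance (frozen dataclass -> object.__setattr__)
        cached = self.__dict__.get("_index")
        if cached is None:
            cached = {g: i for i, g in enumerate(self.genes)}
            object.__setattr__(self, "_index", cached)
        return cached

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "GeneUniverse":
        return cls(tuple(dict.fromkeys(genes)))


@dataclass(frozen=True)
class GeneSet:
    """A named, role-tagged subset of a gene universe."""

    name: str
    members: frozenset[str]
    role: Role = "candidate"

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def validate_against(self, universe: GeneUniverse) -> None:
        extra = self.members - set(universe.genes)
        if extra:
            raise ValueError(
                f"gene set {self.name!r} has {len(extra)} members outside the "
                f"universe, e.g. {sorted(extra)[:5]}"
            )


class _AnnotationMatrix:
    """Genes x annotations table; NaN encodes a missing value."""

    kind: str = "continuous"

    def __init__(self, values: pd.DataFrame):
        if values.columns.duplicated().any():
            raise ValueError("annotation names must be unique")
        if values.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")
        data = values.astype(float)
        self._check(data)
        self.values = data

    def _check(self, data: pd.DataFrame) -> None:
        finite = np.isfinite(data.to_numpy()) | np.isnan(data.to_numpy())
        if not finite.all():
            raise ValueError("continuous annotations must be finite or missing")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def annotations(self) -> pd.Index:
        return self.values.columns

    def column(self, annotation: str) -> pd.Series:
        return self.values[annotation]


class ContinuousAnnotationMatrix(_AnnotationMatrix):
    kind = "continuous"


class BinaryAnnotationMatrix(_AnnotationMatrix):
    kind = "binary"

    def _check(self, data: pd.DataFrame) -> None:
        arr = data.to_numpy()
        bad = ~(np.isnan(arr) | (arr == 0.0) | (arr == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"binary annotation matrix holds non-binary value "
                f"{arr[i, j]!r} at gene {data.index[i]!r}, "
                f"annotation {data.columns[j]!r}"
            )


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x conditions expression table (no missing values)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("an expression matrix needs at least 2 conditions")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("expression matrix may not contain missing values")
        if (arr < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.values = self.values.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# readers / writers


def read_gene_set(
    path: str | Path,
    format: Literal["plain", "gmt"] = "plain",
    name: str | None = None,
    role: Role = "candidate",
) -> GeneSet:
    """Read a gene set from a plain list (one gene per line) or a GMT line.

    Duplicate members are dropped with a warning; an empty file is an error.
    For ``gmt``, only the first record of the file is read.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if format == "plain":
        raw = [line.strip() for line in text.splitlines()]
        raw = [g for g in raw if g]
        set_name = name or path.stem
    elif format == "gmt":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError(f"empty gene set file: {path}")
        fields = lines[0].rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT record in {path}")
        set_name = name or fields[0]
        raw = [g.strip() for g in fields[2:] if g.strip()]
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown gene set format {format!r}")
    if not raw:
        raise ValueError(f"empty gene set file: {path}")
    members = frozenset(raw)
    if len(members) < len(raw):
        warnings.warn(
            f"{len(raw) - len(members)} duplicate gene(s) in {path}; deduplicated",
            stacklevel=2,
        )
    return GeneSet(name=set_name, members=members, role=role)


def write_gene_set(gene_set: GeneSet | Iterable[str], path: str | Path) -> None:
    members = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
    Path(path).write_text("\n".join(sorted(members)) + "\n", encoding="utf-8")


def read_annotation_matrix(
    path: str | Path, kind: Literal["binary", "continuous"]
) -> BinaryAnnotationMatrix | ContinuousAnnotationMatrix:
    """Read a genes x annotations TSV; empty cells become missing (NaN)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"annotation {raw.columns[j]!r} in {path}"
        )
    cls = BinaryAnnotationMatrix if kind == "binary" else ContinuousAnnotationMatrix
    return cls(numeric)


def write_annotation_matrix(
    matrix: _AnnotationMatrix, path: str | Path
) -> None:
    df = matrix.values.copy()
    if matrix.kind == "binary":
        # keep 0/1 unquoted integers so the round trip is bit-exact
        df = df.map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index_label="gene", na_rep="")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        raise ValueError(f"expression matrix {path} contains missing values")
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# background construction


def sample_background(
    universe: GeneUniverse,
    seeds: GeneSet,
    n: int = 500,
    rng_seed: int | None = None,
) -> GeneSet:
    """Uniformly sample ``n`` non-seed genes without replacement.

    Emulates the construction of a genome background set: a random draw
    from the universe excluding the seed genes, assumed to be overwhelmingly
    non-risk.  Reproducible for a fixed ``rng_seed``.
    """
    pool = [g for g in universe.genes if g not in seeds.members]
    if n > len(pool):
        raise ValueError(
            f"cannot sample {n} background genes from {len(pool)} non-seed genes"
        )
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return GeneSet(
        name="background",
        members=frozenset(pool[i] for i in chosen),
        role="background",
    )
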