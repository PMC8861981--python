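"""Readers and writers for every on-disk artifact.

All tabular formats are plain TSV with a header row; gene sets are standard
GMT; fitted mixture models are dumped as JSON.  Identifier matching is exact,
case-sensitive string equality throughout the package — symbol aliasing and
probe-set mapping are the user's concern, not ours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ValidationError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "write_crosstab",
    "FLOAT_FORMAT",
]

#: numeric output precision for all TSV writers (6 significant digits)
FLOAT_FORMAT = "%.6g"

_SEX_TOKENS = {
    "m": "M", "male": "M", "M": "M", "Male": "M", "MALE": "M",
    "f": "F", "female": "F", "F": "F", "Female": "F", "FEMALE": "F",
}

ANNOTATION_COLUMNS = ("sample_id", "sex", "age_months", "replicate")


class ValidationError(ValueError):
    """An on-disk artifact or in-memory object violates a format invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with identifiers.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers (probe sets or gene symbols; treated as opaque).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Finite expression values.
    scale : {"linear", "log2"}
        Whether values are on the linear intensity scale or log2 of it.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "linear") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (exponentiates log2 input)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(self.gene_ids, self.sample_ids,
                                np.exp2(self.values), "linear")


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as carried by a GMT file."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


def read_expression_matrix(path, scale: str = "linear",
                           comment: str = "#") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header sample ids).

    Raises
    ------
    ValidationError
        On duplicate identifiers or a non-numeric cell (reported with its
        row and column coordinates).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, comment=comment, dtype=str)
    if raw.index.name is None:
        raise ValidationError(f"{path}: missing header row")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(list(raw.index), list(raw.columns), values, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path,
                            header_comment: str | None = None) -> None:
    """Write a TSV expression matrix with 6-significant-digit values."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_frame().to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


def read_sample_annotation(path) -> pd.DataFrame:
    """Read and validate a sample annotation table.

    Required columns: sample_id, sex, age_months, replicate (extras ignored).
    Sex tokens are normalized to {M, F}; ages must be positive; replicate a
    positive integer.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame()
    out["sample_id"] = df["sample_id"].astype(str)
    _check_unique(out["sample_id"], "sample id")
    try:
        out["sex"] = [_SEX_TOKENS[t] for t in df["sex"]]
    except KeyError as exc:
        raise ValidationError(f"{path}: unknown sex token {exc.args[0]!r}") from None
    out["age_months"] = pd.to_numeric(df["age_months"], errors="raise")
    if (out["age_months"] <= 0).any():
        bad = out.loc[out["age_months"] <= 0, "sample_id"].iloc[0]
        raise ValidationError(f"{path}: non-positive age for sample {bad!r}")
    out["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    if (out["replicate"] <= 0).any():
        bad = out.loc[out["replicate"] <= 0, "sample_id"].iloc[0]
        raise ValidationError(f"{path}: non-positive replicate for sample {bad!r}")
    return out


def write_sample_annotation(annot: pd.DataFrame, path,
                            header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        annot.to_csv(fh, sep="\t", index=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then >=1 gene per tab-delimited line.

    Genes duplicated within a set are dropped (first occurrence kept).
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_crosstab(counts: np.ndarray, path) -> None:
    """Write a KxK male (rows) x female (columns) cluster count table."""
    K = counts.shape[0]
    df = pd.DataFrame(counts,
                      index=pd.Index(range(1, K + 1), name="male_cluster"),
                      columns=[str(k) for k in range(1, K + 1)])
    df.to_csv(path, sep="\t")


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
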