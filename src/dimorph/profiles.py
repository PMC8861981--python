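"""Temporal profile construction: replicate collapsing and standardization.

The unit object of clustering is one gene's replicate-averaged expression
trajectory in one sex.  Male and female trajectories of the same gene are
distinct objects, so a study with G genes yields 2G profiles on the shared
age grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "ProfileSet",
    "scale_ages",
    "design_matrices",
    "collapse_replicates",
    "standardize_profiles",
    "read_profiles",
    "write_profiles",
]

#: profiles whose sample SD over the age grid falls below this are removed
#: by standardization (a flat trajectory carries no shape information)
SD_FLOOR = 1e-8


def scale_ages(ages) -> np.ndarray:
    """Map an age grid linearly onto [-1, 1].

    Cubic powers of raw months (up to 18**3) are numerically hostile; all
    polynomial bases in the package are built on this scaled time axis.
    """
    a = np.asarray(ages, dtype=float)
    if a.ndim != 1 or len(a) < 2 or np.any(np.diff(a) <= 0):
        raise ValidationError("age grid must be strictly increasing, length >= 2")
    return 2.0 * (a - a[0]) / (a[-1] - a[0]) - 1.0


def design_matrices(ages) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial design matrices on the scaled age grid.

    Returns
    -------
    X : ndarray, shape (T, 4)
        Cubic fixed-effect basis [1, s, s^2, s^3].
    Z : ndarray, shape (T, 3)
        Quadratic random-effect basis [1, s, s^2].
    """
    s = scale_ages(ages)
    X = np.vander(s, 4, increasing=True)
    return X, X[:, :3].copy()


@dataclass
class ProfileSet:
    """Per-(gene, sex) time-course vectors on a shared age grid.

    ``standardized`` marks the set as fit-ready: each row centered by its own
    mean and scaled by its own sample SD over the grid.  ``excluded`` lists
    (gene_id, sex) objects removed because their trajectory was flat.
    """

    object_ids: list[tuple[str, str]]
    age_grid: np.ndarray
    values: np.ndarray
    standardized: bool = False
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.age_grid) <= 0):
            raise ValidationError("age grid must be strictly increasing")
        if self.values.shape != (len(self.object_ids), len(self.age_grid)):
            raise ValidationError("profile matrix shape does not match ids/grid")

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def n_times(self) -> int:
        return len(self.age_grid)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.object_ids, names=["gene_id", "sex"])
        return pd.DataFrame(self.values, index=idx,
                            columns=[f"{a:g}" for a in self.age_grid])


def collapse_replicates(matrix: ExpressionMatrix, annot: pd.DataFrame) -> ProfileSet:
    """Average replicates within each (sex, age) group.

    One value per (gene, sex, age): the arithmetic mean over that group's
    replicate samples.  Output objects are ordered gene-major with the male
    profile before the female one; the age grid is the sorted set of observed
    ages.
    """
    annot = annot.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in annot.index]
    if missing:
        raise ValidationError(f"samples not annotated: {missing[:5]}")
    annot = annot.loc[matrix.sample_ids]
    ages = np.array(sorted(annot["age_months"].unique()), dtype=float)
    sexes = ("M", "F")
    col_groups: dict[tuple[str, float], np.ndarray] = {}
    for sex in sexes:
        for age in ages:
            mask = ((annot["sex"] == sex) & (annot["age_months"] == age)).to_numpy()
            if not mask.any():
                raise ValidationError(f"empty (sex={sex}, age={age:g}) group")
            col_groups[(sex, age)] = mask
    G = matrix.n_genes
    T = len(ages)
    values = np.empty((2 * G, T))
    for s_i, sex in enumerate(sexes):
        block = np.column_stack([
            matrix.values[:, col_groups[(sex, age)]].mean(axis=1) for age in ages
        ])
        values[s_i::2] = block  # gene-major layout: M row then F row per gene
    object_ids = [(gene, sex) for gene in matrix.gene_ids for sex in sexes]
    return ProfileSet(object_ids, ages, values, standardized=False)


def standardize_profiles(profiles: ProfileSet, per: str = "profile") -> ProfileSet:
    """Center and scale profiles by gene-specific means and sample SDs (ddof=1).

    ``per="profile"`` (default) standardizes each (gene, sex) row by its own
    mean and SD, making clustering purely shape-based.  ``per="gene"`` pools
    the gene's male and female rows and standardizes both by the shared mean
    and SD, preserving between-sex level and amplitude differences and
    avoiding the exact per-row mean/SD constraints the per-profile variant
    imposes.  Flat rows (SD below ``SD_FLOOR``) are removed and reported on
    the result's ``excluded`` attribute.
    """
    if profiles.standardized:
        raise ValidationError("profiles already standardized")
    if profiles.n_times < 3:
        raise ValidationError(
            f"need >= 3 time points to fit a polynomial model, got {profiles.n_times}"
        )
    if per not in ("profile", "gene"):
        raise ValidationError("per must be 'profile' or 'gene'")
    if per == "profile":
        mean = profiles.values.mean(axis=1, keepdims=True)
        sd = profiles.values.std(axis=1, ddof=1, keepdims=True)
    else:
        # pool each gene's rows (both sexes) for a shared mean/SD
        groups: dict[str, list[int]] = {}
        for i, (gene, _) in enumerate(profiles.object_ids):
            groups.setdefault(gene, []).append(i)
        mean = np.empty((profiles.n_objects, 1))
        sd = np.empty((profiles.n_objects, 1))
        for rows in groups.values():
            pooled = profiles.values[rows].ravel()
            mean[rows] = pooled.mean()
            sd[rows] = pooled.std(ddof=1)
    keep = (sd[:, 0] >= SD_FLOOR)
    excluded = [oid for oid, k in zip(profiles.object_ids, keep) if not k]
    values = (profiles.values[keep] - mean[keep]) / sd[keep]
    kept_ids = [oid for oid, k in zip(profiles.object_ids, keep) if k]
    return ProfileSet(kept_ids, profiles.age_grid, values,
                      standardized=True, excluded=excluded)


def write_profiles(profiles: ProfileSet, path,
                   header_comment: str | None = None) -> None:
    """Write a profile TSV: gene_id, sex, standardized flag header, ages."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# standardized={int(profiles.standardized)}\n")
        cols = "\t".join(f"age_{a:g}" for a in profiles.age_grid)
        fh.write(f"gene_id\tsex\t{cols}\n")
        for (gene, sex), row in zip(profiles.object_ids, profiles.values):
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{gene}\t{sex}\t{vals}\n")


def read_profiles(path) -> ProfileSet:
    """Read a profile TSV written by :func:`write_profiles`."""
    standardized = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "standardized=" in line:
                    standardized = line.strip().split("standardized=")[1] == "1"
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "sex"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    age_cols = [c for c in df.columns if c.startswith("age_")]
    if len(age_cols) < 2:
        raise ValidationError(f"{path}: needs >= 2 age_* columns")
    ages = np.array([float(c[4:]) for c in age_cols])
    ids = list(zip(df["gene_id"].astype(str), df["sex"].astype(str)))
    return ProfileSet(ids, ages, df[age_cols].to_numpy(dtype=float),
                      standardized=standardized)
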