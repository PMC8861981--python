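"""Sex-specific differential-expression screen.

A pooled-variance two-sample t test per gene, male versus female, across all
time points on the unlogged expression scale, followed by Benjamini-Hochberg
FDR control and extraction of a signed sex signature at a chosen q threshold
(+1 = higher in males, -1 = higher in females).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "Signature",
    "sex_ttest",
    "benjamini_hochberg",
    "extract_signature",
    "SexDifferentialExpression",
    "SexDEResults",
]

DE_COLUMNS = ["gene_id", "mean_M", "mean_F", "ratio_MF", "ratio_defined",
              "t_stat", "p_value", "q_value"]


@dataclass
class Signature:
    """Signed gene set: gene_id -> +1 (higher in males) / -1 (higher in females)."""

    entries: dict[str, int]
    threshold_q: float = np.nan

    @property
    def n_up(self) -> int:
        return sum(1 for s in self.entries.values() if s > 0)

    @property
    def n_down(self) -> int:
        return sum(1 for s in self.entries.values() if s < 0)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": list(self.entries),
                             "sign": list(self.entries.values())})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "Signature":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
        for col in ("gene_id", "sign"):
            if col not in df.columns:
                raise ValidationError(f"{path}: missing column {col!r}")
        signs = df["sign"].astype(int)
        if not signs.isin([1, -1]).all():
            raise ValidationError(f"{path}: signs must be +1 or -1")
        return cls(dict(zip(df["gene_id"], signs)))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sex_ttest(matrix: ExpressionMatrix, annot: pd.DataFrame) -> pd.DataFrame:
    """Per-gene pooled-variance two-sample t test, male vs female.

    Pools all time points; log2 input is exponentiated first so means and
    male/female ratios are on the unlogged scale.  df = n_M + n_F - 2,
    two-sided p, BH q over all genes in the matrix.  Genes with zero variance
    in both sexes and equal means get t = 0, p = 1.
    """
    matrix = matrix.to_linear()
    annot = annot.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in annot.index]
    if missing:
        raise ValidationError(f"samples not annotated: {missing[:5]}")
    sex = annot.loc[matrix.sample_ids, "sex"].to_numpy()
    m_mask, f_mask = sex == "M", sex == "F"
    n_m, n_f = int(m_mask.sum()), int(f_mask.sum())
    if n_m < 2 or n_f < 2:
        raise ValidationError(
            f"need >= 2 samples per sex, got M={n_m}, F={n_f}")
    male, female = matrix.values[:, m_mask], matrix.values[:, f_mask]
    t_stat, p_value = stats.ttest_ind(male, female, axis=1, equal_var=True)
    # identical groups (zero pooled variance, equal means) -> t = 0, p = 1
    degenerate = np.isnan(t_stat)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_value = np.where(degenerate, 1.0, p_value)
    mean_m, mean_f = male.mean(axis=1), female.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_f > 0, mean_m / mean_f, np.nan)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "mean_M": mean_m,
        "mean_F": mean_f,
        "ratio_MF": ratio,
        "ratio_defined": mean_f > 0,
        "t_stat": t_stat,
        "p_value": p_value,
        "q_value": benjamini_hochberg(p_value),
    })


def extract_signature(records: pd.DataFrame, threshold_q: float) -> Signature:
    """Signed signature of genes with q below ``threshold_q``.

    Sign +1 if the male mean exceeds the female mean, -1 if below; genes with
    exactly equal means carry no direction and are excluded.
    """
    if not 0.0 < threshold_q <= 1.0:
        raise ValidationError("threshold_q must be in (0, 1]")
    entries: dict[str, int] = {}
    if len(records):
        hits = records[(records["q_value"] < threshold_q)
                       & (records["mean_M"] != records["mean_F"])]
        for gene, m, f in zip(hits["gene_id"], hits["mean_M"], hits["mean_F"]):
            entries[str(gene)] = 1 if m > f else -1
    return Signature(entries, threshold_q=threshold_q)


class SexDifferentialExpression:
    """Model object for the sex DE screen (statsmodels-style)."""

    def __init__(self, matrix: ExpressionMatrix, annot: pd.DataFrame):
        self.matrix = matrix
        self.annot = annot

    def fit(self) -> "SexDEResults":
        return SexDEResults(self, sex_ttest(self.matrix, self.annot))


class SexDEResults:
    """DE screen results: per-gene records plus signature extraction."""

    def __init__(self, model: SexDifferentialExpression, records: pd.DataFrame):
        self.model = model
        self.records = records

    def signature(self, threshold_q: float) -> Signature:
        return extract_signature(self.records, threshold_q)

    def n_significant(self, threshold_q: float) -> int:
        return int((self.records["q_value"] < threshold_q).sum())

    def summary(self, threshold_q: float = 0.25) -> pd.DataFrame:
        """Top differential genes at the given q threshold, sorted by p."""
        hits = self.records[self.records["q_value"] < threshold_q]
        return hits.sort_values("p_value").reset_index(drop=True)

    def write(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6g")
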