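"""Signature-association scan over a compendium of expression datasets.

Projects a signed gene signature onto every dataset: each signature gene is
z-scored across the dataset's samples, and a sample's signature-association
(SA) score is the mean of the direction-signed z-scores.  Positive scores
mean the sample regulates the signature coordinately in the signature's own
direction, negative scores in the opposite direction.  Datasets are then
ranked by a two-sided Fisher exact test for enrichment in samples with
strong |SA| scores, "strong" being a pooled quantile across the compendium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ValidationError
from .descreen import Signature, benjamini_hochberg

__all__ = [
    "SAResult",
    "sa_scores",
    "signature_coverage",
    "scan_compendium",
    "fisher_exact_2x2",
]


@dataclass
class SAResult:
    """Per-dataset outcome of the compendium scan."""

    dataset_id: str
    sample_scores: dict[str, float]
    n_strong: int
    n_samples: int
    fisher_p: float
    q_value: float
    coverage: float


class CoverageWarning(UserWarning):
    """A dataset covers too little of the signature and was skipped."""


def signature_coverage(dataset: ExpressionMatrix, signature: Signature) -> float:
    """Fraction of signature genes present in the dataset's rows."""
    if not signature.entries:
        raise ValidationError("signature is empty")
    present = set(dataset.gene_ids)
    return sum(1 for g in signature.entries if g in present) / len(signature)


def sa_scores(dataset: ExpressionMatrix, signature: Signature) -> dict[str, float]:
    """Signature-association score per sample.

    Each signature gene present in the dataset is z-scored across samples
    (sample SD, ddof=1); genes with zero spread are dropped.  The score is
    the unweighted mean of sign * z over the scored genes, so any positive
    affine transform of a single gene's row leaves the scores unchanged and
    every dataset's scores average to zero.
    """
    if dataset.n_samples < 2:
        raise ValidationError("need >= 2 samples to z-score a dataset")
    if not signature.entries:
        raise ValidationError("signature is empty")
    row_of = {}
    for i, g in enumerate(dataset.gene_ids):
        row_of.setdefault(g, i)  # duplicate rows: first occurrence wins
    rows, signs = [], []
    for g, s in signature.entries.items():
        if g in row_of:
            rows.append(row_of[g])
            signs.append(float(s))
    if not rows:
        raise ValidationError("no signature gene present in dataset")
    sub = dataset.values[rows]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    if not ok.any():
        raise ValidationError("all signature genes are flat in this dataset")
    z = (sub[ok] - mu[ok]) / sd[ok]
    scores = (np.asarray(signs)[ok, None] * z).mean(axis=0)
    return dict(zip(dataset.sample_ids, scores.tolist()))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table with fixed margins."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def scan_compendium(datasets: list[ExpressionMatrix], signature: Signature,
                    strong_quantile: float = 0.90,
                    min_coverage: float = 0.5,
                    dataset_ids: list[str] | None = None) -> list[SAResult]:
    """Rank compendium datasets by enrichment in strong-|SA| samples.

    Samples of all coverage-passing datasets are pooled; a sample is
    "strong" when its |SA| reaches the pooled ``strong_quantile`` quantile.
    Each dataset's 2x2 table (strong / not strong x this dataset / rest) is
    tested with the two-sided Fisher exact test; BH q across datasets;
    results sorted by ascending p (ties by dataset id).
    """
    if not 0.0 <= strong_quantile <= 1.0:
        raise ValidationError("strong_quantile must be in [0, 1]")
    if dataset_ids is None:
        dataset_ids = [f"DS{d + 1:03d}" for d in range(len(datasets))]
    passing: list[tuple[str, dict[str, float], float]] = []
    for ds_id, ds in zip(dataset_ids, datasets):
        cov = signature_coverage(ds, signature)
        if cov < min_coverage:
            warnings.warn(
                f"dataset {ds_id}: coverage {cov:.2f} < {min_coverage:.2f}, "
                "skipped", CoverageWarning, stacklevel=2)
            continue
        passing.append((ds_id, sa_scores(ds, signature), cov))
    if len(passing) < 2:
        raise ValidationError(
            f"need >= 2 datasets passing coverage, got {len(passing)}")
    pooled = np.concatenate([np.abs(list(s.values())) for _, s, _ in passing])
    threshold = float(np.quantile(pooled, strong_quantile))
    strong_total = int(np.sum(pooled >= threshold))
    n_total = len(pooled)
    results = []
    for ds_id, scores, cov in passing:
        abs_scores = np.abs(list(scores.values()))
        n_strong = int(np.sum(abs_scores >= threshold))
        n_samples = len(abs_scores)
        table = [[n_strong, strong_total - n_strong],
                 [n_samples - n_strong,
                  (n_total - strong_total) - (n_samples - n_strong)]]
        results.append(SAResult(ds_id, scores, n_strong, n_samples,
                                fisher_exact_2x2(table), np.nan, cov))
    q = benjamini_hochberg([r.fisher_p for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return sorted(results, key=lambda r: (r.fisher_p, r.dataset_id))


def scan_to_frame(results: list[SAResult]) -> pd.DataFrame:
    rows = [{"dataset_id": r.dataset_id, "n_samples": r.n_samples,
             "n_strong": r.n_strong, "coverage": r.coverage,
             "fisher_p": r.fisher_p, "q_value": r.q_value}
            for r in results]
    return pd.DataFrame(rows, columns=["dataset_id", "n_samples", "n_strong",
                                       "coverage", "fisher_p", "q_value"])
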