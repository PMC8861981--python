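"""Male x female cluster-label concordance and gene-set overrepresentation.

Cross-tabulates the cluster labels of each gene's male and female temporal
profiles (male clusters as rows, female clusters as columns), partitions
genes into concordant (on-diagonal) and discordant (off-diagonal) sets, and
tests user-supplied gene sets for overrepresentation with the one-sided
hypergeometric ("modified Fisher exact") test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError
from .descreen import benjamini_hochberg

__all__ = [
    "CrossTab",
    "ConcordancePartition",
    "cross_tabulate",
    "summarize_crosstab",
    "partition_genes",
    "gene_set_summary",
    "overrepresentation_test",
]


@dataclass
class CrossTab:
    """K x K male-cluster (rows) x female-cluster (columns) count matrix."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts.ndim != 2
                or self.counts.shape[0] != self.counts.shape[1]):
            raise ValidationError("cross-tabulation must be square")
        if (self.counts < 0).any():
            raise ValidationError("cross-tabulation counts must be >= 0")

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    def cell(self, male: int, female: int) -> int:
        """Count of genes with male label ``male`` and female label ``female``."""
        return int(self.counts[male - 1, female - 1])

    def to_frame(self) -> pd.DataFrame:
        labels = list(range(1, self.K + 1))
        return pd.DataFrame(self.counts,
                            index=pd.Index(labels, name="male_cluster"),
                            columns=pd.Index(labels, name="female_cluster"))


@dataclass
class ConcordancePartition:
    """Genes split by whether both sexes landed in the same cluster."""

    labels: dict[str, tuple[int, int]]          # gene -> (male, female)
    excluded: list[str] = field(default_factory=list)

    @property
    def common_genes(self) -> set[str]:
        return {g for g, (m, f) in self.labels.items() if m == f}

    @property
    def discordant_genes(self) -> set[str]:
        return {g for g, (m, f) in self.labels.items() if m != f}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "male_cluster": m, "female_cluster": f,
                 "concordant": int(m == f)}
                for g, (m, f) in self.labels.items()]
        return pd.DataFrame(rows, columns=["gene_id", "male_cluster",
                                           "female_cluster", "concordant"])


def cross_tabulate(male_labels: dict[str, int], female_labels: dict[str, int],
                   K: int) -> CrossTab:
    """Count genes per (male cluster, female cluster) cell.

    Only genes labeled in both sexes are counted; labels must lie in 1..K.
    """
    counts = np.zeros((K, K), dtype=int)
    for gene, m in male_labels.items():
        f = female_labels.get(gene)
        if f is None:
            continue
        if not (1 <= m <= K and 1 <= f <= K):
            raise ValidationError(
                f"gene {gene!r}: labels ({m}, {f}) outside 1..{K}")
        counts[m - 1, f - 1] += 1
    return CrossTab(counts)


def summarize_crosstab(tab: CrossTab) -> dict:
    """Exact diagonal (concordant) / off-diagonal (discordant) totals."""
    diag = int(np.trace(tab.counts))
    total = int(tab.counts.sum())
    return {
        "diagonal_total": diag,
        "offdiagonal_total": total - diag,
        "grand_total": total,
        "per_cell": tab.cell,
    }


def partition_genes(male_labels: dict[str, int],
                    female_labels: dict[str, int]) -> ConcordancePartition:
    """Split genes into concordant/discordant by their two labels.

    Genes labeled in only one sex are excluded and reported on the result.
    """
    labels: dict[str, tuple[int, int]] = {}
    excluded: list[str] = []
    for gene in set(male_labels) | set(female_labels):
        m, f = male_labels.get(gene), female_labels.get(gene)
        if m is None or f is None:
            excluded.append(gene)
        else:
            labels[gene] = (int(m), int(f))
    return ConcordancePartition(labels, sorted(excluded))


def gene_set_summary(partition: ConcordancePartition,
                     sets: GeneSetCollection) -> pd.DataFrame:
    """Per-set membership counts on each side of the partition.

    Percentages are of the set's dually-labeled members and are rounded to
    the nearest integer for display; the exact fractions are retained.
    """
    common = partition.common_genes
    discordant = partition.discordant_genes
    rows = []
    for name in sets.names():
        genes = set(sets.genes(name))
        n_c = len(genes & common)
        n_d = len(genes & discordant)
        total = n_c + n_d
        frac_c = n_c / total if total else 0.0
        frac_d = n_d / total if total else 0.0
        rows.append({
            "set_name": name, "n_common": n_c, "n_discordant": n_d,
            "n_total": total,
            "frac_common": frac_c, "frac_discordant": frac_d,
            "pct_common": int(round(100 * frac_c)) if total else 0,
            "pct_discordant": int(round(100 * frac_d)) if total else 0,
        })
    return pd.DataFrame(rows, columns=["set_name", "n_common", "n_discordant",
                                       "n_total", "frac_common",
                                       "frac_discordant", "pct_common",
                                       "pct_discordant"])


def overrepresentation_test(query, sets: GeneSetCollection,
                            background) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each set in the query.

    Each set is intersected with the background universe before testing;
    p = P(overlap >= observed) under sampling ``|query|`` genes from the
    background without replacement.  BH q across sets.
    """
    background = set(background)
    if not background:
        raise ValidationError("background gene universe is empty")
    query = set(query)
    if not query <= background:
        raise ValidationError("query must be a subset of the background")
    M, N_query = len(background), len(query)
    rows = []
    for name in sets.names():
        in_bg = set(sets.genes(name)) & background
        n_set = len(in_bg)
        overlap = len(in_bg & query)
        p = float(stats.hypergeom.sf(overlap - 1, M, n_set, N_query))
        rows.append({"set_name": name, "overlap": overlap, "set_size": n_set,
                     "query_size": N_query, "background_size": M,
                     "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                     "query_size", "background_size",
                                     "p_value"])
    df["q_value"] = benjamini_hochberg(df["p_value"]) if len(df) else []
    return df
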