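"""Per-family accounting: counts by status and source, genomic coverage,
prediction accuracy, and conservation categorization.

The coverage of a genomic dataset is estimated from how many network genes
the genomic database already contained versus how many had to be found by
targeted PCR:  coverage = 100 x n_database / (n_database + n_pcr).  The
complementary new-gene percentage (PCR finds over the total) gauges what an
annotation would have missed.  Families are split into duplicated
(size-variable, tandem-cluster-bearing) and non-duplicated (stable-size)
categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .families import ROS_FAMILIES, check_family
from .genes import OrganismAnnotation
from .utils import round_half_up

_STATUS_ORDER = ("complete", "partial", "pseudogene")


@dataclass
class FamilySummary:
    """Counts per (family, organism, source, status), plus totals.

    ``table`` is a DataFrame indexed by family with a column MultiIndex
    (organism, source, status); ``totals`` aggregates over families.
    """

    table: pd.DataFrame
    totals: pd.DataFrame

    def count(self, family: str, organism: str, source: str, status: str) -> int:
        return int(self.table.loc[family, (organism, source, status)])

    def family_sizes(self) -> pd.DataFrame:
        """Total genes per (family, organism), all sources and statuses."""
        return self.table.T.groupby(level="organism").sum().T

    def source_totals(self, organism: str) -> dict[str, int]:
        t = self.totals[organism].groupby(level="source").sum()
        return {s: int(t.get(s, 0)) for s in ("database", "pcr")}

    def cell_text(self, family: str, organism: str, source: str) -> str:
        """A printed-table style cell: 'total (complete+partial+pseudo)'."""
        c = [self.count(family, organism, source, s) for s in _STATUS_ORDER]
        return f"{sum(c)} ({c[0]}+{c[1]}+{c[2]})"


def summarize_families(annotations: dict[str, OrganismAnnotation]) -> FamilySummary:
    """Tabulate gene counts by family, organism, source and status."""
    organisms = sorted(annotations)
    columns = pd.MultiIndex.from_product(
        [organisms, ("database", "pcr"), _STATUS_ORDER],
        names=["organism", "source", "status"],
    )
    table = pd.DataFrame(0, index=list(ROS_FAMILIES), columns=columns)
    for org, ann in annotations.items():
        for g in ann.genes:
            check_family(g.family)
            table.loc[g.family, (org, g.source, g.status)] += 1
    totals = table.sum(axis=0)
    return FamilySummary(table=table, totals=totals)


def genomic_coverage(n_database: int, n_pcr: int) -> float:
    """Percent of network genes already present in the genomic database.

    100 x n_database / (n_database + n_pcr), rounded half-up to 1 decimal.
    Monotone decreasing in ``n_pcr`` for fixed ``n_database``.
    """
    if n_database < 0 or n_pcr < 0:
        raise ValueError("counts must be non-negative")
    total = n_database + n_pcr
    if total == 0:
        raise ValueError("coverage undefined for zero genes")
    return round_half_up(100.0 * n_database / total, 1)


def prediction_accuracy(n_correct: int, n_total: int) -> float:
    """Percent of genes correctly predicted automatically, 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    return round_half_up(100.0 * n_correct / n_total, 2)


def new_gene_percentage(n_pcr: int, n_total: int) -> float:
    """Percent of the total gene set that only targeted PCR detected."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pcr <= n_total:
        raise ValueError("need 0 <= n_pcr <= n_total")
    return round_half_up(100.0 * n_pcr / n_total, 1)


def categorize_conservation(
    family_sizes: pd.DataFrame,
    families_with_clusters: set[str] | None = None,
    cv_threshold: float = 0.15,
) -> dict[str, str]:
    """Label each family ``duplicated`` or ``non_duplicated``.

    A family is duplicated when its size varies across organisms
    (coefficient of variation >= ``cv_threshold``), or some organism holds
    at least twice the minimum observed size, or tandem clusters were
    detected for it.  ``family_sizes`` is families x organisms (as from
    :meth:`FamilySummary.family_sizes`).
    """
    if family_sizes.shape[1] < 2:
        raise ValueError("need sizes from at least two organisms")
    families_with_clusters = families_with_clusters or set()
    out: dict[str, str] = {}
    for family, sizes in family_sizes.iterrows():
        x = sizes.to_numpy(dtype=float)
        mean = x.mean()
        cv = float(x.std() / mean) if mean > 0 else 0.0
        doubled = x.max() >= 2 * x.min() and x.max() > 0
        clustered = family in families_with_clusters
        dup = (cv >= cv_threshold) or doubled or clustered
        out[family] = "duplicated" if dup else "non_duplicated"
    return out
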