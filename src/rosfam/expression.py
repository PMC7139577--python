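"""EST/RNA-seq expression summarization for the ROS gene network.

The per-family expression level in an organism is defined as

    level(f) = (sum of counts over genes of f / number of genes of f)
               / (total counts over all network genes)

i.e. the family's average count normalized by the network total.  Levels
are dimensionless, non-negative, zero exactly when the family has no
counts, and — being a ratio — invariant to a global rescaling of the
library.  They do not sum to 1 across families (the numerator is an
average, not a share).  Pseudogenes are excluded from the per-family gene
count: they cannot be expressed, and keeping them in the denominator would
deflate the averages of pseudogene-rich families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genes import OrganismAnnotation


def load_counts_table(path, organism: str | None = None) -> pd.DataFrame:
    """Read a long-format counts TSV (organism, gene_id, tissue, count)
    into a genes x tissues table, optionally for one organism."""
    df = pd.read_csv(path, sep="\t")
    if organism is not None:
        df = df[df["organism"] == organism]
    return df.pivot_table(
        index="gene_id", columns="tissue", values="count", aggfunc="sum", fill_value=0
    )


def family_expression_level(
    counts: pd.DataFrame,
    family_map: dict[str, str],
    pseudogenes: set[str] | None = None,
) -> dict[str, float]:
    """Per-family expression level: family average over network total.

    ``counts`` is genes x tissues; ``family_map`` maps each gene id to its
    family; genes listed in ``pseudogenes`` are dropped from the family-size
    denominator.  Raises if the network total is zero.
    """
    pseudogenes = pseudogenes or set()
    known = [g for g in counts.index if g in family_map]
    totals = counts.loc[known].sum(axis=1)
    network_total = float(totals.sum())
    if network_total <= 0:
        raise ValueError("network total expression is zero; levels undefined")
    levels: dict[str, float] = {}
    families = sorted(set(family_map[g] for g in known))
    for fam in families:
        members = [g for g in known if family_map[g] == fam]
        expressed = [g for g in members if g not in pseudogenes]
        if not expressed:
            levels[fam] = 0.0
            continue
        fam_total = float(totals.loc[expressed].sum())
        levels[fam] = (fam_total / len(expressed)) / network_total
    return levels


def tissue_matrix(
    counts: pd.DataFrame,
    transform: str = "none",
    annotation: OrganismAnnotation | None = None,
) -> pd.DataFrame:
    """Gene x tissue matrix ready for heatmap export.

    Rows follow chromosomal order when an annotation is supplied, otherwise
    the input order.  ``transform`` is ``none`` (raw counts) or ``log1p``.
    """
    if transform not in ("none", "log1p"):
        raise ValueError(f"unknown transform {transform!r}")
    mat = counts.copy()
    if annotation is not None:
        order = [
            g.gene_id for g in annotation.sorted_genes() if g.gene_id in mat.index
        ]
        rest = [g for g in mat.index if g not in set(order)]
        mat = mat.loc[order + rest]
    if transform == "log1p":
        mat = np.log1p(mat)
    return mat
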