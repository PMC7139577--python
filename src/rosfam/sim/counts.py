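"""Simulated EST/RNA-seq read counts per gene and tissue."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .birthdeath import Inventory

DEFAULT_TISSUES = (
    "root_phloem",
    "immature_xylem",
    "root",
    "mature_leaf",
    "young_leaf",
    "shoot_tip",
    "flower",
)


def negative_binomial_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size
) -> np.ndarray:
    """NB draws with mean ``mean`` and variance ``mean + mean**2/dispersion``.

    As dispersion grows the distribution converges to Poisson(mean).
    """
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if mean == 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_est_counts(
    inventories: dict[str, Inventory],
    mean_depth: float,
    dispersion: float,
    tissue_labels=DEFAULT_TISSUES,
    seed: int | np.random.SeedSequence = 0,
    gene_means: dict[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Negative-binomial counts per expressed gene per tissue.

    Pseudogenes get zero counts in every tissue (they are not transcribed
    into the EST pool); all other genes draw independently per tissue around
    ``mean_depth`` (or a per-gene mean from ``gene_means``).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}
    for org in sorted(inventories):
        inv = inventories[org]
        ids = sorted(inv.genes)
        rows = np.zeros((len(ids), len(tissue_labels)), dtype=int)
        for i, gid in enumerate(ids):
            if inv.genes[gid].status == "pseudogene":
                continue
            m = gene_means.get(gid, mean_depth) if gene_means else mean_depth
            rows[i] = negative_binomial_counts(rng, m, dispersion, len(tissue_labels))
        tables[org] = pd.DataFrame(rows, index=ids, columns=list(tissue_labels))
    return tables
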