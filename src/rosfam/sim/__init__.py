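"""Synthetic-data generation: species tree, birth–death gene families,
codon sequences, expression counts, and file emission.

The default configuration emulates the study system: four closely related
genomes splitting 0.15 / 0.89 / 1.27 MYA (plus a distant calibration
outgroup at 112 MYA), eleven ROS families with contrasting dynamics — one
large, duplication-rich class III peroxidase family with tandem arrays and
many pseudogenes, a handful of mid-sized families, and stable single/low-copy
families — with tandem-clustered paralogs, pseudogenes and incomplete
(N-containing) gene models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genes import OrganismAnnotation
from .birthdeath import (
    EventRecord,
    FamilyParams,
    Inventory,
    SimulationResult,
    replay_event_log,
    simulate_family_evolution,
)
from .counts import DEFAULT_TISSUES, simulate_est_counts
from .emit import build_annotations, emit_dataset
from .fixtures import LadderTruth, simulate_tandem_ladder
from .seqevo import evolve_seq, evolve_sequences, mark_pseudogene, random_cds
from .species import (
    DEFAULT_ORGANISMS,
    DEFAULT_SPLIT_AGES,
    SpeciesTree,
    ingroup_tree,
    simulate_species_history,
)

__all__ = [
    "EventRecord",
    "FamilyParams",
    "Inventory",
    "SimulationResult",
    "replay_event_log",
    "simulate_family_evolution",
    "simulate_est_counts",
    "DEFAULT_TISSUES",
    "build_annotations",
    "emit_dataset",
    "LadderTruth",
    "simulate_tandem_ladder",
    "evolve_seq",
    "evolve_sequences",
    "mark_pseudogene",
    "random_cds",
    "DEFAULT_ORGANISMS",
    "DEFAULT_SPLIT_AGES",
    "SpeciesTree",
    "ingroup_tree",
    "simulate_species_history",
    "default_family_params",
    "simulate_dataset",
    "DatasetBundle",
]


def default_family_params() -> list[FamilyParams]:
    """Study-condition defaults for the 11 families.

    Sizes mirror the published per-organism family sizes (CIII Prx ~170–190,
    Kat ~14, GPx ~10, APx ~10, Rboh 7, PrxII 3, APx-R 2, singletons for
    2CysPrx/DiOx/PrxQ, 1CysPrx ~4); duplication-rich families get nonzero
    birth/death/pseudogenization rates and tandem arrays at the root,
    conserved families are static.  Rates are in events/gene/MY on the
    ingroup timescale (root 1.27 MYA).
    """
    return [
        FamilyParams(
            "CIII Prx",
            initial_copies=170,
            dup_rate=0.03,
            loss_rate=0.05,
            pseudo_rate=0.05,
            tandem_prob=0.7,
            initial_tandem_arrays=(8, 8, 9, 12, 6),
            initial_pseudo_frac=0.25,
        ),
        FamilyParams(
            "Kat",
            initial_copies=13,
            dup_rate=0.02,
            loss_rate=0.02,
            pseudo_rate=0.05,
            tandem_prob=0.7,
            initial_tandem_arrays=(3, 4),
            initial_pseudo_frac=0.4,
        ),
        FamilyParams(
            "1CysPrx",
            initial_copies=4,
            dup_rate=0.05,
            loss_rate=0.02,
            pseudo_rate=0.1,
            tandem_prob=0.8,
            initial_tandem_arrays=(2,),
            initial_pseudo_frac=0.4,
        ),
        FamilyParams(
            "GPx", initial_copies=10, dup_rate=0.01, loss_rate=0.02, pseudo_rate=0.05,
            initial_pseudo_frac=0.2,
        ),
        FamilyParams("APx", initial_copies=10, loss_rate=0.01, pseudo_rate=0.02,
                     initial_pseudo_frac=0.3),
        FamilyParams("APx-R", initial_copies=2, initial_pseudo_frac=0.3),
        FamilyParams("Rboh", initial_copies=7),
        FamilyParams("PrxII", initial_copies=3),
        FamilyParams("2CysPrx", initial_copies=1),
        FamilyParams("PrxQ", initial_copies=1),
        FamilyParams("DiOx", initial_copies=1),
    ]


@dataclass
class DatasetBundle:
    """Everything one simulated comparative dataset comprises."""

    tree: SpeciesTree
    results: list[SimulationResult]
    sequences: list[dict[str, dict[str, str]]]
    annotations: dict[str, OrganismAnnotation]
    counts: dict[str, pd.DataFrame]

    def truth_presence(self) -> dict[str, dict[str, str]]:
        """``{gene_id: {organism: status}}`` over all families."""
        out: dict[str, dict[str, str]] = {}
        for res in self.results:
            for org, inv in res.inventories.items():
                for gid, gene in inv.genes.items():
                    out.setdefault(gid, {})[org] = gene.status
        return out


def simulate_dataset(
    seed: int | np.random.SeedSequence,
    tree: SpeciesTree | None = None,
    family_params: list[FamilyParams] | None = None,
    mean_depth: float = 50.0,
    dispersion: float = 5.0,
    partial_prob: float = 0.05,
    pcr_prob: float = 0.05,
    out_dir=None,
) -> DatasetBundle:
    """Simulate the full multi-family comparative dataset.

    One hierarchical seed drives every stage (family histories, sequences,
    counts, layout) so the bundle is fully reproducible.  If ``out_dir`` is
    given the dataset is also written to disk via :func:`emit_dataset`.
    """
    tree = tree or ingroup_tree()
    family_params = family_params or default_family_params()
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    fam_seeds = ss.spawn(len(family_params))
    results: list[SimulationResult] = []
    sequences: list[dict[str, dict[str, str]]] = []
    for params, fs in zip(family_params, fam_seeds):
        sub = fs.spawn(2)
        res = simulate_family_evolution(tree, params, sub[0])
        results.append(res)
        sequences.append(evolve_sequences(res, sub[1], partial_prob=partial_prob))
    layout_seed, counts_seed, emit_seed = ss.spawn(3)
    annotations = build_annotations(results, sequences, layout_seed, pcr_prob=pcr_prob)
    merged_inventories: dict[str, Inventory] = {}
    for res in results:
        for org, inv in res.inventories.items():
            m = merged_inventories.setdefault(org, Inventory())
            for gid, gene in inv.genes.items():
                m.genes[gid] = gene
    counts = simulate_est_counts(
        merged_inventories, mean_depth, dispersion, DEFAULT_TISSUES, counts_seed
    )
    bundle = DatasetBundle(
        tree=tree,
        results=results,
        sequences=sequences,
        annotations=annotations,
        counts=counts,
    )
    if out_dir is not None:
        emit_dataset(annotations, out_dir, counts=counts, results=results, seed=emit_seed)
    return bundle
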