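"""Forward birth–death simulation of a gene family along a species tree.

Each gene on a branch carries exponential-rate hazards for duplication
(lambda), loss (mu) and — for complete genes — pseudogenization (psi), all in
events/gene/MY.  Events are drawn Gillespie-style branch by branch; at a
speciation node the whole inventory is copied into both daughter lineages.
A duplicate is inserted adjacent to its parent with probability
``tandem_prob`` (a tandem duplication, 10 kb from its parent), otherwise at
a uniformly random dispersed position (20 kb gaps).  Every event is appended
to an :class:`EventLog` that doubles as ground truth for recovery tests:
replaying the log from the root inventory reproduces the leaf inventories
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..families import FAMILY_ABBREV, check_family
from .species import SpeciesTree, TreeNode

TANDEM_GAP = 10_000  # bp between a tandem duplicate and its parent
DISPERSED_GAP = 20_000  # bp before a dispersed gene


@dataclass
class FamilyParams:
    """Generative parameters for one gene family.

    Rates are per gene per MY; ``omega`` is the nonsynonymous/synonymous
    acceptance ratio of the sequence process (the generative analogue of
    Ka/Ks); ``clock_rate`` is in candidate substitutions/site/MY.
    """

    family_name: str = "CIII Prx"
    initial_copies: int = 1
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    pseudo_rate: float = 0.0
    tandem_prob: float = 0.5
    clock_rate: float = 0.002
    omega: float = 0.2
    n_codons: int = 333
    initial_tandem_arrays: tuple[int, ...] = ()
    initial_pseudo_frac: float = 0.0

    def __post_init__(self) -> None:
        check_family(self.family_name)
        for r in (self.dup_rate, self.loss_rate, self.pseudo_rate, self.clock_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not 0.0 <= self.tandem_prob <= 1.0:
            raise ValueError("tandem_prob must be in [0, 1]")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if sum(self.initial_tandem_arrays) > self.initial_copies:
            raise ValueError("tandem arrays exceed initial_copies")


@dataclass
class SimGene:
    gene_id: str
    family: str
    status: str = "complete"  # complete | pseudogene (partials arise later)


@dataclass
class Inventory:
    """Gene content of one lineage: genes plus their chromosomal layout.

    ``order[chrom]`` lists gene ids left to right; ``gap_before[gene]`` is
    the bp gap separating a gene from its left neighbour (or chromosome
    start), which fixes coordinates at emission time.
    """

    genes: dict[str, SimGene] = field(default_factory=dict)
    order: dict[str, list[str]] = field(default_factory=dict)
    gap_before: dict[str, int] = field(default_factory=dict)

    def copy(self) -> "Inventory":
        return Inventory(
            genes={k: replace(v) for k, v in self.genes.items()},
            order={c: list(g) for c, g in self.order.items()},
            gap_before=dict(self.gap_before),
        )

    def chromosome_of(self, gene_id: str) -> str:
        for chrom, ids in self.order.items():
            if gene_id in ids:
                return chrom
        raise KeyError(gene_id)

    def add_gene(
        self, gene: SimGene, chromosome: str, index: int, gap: int
    ) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"gene id collision: {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        self.order.setdefault(chromosome, []).insert(index, gene.gene_id)
        self.gap_before[gene.gene_id] = gap

    def insert_tandem(self, parent_id: str, child: SimGene) -> tuple[str, int]:
        chrom = self.chromosome_of(parent_id)
        idx = self.order[chrom].index(parent_id) + 1
        self.add_gene(child, chrom, idx, TANDEM_GAP)
        return chrom, idx

    def remove(self, gene_id: str) -> None:
        del self.genes[gene_id]
        chrom = self.chromosome_of(gene_id)
        self.order[chrom].remove(gene_id)
        del self.gap_before[gene_id]

    def size(self) -> int:
        return len(self.genes)


@dataclass
class EventRecord:
    event_kind: str  # duplication | loss | pseudogenization | speciation
    branch: str  # label of the tree node whose subtending branch hosts it
    time: float  # MYA; decreases toward the present
    parent_gene: str | None = None
    child_gene: str | None = None
    # placement details so the log is a replayable audit
    chromosome: str | None = None
    index: int | None = None
    tandem: bool | None = None


EventLog = list  # list[EventRecord], ordered with times decreasing


@dataclass
class SimulationResult:
    tree: SpeciesTree
    params: FamilyParams
    root_inventory: Inventory
    inventories: dict[str, Inventory]  # per leaf organism
    event_log: list[EventRecord]


def _make_root_inventory(
    params: FamilyParams, rng: np.random.Generator, n_chromosomes: int, counter: list[int]
) -> Inventory:
    tag = FAMILY_ABBREV[params.family_name]
    inv = Inventory()
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    for c in chroms:
        inv.order[c] = []

    def new_gene() -> SimGene:
        counter[0] += 1
        status = "pseudogene" if rng.random() < params.initial_pseudo_frac else "complete"
        return SimGene(gene_id=f"{tag}g{counter[0]:04d}", family=params.family_name, status=status)

    # tandem arrays first, each on a random chromosome, then dispersed singles
    for size in params.initial_tandem_arrays:
        chrom = chroms[rng.integers(len(chroms))]
        first = new_gene()
        inv.add_gene(first, chrom, len(inv.order[chrom]), DISPERSED_GAP)
        prev = first.gene_id
        for _ in range(size - 1):
            g = new_gene()
            inv.insert_tandem(prev, g)
            prev = g.gene_id
    for _ in range(params.initial_copies - sum(params.initial_tandem_arrays)):
        chrom = chroms[rng.integers(len(chroms))]
        g = new_gene()
        inv.add_gene(g, chrom, rng.integers(len(inv.order[chrom]) + 1), DISPERSED_GAP)
    return inv


def _apply_duplication(
    inv: Inventory,
    parent_id: str,
    child: SimGene,
    tandem: bool,
    rng: np.random.Generator,
) -> tuple[str, int]:
    if tandem:
        return inv.insert_tandem(parent_id, child)
    chroms = sorted(inv.order)
    chrom = chroms[rng.integers(len(chroms))]
    idx = int(rng.integers(len(inv.order[chrom]) + 1))
    inv.add_gene(child, chrom, idx, DISPERSED_GAP)
    return chrom, idx


def _evolve_branch(
    inv: Inventory,
    node: TreeNode,
    params: FamilyParams,
    rng: np.random.Generator,
    log: list[EventRecord],
    counter: list[int],
) -> None:
    tag = FAMILY_ABBREV[params.family_name]
    t = node.parent.age
    while True:
        ids = sorted(inv.genes)
        if not ids:
            return
        hazards = np.array(
            [
                params.dup_rate
                + params.loss_rate
                + (params.pseudo_rate if inv.genes[g].status == "complete" else 0.0)
                for g in ids
            ]
        )
        total = float(hazards.sum())
        if total == 0.0:
            return
        t = t - rng.exponential(1.0 / total)
        if t <= node.age:
            return
        gid = ids[rng.choice(len(ids), p=hazards / total)]
        gene = inv.genes[gid]
        psi = params.pseudo_rate if gene.status == "complete" else 0.0
        u = rng.random() * (params.dup_rate + params.loss_rate + psi)
        if u < params.dup_rate:
            counter[0] += 1
            child = SimGene(
                gene_id=f"{tag}g{counter[0]:04d}",
                family=params.family_name,
                status=gene.status,
            )
            tandem = bool(rng.random() < params.tandem_prob)
            chrom, idx = _apply_duplication(inv, gid, child, tandem, rng)
            log.append(
                EventRecord(
                    "duplication", node.label, t, gid, child.gene_id, chrom, idx, tandem
                )
            )
        elif u < params.dup_rate + params.loss_rate:
            inv.remove(gid)
            log.append(EventRecord("loss", node.label, t, gid, None))
        else:
            gene.status = "pseudogene"
            log.append(EventRecord("pseudogenization", node.label, t, gid, None))


def simulate_family_evolution(
    tree: SpeciesTree,
    params: FamilyParams,
    seed: int | np.random.SeedSequence,
    n_chromosomes: int = 3,
) -> SimulationResult:
    """Simulate one family's gain/loss/pseudogenization history on ``tree``.

    Returns per-organism inventories plus the complete, replayable event log.
    With all rates zero every organism inherits the root inventory unchanged
    and the log holds only speciation records.
    """
    rng = np.random.default_rng(seed)
    counter = [0]
    root_inv = _make_root_inventory(params, rng, n_chromosomes, counter)
    log: list[EventRecord] = []
    inventories: dict[str, Inventory] = {}

    def recurse(node: TreeNode, inv: Inventory) -> None:
        if node.parent is not None:
            _evolve_branch(inv, node, params, rng, log, counter)
        if node.is_leaf:
            inventories[node.label] = inv
            return
        log.append(EventRecord("speciation", node.label, node.age))
        for child in node.children:
            recurse(child, inv.copy())

    recurse(tree.root, root_inv.copy())
    return SimulationResult(
        tree=tree,
        params=params,
        root_inventory=root_inv,
        inventories=inventories,
        event_log=log,
    )


def replay_event_log(result: SimulationResult) -> dict[str, Inventory]:
    """Re-derive the leaf inventories by replaying the event log.

    Independent audit of the forward simulation: starts from the recorded
    root inventory and applies each branch's events (placement details
    included) down the tree.
    """
    by_branch: dict[str, list[EventRecord]] = {}
    for ev in result.event_log:
        if ev.event_kind != "speciation":
            by_branch.setdefault(ev.branch, []).append(ev)
    for evs in by_branch.values():
        evs.sort(key=lambda e: -e.time)

    leaves: dict[str, Inventory] = {}

    def recurse(node: TreeNode, inv: Inventory) -> None:
        if node.parent is not None:
            for ev in by_branch.get(node.label, []):
                if ev.event_kind == "duplication":
                    child = SimGene(
                        gene_id=ev.child_gene,
                        family=result.params.family_name,
                        status=inv.genes[ev.parent_gene].status,
                    )
                    gap = TANDEM_GAP if ev.tandem else DISPERSED_GAP
                    inv.add_gene(child, ev.chromosome, ev.index, gap)
                elif ev.event_kind == "loss":
                    inv.remove(ev.parent_gene)
                elif ev.event_kind == "pseudogenization":
                    inv.genes[ev.parent_gene].status = "pseudogene"
        if node.is_leaf:
            leaves[node.label] = inv
            return
        for child in node.children:
            recurse(child, inv.copy())

    recurse(result.tree.root, result.root_inventory.copy())
    return leaves
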