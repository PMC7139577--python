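"""Cross-species ortholog matching and presence/absence accounting.

Orthologs are identified as reciprocal best hits (RBH) by percent sequence
identity within the same family — protein identity for genes with an intact
reading frame, CDS identity when a pseudogene is involved.  The per-group
presence/absence matrix across organisms drives the Venn decomposition,
pairwise gain/loss counts, and the classification of genes missed in one
organism by the positional (tandem-cluster member vs singleton) and
functional (pseudogene) context of their orthologs elsewhere.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align

from .genes import GeneModel, OrganismAnnotation

PRESENT_STATUSES = ("complete", "partial", "pseudogene")
MISSED = "missed"


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    identity: float  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage")


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -0.5


def percent_identity(a: str, b: str) -> float:
    """Percent identity between two sequences.

    Equal-length sequences (the indel-free simulator case) are compared
    site-by-site; unequal lengths fall back to global pairwise alignment
    with affine penalties, identity over alignment columns.
    """
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        xa = np.frombuffer(a.encode(), dtype=np.uint8)
        xb = np.frombuffer(b.encode(), dtype=np.uint8)
        return 100.0 * float((xa == xb).mean())
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def _comparison_seq(g: GeneModel, other_is_pseudo: bool) -> str:
    if g.status == "pseudogene" or other_is_pseudo:
        return g.cds
    return g.protein or g.cds


def pair_identity(a: GeneModel, b: GeneModel) -> float:
    """Identity between two gene models: protein-based, CDS if a pseudogene
    is involved (pseudogenes have no reliable translation)."""
    pseudo = a.status == "pseudogene" or b.status == "pseudogene"
    return percent_identity(_comparison_seq(a, pseudo), _comparison_seq(b, pseudo))


def _identity_matrix(genes_a: list[GeneModel], genes_b: list[GeneModel]) -> np.ndarray:
    m = np.zeros((len(genes_a), len(genes_b)))
    for i, ga in enumerate(genes_a):
        for j, gb in enumerate(genes_b):
            m[i, j] = pair_identity(ga, gb)
    return m


def match_orthologs(
    annot_a: OrganismAnnotation,
    annot_b: OrganismAnnotation,
    min_identity: float = 70.0,
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two organisms.

    Matching is restricted to genes of the same family; pairs below
    ``min_identity`` percent are discarded; each gene joins at most one
    pair.  Identity ties (e.g. a freshly duplicated paralog still identical
    to the true ortholog) are broken by conserved gene order: the candidate
    whose positional rank within the family is closest to the query's rank
    wins — closely related genomes retain synteny — with the
    lexicographically smaller gene id as the final deterministic tie-break.
    """
    pairs: list[OrthologPair] = []
    families = sorted(
        {g.family for g in annot_a.genes} & {g.family for g in annot_b.genes}
    )
    for family in families:
        ga = annot_a.by_family(family)  # positional order
        gb = annot_b.by_family(family)
        if not ga or not gb:
            continue
        m = _identity_matrix(ga, gb)

        def best(row: np.ndarray, rank: int, others: list[GeneModel]) -> int:
            top = row.max()
            ties = [j for j in range(len(row)) if row[j] >= top - 1e-9]
            return min(ties, key=lambda j: (abs(j - rank), others[j].gene_id))

        best_b = [best(m[i, :], i, gb) for i in range(len(ga))]
        best_a = [best(m[:, j], j, ga) for j in range(len(gb))]
        for i, j in enumerate(best_b):
            if best_a[j] == i and m[i, j] >= min_identity:
                pairs.append(
                    OrthologPair(ga[i].gene_id, gb[j].gene_id, float(m[i, j]))
                )
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


GainLoss = namedtuple("GainLoss", "gained lost common")


class PresenceMatrix:
    """Ortholog groups (rows) by organisms (columns).

    Cells hold the member's status (``complete`` / ``partial`` /
    ``pseudogene``) or ``missed``.  ``members[group][organism]`` gives the
    gene id backing each non-missed cell; every row has at least one
    non-missed cell.
    """

    def __init__(
        self,
        organisms: list[str],
        reference: str,
        rows: dict[str, dict[str, GeneModel]],
    ) -> None:
        self.organisms = list(organisms)
        self.reference = reference
        self.members: dict[str, dict[str, str]] = {}
        self.family: dict[str, str] = {}
        data = {}
        for group in sorted(rows):
            cells = rows[group]
            if not cells:
                raise ValueError(f"group {group} has no members")
            self.members[group] = {o: g.gene_id for o, g in cells.items()}
            self.family[group] = next(iter(cells.values())).family
            data[group] = {
                o: (cells[o].status if o in cells else MISSED) for o in organisms
            }
        self.df = pd.DataFrame.from_dict(data, orient="index")[self.organisms]

    @property
    def groups(self) -> list[str]:
        return list(self.df.index)

    def rows_for_family(self, family_filter: str | None) -> pd.DataFrame:
        if family_filter is None:
            return self.df
        keep = [g for g in self.df.index if self.family[g] == family_filter]
        return self.df.loc[keep]

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "family", [self.family[g] for g in out.index])
        out.to_csv(path, sep="\t", index_label="group")


def build_presence_matrix(
    annotations: dict[str, OrganismAnnotation],
    reference: str,
    min_identity: float = 70.0,
    ortholog_map: dict[str, str] | None = None,
) -> PresenceMatrix:
    """Build the ortholog presence/absence matrix across all organisms.

    Each non-reference organism is RBH-matched against the reference; genes
    matching a reference gene join that gene's group.  Unmatched genes are
    reconciled transitively among the non-reference organisms (pairs taken
    in decreasing identity order; a union that would put two genes of the
    same organism in one group is skipped, so conflicts resolve to the
    highest identity).  Alternatively ``ortholog_map`` (gene id -> group
    name, e.g. a simulator truth table) can bypass sequence matching.
    """
    if reference not in annotations:
        raise ValueError(f"reference organism {reference!r} not in annotations")
    organisms = sorted(annotations)
    rows: dict[str, dict[str, GeneModel]] = {}

    if ortholog_map is not None:
        for org in organisms:
            for g in annotations[org].genes:
                group = ortholog_map.get(g.gene_id, g.gene_id)
                rows.setdefault(group, {})
                if org in rows[group]:
                    raise ValueError(
                        f"ortholog_map places two {org} genes in group {group}"
                    )
                rows[group][org] = g
        return PresenceMatrix(organisms, reference, rows)

    ref_ann = annotations[reference]
    group_of: dict[tuple[str, str], str] = {}
    for g in ref_ann.genes:
        rows[g.gene_id] = {reference: g}
        group_of[(reference, g.gene_id)] = g.gene_id
    for org in organisms:
        if org == reference:
            continue
        for p in match_orthologs(ref_ann, annotations[org], min_identity):
            rows[p.gene_a][org] = annotations[org].by_id(p.gene_b)
            group_of[(org, p.gene_b)] = p.gene_a

    # transitive reconciliation of genes unmatched to the reference
    leftovers = {
        org: [g for g in annotations[org].genes if (org, g.gene_id) not in group_of]
        for org in organisms
        if org != reference
    }
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for org, genes in leftovers.items():
        for g in genes:
            parent[(org, g.gene_id)] = (org, g.gene_id)
    candidate_pairs: list[tuple[float, tuple[str, str], tuple[str, str]]] = []
    nonref = [o for o in organisms if o != reference]
    for oa, ob in combinations(nonref, 2):
        sub_a = OrganismAnnotation(oa, leftovers[oa])
        sub_b = OrganismAnnotation(ob, leftovers[ob])
        for p in match_orthologs(sub_a, sub_b, min_identity):
            candidate_pairs.append((p.identity, (oa, p.gene_a), (ob, p.gene_b)))
    candidate_pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    comp_orgs: dict[tuple[str, str], set[str]] = {
        k: {k[0]} for k in parent
    }
    for _, ka, kb in candidate_pairs:
        ra, rb = find(ka), find(kb)
        if ra == rb or comp_orgs[ra] & comp_orgs[rb]:
            continue  # conflict: keep the higher-identity pairing
        parent[rb] = ra
        comp_orgs[ra] |= comp_orgs.pop(rb)
    clusters: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for k in parent:
        clusters.setdefault(find(k), []).append(k)
    for members in clusters.values():
        members.sort()
        group = members[0][1]
        if group in rows:
            group = f"{group}@{members[0][0]}"
        rows[group] = {
            org: annotations[org].by_id(gid) for org, gid in members
        }
    return PresenceMatrix(organisms, reference, rows)


def venn_counts(
    matrix: PresenceMatrix, family_filter: str | None = None
) -> dict[tuple[str, ...], int]:
    """Counts per region of the 4-set Venn over presence patterns.

    Keys are sorted tuples of the organisms a row is present in (15 regions);
    values always partition the (filtered) row set.
    """
    if len(matrix.organisms) != 4:
        raise ValueError("Venn decomposition requires exactly 4 organisms")
    df = matrix.rows_for_family(family_filter)
    counts: dict[tuple[str, ...], int] = {}
    orgs = sorted(matrix.organisms)
    for r in range(1, 5):
        for combo in combinations(orgs, r):
            counts[combo] = 0
    for _, row in df.iterrows():
        present = tuple(sorted(o for o in orgs if row[o] != MISSED))
        counts[present] += 1
    return counts


def pairwise_gain_loss(
    matrix: PresenceMatrix,
    org_x: str,
    org_y: str,
    family_filter: str | None = None,
) -> GainLoss:
    """Presence-pattern comparison of two organisms.

    gained = present in x / missed in y; lost = the reverse; common =
    present in both.  Reported neutrally as patterns, not polarized events —
    without an outgroup one cannot tell a gain in x from a loss in y.
    """
    for o in (org_x, org_y):
        if o not in matrix.organisms:
            raise ValueError(f"organism {o!r} not in matrix")
    df = matrix.rows_for_family(family_filter)
    px = df[org_x] != MISSED
    py = df[org_y] != MISSED
    return GainLoss(
        gained=int((px & ~py).sum()),
        lost=int((~px & py).sum()),
        common=int((px & py).sum()),
    )


@dataclass(frozen=True)
class MissedGeneCall:
    group: str
    organism: str  # the organism missing the gene
    positional_class: str  # cluster_member | singleton
    status_class: str  # all_pseudogene | none_pseudogene | mixed


def classify_missed_gene(
    group: str,
    matrix: PresenceMatrix,
    clusters_per_organism: dict[str, list],
    organism: str | None = None,
) -> MissedGeneCall:
    """Classify one missed gene by its orthologs in the other organisms.

    ``positional_class`` is ``cluster_member`` if the ortholog sits inside a
    detected tandem cluster in at least one organism where it is present,
    else ``singleton``.  ``status_class`` summarizes the present orthologs'
    statuses: all pseudogenes, none, or mixed.  Both classes are derived
    only from organisms where the gene is present.
    """
    row = matrix.df.loc[group]
    missing = [o for o in matrix.organisms if row[o] == MISSED]
    present = [o for o in matrix.organisms if row[o] != MISSED]
    if not present:
        raise ValueError(f"group {group} is missed everywhere; cannot classify")
    if not missing:
        raise ValueError(f"group {group} has no missed cell")
    organism = organism or missing[0]
    if organism not in missing:
        raise ValueError(f"group {group} is not missed in {organism}")
    in_cluster = False
    for o in present:
        gid = matrix.members[group][o]
        for cluster in clusters_per_organism.get(o, []):
            if gid in cluster.members:
                in_cluster = True
                break
    statuses = {row[o] for o in present}
    if statuses == {"pseudogene"}:
        status_class = "all_pseudogene"
    elif "pseudogene" not in statuses:
        status_class = "none_pseudogene"
    else:
        status_class = "mixed"
    return MissedGeneCall(
        group=group,
        organism=organism,
        positional_class="cluster_member" if in_cluster else "singleton",
        status_class=status_class,
    )
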