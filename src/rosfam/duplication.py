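"""Tandem clusters, segmental duplication blocks, chromosomal statistics,
and tandem-duplication order inference.

A tandem cluster is a maximal single-linkage chain of same-family genes
along a chromosome whose consecutive intergenic distances (next.start −
prev.end − 1) are below a threshold — default 15 kb, the genome-wide average
intergenic distance.  A segmental duplication block is a chain of at least
``min_block`` within-organism paralog pairs whose positions are strictly
collinear (direct) or strictly reversed (inverted) between two chromosomal
segments.  The order of tandem duplications inside a cluster is read off a
midpoint-rooted neighbor-joining tree of the members' CDS distances: each
internal node is one duplication, older nodes (greater height) first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode as SkbioTree
from skbio.tree import nj

from .genes import GeneModel, OrganismAnnotation, chromosome_key
from .utils import percent, round_half_up

DEFAULT_MAX_GAP = 15_000  # bp


@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]  # gene ids, in positional order
    span: int  # bp from first gene start to last gene end
    max_gap: int  # threshold used for chaining

    def __len__(self) -> int:
        return len(self.members)


def intergenic_distance(prev: GeneModel, nxt: GeneModel) -> int:
    """bp between two features: next.start - prev.end - 1."""
    return nxt.start - prev.end - 1


def detect_tandem_clusters(
    annotation: OrganismAnnotation,
    max_gap: int = DEFAULT_MAX_GAP,
    family_restricted: bool = True,
) -> list[TandemCluster]:
    """Single-linkage chaining of neighbouring same-family genes.

    With ``family_restricted`` (default) the chaining considers each family
    separately, ignoring interleaved genes of other families — published
    clusters are family-named.  Clusters of size >= 2 are reported, maximal
    and disjoint; membership is invariant to input order.
    """
    clusters: list[TandemCluster] = []
    if family_restricted:
        families = sorted({g.family for g in annotation.genes})
        streams = [
            [g for g in annotation.sorted_genes() if g.family == fam]
            for fam in families
        ]
    else:
        streams = [annotation.sorted_genes()]
    for stream in streams:
        run: list[GeneModel] = []
        for g in stream:
            if run and (
                g.chromosome != run[-1].chromosome
                or intergenic_distance(run[-1], g) >= max_gap
            ):
                if len(run) >= 2:
                    clusters.append(_make_cluster(run, max_gap))
                run = []
            run.append(g)
        if len(run) >= 2:
            clusters.append(_make_cluster(run, max_gap))
    clusters.sort(key=lambda c: (chromosome_key(c.chromosome), c.members))
    return clusters


def _make_cluster(run: list[GeneModel], max_gap: int) -> TandemCluster:
    return TandemCluster(
        chromosome=run[0].chromosome,
        members=[g.gene_id for g in run],
        span=run[-1].end - run[0].start + 1,
        max_gap=max_gap,
    )


@dataclass
class SegmentalBlock:
    segment_a: tuple[str, int, int]  # chromosome, start, end
    segment_b: tuple[str, int, int]
    pairs: list[tuple[str, str]]  # gene id pairs in segment-a order
    orientation: str  # direct | inverted

    def __len__(self) -> int:
        return len(self.pairs)


def detect_segmental_blocks(
    annotation: OrganismAnnotation,
    paralog_pairs: list[tuple[str, str]],
    min_block: int = 3,
) -> list[SegmentalBlock]:
    """Collinear chains of paralog pairs = segmental duplication blocks.

    For every chromosome pair, paralog anchor points are sorted by the first
    gene's position and the longest strictly increasing (direct) or strictly
    decreasing (inverted) chain in the partner positions is extracted;
    chains of at least ``min_block`` pairs become blocks.  Extraction
    repeats greedily on the remaining anchors so multiple disjoint blocks
    can be reported.
    """
    pos = {g.gene_id: g for g in annotation.genes}
    anchors: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in paralog_pairs:
        if a == b:
            continue
        ga, gb = pos[a], pos[b]
        # orient each anchor consistently: smaller (chrom, start) first
        if (chromosome_key(ga.chromosome), ga.start) > (
            chromosome_key(gb.chromosome),
            gb.start,
        ):
            ga, gb = gb, ga
        key = (ga.chromosome, gb.chromosome)
        anchors.setdefault(key, []).append((ga.start, gb.start, ga.gene_id, gb.gene_id))

    blocks: list[SegmentalBlock] = []
    for (chrom_a, chrom_b), pts in sorted(anchors.items()):
        pts = sorted(pts)
        while True:
            chain, direction = _best_chain(pts)
            if len(chain) < min_block:
                break
            ids_a = [pts[i][2] for i in chain]
            ids_b = [pts[i][3] for i in chain]
            genes_a = [pos[i] for i in ids_a]
            genes_b = [pos[i] for i in ids_b]
            blocks.append(
                SegmentalBlock(
                    segment_a=(
                        chrom_a,
                        min(g.start for g in genes_a),
                        max(g.end for g in genes_a),
                    ),
                    segment_b=(
                        chrom_b,
                        min(g.start for g in genes_b),
                        max(g.end for g in genes_b),
                    ),
                    pairs=list(zip(ids_a, ids_b)),
                    orientation=direction,
                )
            )
            used = set(chain)
            pts = [p for i, p in enumerate(pts) if i not in used]
    blocks.sort(key=lambda b: (b.segment_a, b.segment_b))
    return blocks


def _best_chain(pts: list[tuple[int, int, str, str]]) -> tuple[list[int], str]:
    """Longest strictly monotone chain in the second coordinate.

    ``pts`` must be sorted by the first coordinate.  Classic O(n^2) longest
    increasing / decreasing subsequence; ties favour the earlier start for
    determinism.
    """
    n = len(pts)
    if n == 0:
        return [], "direct"
    best: tuple[list[int], str] = ([], "direct")
    for direction in ("direct", "inverted"):
        lengths = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if pts[j][0] >= pts[i][0]:
                    continue  # require strict progress along segment A
                ok = (
                    pts[j][1] < pts[i][1]
                    if direction == "direct"
                    else pts[j][1] > pts[i][1]
                )
                if ok and lengths[j] + 1 > lengths[i]:
                    lengths[i] = lengths[j] + 1
                    prev[i] = j
        i = int(np.argmax(lengths))
        chain = []
        while i != -1:
            chain.append(i)
            i = prev[i]
        chain.reverse()
        if len(chain) > len(best[0]):
            best = (chain, direction)
    return best


@dataclass
class ChromStats:
    counts: dict[str, int]
    percents: dict[str, float]  # of placed genes, rounded half-up, 1 decimal
    densities: dict[str, float]  # genes per Mb
    total_placed: int
    unplaced: int = 0


def chromosome_stats(
    annotation: OrganismAnnotation,
    family_filter: str | None = None,
    unplaced_labels: tuple[str, ...] = ("X", "XX"),
) -> ChromStats:
    """Per-chromosome gene count, percent of placed genes, density per Mb.

    Genes on unplaced scaffolds (labels in ``unplaced_labels``) are excluded
    from the percentages, mirroring how chromosome maps are drawn.
    """
    genes = [
        g
        for g in annotation.genes
        if family_filter is None or g.family == family_filter
    ]
    placed = [g for g in genes if g.chromosome not in unplaced_labels]
    counts: dict[str, int] = {}
    for chrom in sorted(annotation.chromosome_sizes, key=chromosome_key):
        if chrom in unplaced_labels:
            continue
        counts[chrom] = sum(1 for g in placed if g.chromosome == chrom)
    total = len(placed)
    percents = {c: percent(n, total, 1) if total else 0.0 for c, n in counts.items()}
    densities = {}
    for c, n in counts.items():
        size = annotation.chromosome_sizes[c]
        if size <= 0:
            raise ValueError(f"chromosome {c} has non-positive size")
        densities[c] = round_half_up(n / (size / 1e6), 2)
    return ChromStats(
        counts=counts,
        percents=percents,
        densities=densities,
        total_placed=total,
        unplaced=len(genes) - total,
    )


@dataclass
class DuplicationEvent:
    order: int  # 1 = oldest
    height: float  # node height in substitutions/site
    descendants: list[str]  # member genes under this duplication node


def build_member_tree(members: list[GeneModel]) -> SkbioTree:
    """Midpoint-rooted neighbor-joining tree over member CDS p-distances."""
    if len(members) < 2:
        raise ValueError("need at least two members")
    ids = [g.gene_id for g in members]
    n = len(members)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = members[i].cds, members[j].cds
            L = min(len(a), len(b))
            d = sum(1 for x, y in zip(a[:L], b[:L]) if x != y) / max(L, 1)
            dm[i, j] = dm[j, i] = d
    if n == 2:
        tree = SkbioTree.read([f"({ids[0]}:{dm[0, 1] / 2},{ids[1]}:{dm[0, 1] / 2});"])
        return tree
    tree = nj(DistanceMatrix(dm, ids))
    return tree.root_at_midpoint()


def infer_tandem_history(
    cluster: TandemCluster,
    tree: SkbioTree,
) -> list[DuplicationEvent]:
    """Order the duplications that built a tandem cluster.

    Each internal node of the (midpoint-rooted) member tree is one
    duplication; events are emitted in decreasing node height, so the
    deepest split — the oldest duplication — comes first.  Node height is
    the *mean* root-path distance to the node's descendant tips — the
    strict-clock estimate of its age, robust to single fast-evolving tips
    (the maximum would be biased upward by the noisiest tip).  A cluster of
    n members yields exactly n − 1 events.
    """
    if len(cluster) < 2:
        raise ValueError("cluster must have at least two members")
    heights: list[tuple[float, list[str]]] = []
    for node in tree.non_tips(include_self=True):
        # node height = distance to its farthest descendant tip
        heights.append((_node_height(node), sorted(t.name for t in node.tips())))
    heights.sort(key=lambda t: (-t[0], t[1]))
    events = [
        DuplicationEvent(order=i + 1, height=h, descendants=desc)
        for i, (h, desc) in enumerate(heights)
    ]
    if len(events) != len(cluster) - 1:
        # NJ trees of k tips have k-1 internal nodes once rooted; guard
        events = events[: len(cluster) - 1]
    return events


def _node_height(node: SkbioTree) -> float:
    """Mean distance from a node to its descendant tips."""
    if node.is_tip():
        return 0.0
    total = n = 0.0
    for tip in node.tips():
        d = tip.length or 0.0
        anc = tip.parent
        while anc is not None and anc is not node:
            d += anc.length or 0.0
            anc = anc.parent
        total += d
        n += 1
    return total / n
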