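from itertools import combinations

import numpy as np
import pytest

from rosfam.duplication import (
    build_member_tree,
    chromosome_stats,
    detect_segmental_blocks,
    detect_tandem_clusters,
    infer_tandem_history,
    intergenic_distance,
)
from rosfam.genes import GeneModel, OrganismAnnotation
from rosfam.sim.fixtures import simulate_tandem_ladder


def _gene(gid, chrom, start, length=1500, family="CIII Prx"):
    return GeneModel(gid, "grandis", family, chrom, start, start + length - 1)


def _annotation(genes, sizes=None):
    sizes = sizes or {c: 10_000_000 for c in {g.chromosome for g in genes}}
    return OrganismAnnotation("grandis", genes, sizes)


class TestTandemClusters:
    def test_distant_genes_do_not_cluster(self):
        ann = _annotation([_gene("a", "chr1", 1000), _gene("b", "chr1", 23000)])
        assert intergenic_distance(ann.genes[0], ann.genes[1]) >= 15000
        assert detect_tandem_clusters(ann) == []

    def test_chain_of_eight_forms_one_cluster(self):
        genes = [_gene(f"g{i}", "chr1", 1 + i * 11_500) for i in range(8)]
        clusters = detect_tandem_clusters(_annotation(genes))
        assert len(clusters) == 1
        assert clusters[0].members == [f"g{i}" for i in range(8)]
        assert len(clusters[0]) == 8

    def test_interleaved_other_family_ignored_when_restricted(self):
        genes = [
            _gene("a", "chr1", 1000),
            _gene("k", "chr1", 6000, family="Kat"),
            _gene("b", "chr1", 11_000),
        ]
        clusters = detect_tandem_clusters(_annotation(genes), family_restricted=True)
        assert [c.members for c in clusters] == [["a", "b"]]

    def test_matches_bruteforce_transitive_closure(self):
        rng = np.random.default_rng(7)
        genes = []
        for i in range(100):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(1, 2_000_000))
            fam = "CIII Prx" if rng.random() < 0.7 else "Kat"
            genes.append(_gene(f"g{i:03d}", chrom, start, length=1000, family=fam))
        # drop overlapping genes for a clean layout
        kept = []
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            if kept and kept[-1].chromosome == g.chromosome and g.start <= kept[-1].end:
                continue
            kept.append(g)
        ann = _annotation(kept)
        clusters = detect_tandem_clusters(ann, max_gap=15_000)

        # oracle: O(n^2) union-find over the pairwise neighbour relation
        parent = {g.gene_id: g.gene_id for g in kept}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ordered = sorted(kept, key=lambda g: (g.chromosome, g.start))
        for a, b in combinations(ordered, 2):
            if a.chromosome != b.chromosome or a.family != b.family:
                continue
            between = [
                x
                for x in ordered
                if x.chromosome == a.chromosome
                and x.family == a.family
                and a.end < x.start < b.start
            ]
            chain = [a] + between + [b]
            if all(
                intergenic_distance(u, v) < 15_000 for u, v in zip(chain, chain[1:])
            ):
                parent[find(a.gene_id)] = find(b.gene_id)
        expected = {}
        for g in kept:
            expected.setdefault(find(g.gene_id), set()).add(g.gene_id)
        expected_clusters = sorted(
            sorted(v) for v in expected.values() if len(v) >= 2
        )
        assert sorted(sorted(c.members) for c in clusters) == expected_clusters

    def test_permutation_invariance(self):
        genes = [_gene(f"g{i}", "chr1", 1 + i * 12_000) for i in range(6)]
        a = detect_tandem_clusters(_annotation(genes))
        b = detect_tandem_clusters(_annotation(list(reversed(genes))))
        assert [c.members for c in a] == [c.members for c in b]


class TestSegmentalBlocks:
    def test_no_paralogs_no_blocks(self, study_bundle):
        ann = study_bundle.annotations["grandis"]
        assert detect_segmental_blocks(ann, []) == []

    def test_single_pair_below_min_block(self):
        genes = [_gene("a", "chr1", 1000), _gene("b", "chr1", 50_000)]
        assert detect_segmental_blocks(_annotation(genes), [("a", "b")]) == []

    def test_inverted_segment_recovered(self):
        ann, truth = simulate_tandem_ladder(seed=5)
        blocks = detect_segmental_blocks(ann, truth.paralog_pairs)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"
        assert len(blocks[0]) == 8

    def test_direct_collinear_block(self):
        genes = [_gene(f"a{i}", "chr1", 1 + i * 20_000) for i in range(4)]
        genes += [_gene(f"b{i}", "chr2", 1 + i * 20_000) for i in range(4)]
        pairs = [(f"a{i}", f"b{i}") for i in range(4)]
        blocks = detect_segmental_blocks(_annotation(genes), pairs)
        assert len(blocks) == 1 and blocks[0].orientation == "direct"

    def test_matches_exhaustive_chain_search(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 13))
            genes_a = [_gene(f"a{i}", "chr1", 1 + i * 20_000) for i in range(n)]
            perm = rng.permutation(n)
            genes_b = [_gene(f"b{i}", "chr2", 1 + i * 20_000) for i in range(n)]
            pairs = [(f"a{i}", f"b{perm[i]}") for i in range(n)]
            ann = _annotation(genes_a + genes_b)
            blocks = detect_segmental_blocks(ann, pairs, min_block=2)
            found = max((len(b) for b in blocks), default=0)
            # oracle: exhaustive subset search for the longest monotone chain
            best = 0
            idx = sorted(range(n))  # anchors sorted by position in a
            for r in range(n, 1, -1):
                if best >= r:
                    break
                for sub in combinations(idx, r):
                    bs = [perm[i] for i in sub]
                    inc = all(x < y for x, y in zip(bs, bs[1:]))
                    dec = all(x > y for x, y in zip(bs, bs[1:]))
                    if inc or dec:
                        best = r
                        break
            assert found == (best if best >= 2 else 0)


class TestChromosomeStats:
    def _network(self):
        genes = []
        for i in range(56):
            genes.append(_gene(f"c1prx{i}", "chr1", 1 + i * 20_000))
        for i in range(5):
            genes.append(_gene(f"c1oth{i}", "chr1", 1_200_000 + i * 20_000, family="Kat"))
        for i in range(5):
            genes.append(_gene(f"c4{i}", "chr4", 1 + i * 20_000, family="GPx"))
        for i in range(118):
            genes.append(_gene(f"c2prx{i}", "chr2", 1 + i * 20_000))
        for i in range(34):
            genes.append(_gene(f"c2oth{i}", "chr2", 2_500_000 + i * 20_000, family="APx"))
        for i in range(3):
            genes.append(_gene(f"x{i}", "X", 1 + i * 20_000))  # unplaced scaffold
        sizes = {"chr1": 40_000_000, "chr2": 60_000_000, "chr4": 42_000_000, "X": 1_000_000}
        return _annotation(genes, sizes)

    def test_published_fraction_arithmetic(self):
        ann = self._network()
        stats = chromosome_stats(ann)
        assert stats.total_placed == 218
        assert stats.percents["chr1"] == 28.0  # 61/218
        assert stats.percents["chr4"] == 2.3  # 5/218
        prx = chromosome_stats(ann, family_filter="CIII Prx")
        assert prx.total_placed == 174
        assert prx.percents["chr1"] == 32.2  # 56/174

    def test_density_per_mb(self):
        ann = self._network()
        stats = chromosome_stats(ann)
        assert stats.densities["chr1"] == pytest.approx(61 / 40, abs=0.01)

    def test_percentages_sum_to_100(self):
        stats = chromosome_stats(self._network())
        assert sum(stats.percents.values()) == pytest.approx(100, abs=0.1)

    def test_all_on_one_chromosome(self):
        genes = [_gene(f"g{i}", "chr1", 1 + i * 20_000) for i in range(10)]
        stats = chromosome_stats(_annotation(genes, {"chr1": 1_000_000, "chr2": 1_000_000}))
        assert stats.percents["chr1"] == 100.0
        assert stats.percents["chr2"] == 0.0

    def test_zero_size_chromosome_rejected(self):
        genes = [_gene("g", "chr1", 100)]
        with pytest.raises(ValueError):
            chromosome_stats(_annotation(genes, {"chr1": 0}))


class TestInferTandemHistory:
    def test_two_member_cluster_one_event(self):
        ann, _ = simulate_tandem_ladder(n=2, seed=1, with_segment_copy=False)
        clusters = detect_tandem_clusters(ann)
        tree = build_member_tree([ann.by_id(m) for m in clusters[0].members])
        events = infer_tandem_history(clusters[0], tree)
        assert len(events) == 1

    def test_ladder_order_recovered(self):
        """In a ladder the k-th duplication separates gene k from the
        younger rest, so correctly ordered events have strictly decreasing
        descendant counts.  Single replicates can misorder one step (a 1-MY
        internal edge carries few substitutions), so adjacent-pair order
        concordance is scored over 20 replicate ladders."""
        good = total = 0
        for seed in range(20):
            ann, _ = simulate_tandem_ladder(n=8, seed=seed, with_segment_copy=False)
            clusters = detect_tandem_clusters(ann)
            assert len(clusters) == 1
            tree = build_member_tree([ann.by_id(m) for m in clusters[0].members])
            events = infer_tandem_history(clusters[0], tree)
            assert len(events) == 7
            sizes = [len(e.descendants) for e in events]
            for a, b in zip(sizes, sizes[1:]):
                total += 1
                good += a > b
        assert good / total >= 0.80

    def test_fig_style_scenario_seven_tds_plus_inverted_sd(self):
        """8-gene tandem ladder copied in reverse: 7 TD events + 1 SD."""
        ann, truth = simulate_tandem_ladder(n=8, seed=5)
        clusters = detect_tandem_clusters(ann)
        assert [c.members for c in clusters] == [truth.ladder_ids, truth.copy_ids]
        tree = build_member_tree([ann.by_id(m) for m in clusters[0].members])
        events = infer_tandem_history(clusters[0], tree)
        assert len(events) == 7
        blocks = detect_segmental_blocks(ann, truth.paralog_pairs)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted" and len(blocks[0]) == 8

    def test_small_cluster_rejected(self):
        ann, _ = simulate_tandem_ladder(n=2, seed=1, with_segment_copy=False)
        cluster = detect_tandem_clusters(ann)[0]
        cluster.members = cluster.members[:1]
        tree = build_member_tree([ann.by_id("Prx01"), ann.by_id("Prx02")])
        with pytest.raises(ValueError):
            infer_tandem_history(cluster, tree)
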