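import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosfam.genes import GeneModel, OrganismAnnotation, translate_cds
from rosfam.molevol import (
    SENSE_CODONS,
    KaKsResult,
    SaturationError,
    build_chimeric_alignment,
    classify_selection,
    date_divergences,
    jc_correct,
    ng86_kaks,
    pathway_differences,
    synonymous_sites,
)
from rosfam.orthologs import PresenceMatrix
from rosfam.sim import evolve_seq, random_cds

codon_strategy = st.sampled_from(SENSE_CODONS)


class TestPathwayDifferences:
    def test_single_synonymous_change(self):
        assert pathway_differences("TTT", "TTC") == (1.0, 0.0)

    def test_two_step_pathway_average(self):
        # TTT -> GTA via GTT (nonsyn + syn) or via TTA (nonsyn + nonsyn)
        assert pathway_differences("TTT", "GTA") == (0.5, 1.5)

    def test_identical_codons(self):
        assert pathway_differences("AAA", "AAA") == (0.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(codon_strategy, codon_strategy)
    def test_symmetry(self, a, b):
        assert pathway_differences(a, b) == pytest.approx(
            pathway_differences(b, a)
        )

    @settings(max_examples=100, deadline=None)
    @given(codon_strategy, codon_strategy)
    def test_total_differences_equal_hamming(self, a, b):
        sd, nd = pathway_differences(a, b)
        assert sd + nd == pytest.approx(sum(x != y for x, y in zip(a, b)))


class TestSiteCounts:
    def test_fourfold_degenerate_third_position(self):
        # GGx is Gly whatever x: third position fully synonymous
        assert synonymous_sites("GGG") == pytest.approx(1.0)

    def test_methionine_has_no_synonymous_site(self):
        assert synonymous_sites("ATG") == 0.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            synonymous_sites("TAA")


class TestNg86KaKs:
    def test_identical_sequences(self):
        r = ng86_kaks("ATGTTTGGTTAA", "ATGTTTGGTTAA")
        assert r.Sd == 0 and r.Nd == 0
        assert r.Ks == 0 and r.Ka == 0
        assert r.ratio is None  # undefined, not infinity

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(0)
        a = random_cds(rng, 200)
        b = evolve_seq(a, 20, 0.002, 0.5, rng)
        r = ng86_kaks(a, b)
        assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a = random_cds(rng, 150)
        b = evolve_seq(a, 30, 0.002, 0.5, rng)
        assert ng86_kaks(a, b) == ng86_kaks(b, a)

    def test_ambiguous_codons_skipped_in_both(self):
        a = "ATGTTTGGTGGTTAA"
        b = "ATGTTNGGAGGTTAA"
        r = ng86_kaks(a, b)
        assert r.n_codons == 3  # stop and the N-containing codon skipped
        assert r.Sd == 1.0  # the single GGT->GGA change

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            ng86_kaks("ATGTAA", "ATGGGGTAA")

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jc_correct(0.8)

    def test_agrees_with_independent_implementation(self):
        """Cross-check against Biopython's NG86 on a diverged pair; the
        conventions differ only in stop-codon site normalization."""
        rng = np.random.default_rng(1)
        root = random_cds(rng, 1000)
        a = evolve_seq(root, 30, 0.002, 0.5, rng)
        b = evolve_seq(root, 30, 0.002, 0.5, rng)
        r = ng86_kaks(a, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
            dn, ds = cal_dn_ds(CodonSeq(a[:-3]), CodonSeq(b[:-3]), method="NG86")
        assert r.Ka == pytest.approx(dn, rel=0.1)
        assert r.Ks == pytest.approx(ds, rel=0.1)


class TestClassifySelection:
    def _result(self, ratio):
        return KaKsResult(1, 2, 0, 0, 0, 0, 0.1, 0.1, ratio, 10)

    @pytest.mark.parametrize(
        "ratio, expected",
        [(0.2, "negative"), (1.0, "neutral"), (1.04, "neutral"),
         (1.2, "positive"), (None, "undefined")],
    )
    def test_rules(self, ratio, expected):
        assert classify_selection(self._result(ratio)) == expected


def _org(name, cds_by_gene, statuses=None):
    statuses = statuses or {}
    genes = []
    for i, (gid, cds) in enumerate(sorted(cds_by_gene.items())):
        status = statuses.get(gid, "complete")
        genes.append(
            GeneModel(
                gid, name, "APx", "chr1", 1 + i * 20_000, i * 20_000 + len(cds),
                status=status, cds=cds,
                protein="" if status == "pseudogene" else translate_cds(cds),
            )
        )
    return OrganismAnnotation(name, genes)


class TestChimericAlignment:
    ORGS = ["cam", "glo", "gra", "gun"]

    def _matrix(self, annotations):
        rows = {}
        for org, ann in annotations.items():
            for g in ann.genes:
                rows.setdefault(g.gene_id, {})[org] = g
        return PresenceMatrix(sorted(annotations), "gra", rows)

    def test_identical_organisms_concatenate_everything(self):
        cds = {"g1": "ATGGCTTAA", "g2": "ATGTGTTGTTAA", "g3": "ATGAAATAA"}
        anns = {o: _org(o, cds) for o in self.ORGS}
        chim = build_chimeric_alignment(anns, self._matrix(anns))
        total = sum(len(s) for s in cds.values())
        assert set(chim) == set(self.ORGS)
        assert all(len(s) == total for s in chim.values())
        assert len(set(chim.values())) == 1

    def test_pseudogenic_group_excluded(self):
        cds = {"g1": "ATGGCTTAA", "g2": "ATGTGTTGTTAA", "g3": "ATGAAATAA"}
        anns = {o: _org(o, cds) for o in self.ORGS}
        anns["gun"] = _org("gun", cds, statuses={"g2": "pseudogene"})
        chim = build_chimeric_alignment(anns, self._matrix(anns))
        assert all(len(s) == len(cds["g1"]) + len(cds["g3"]) for s in chim.values())

    def test_too_few_groups_rejected(self):
        cds = {"g1": "ATGGCTTAA"}
        anns = {o: _org(o, cds) for o in self.ORGS}
        with pytest.raises(ValueError):
            build_chimeric_alignment(anns, self._matrix(anns))

    def test_qualifying_count_matches_truth(self, study_bundle):
        from rosfam.orthologs import build_presence_matrix

        anns = study_bundle.annotations
        matrix = build_presence_matrix(anns, "grandis", ortholog_map={})
        truth = study_bundle.truth_presence()
        status_of = {
            (o, g.gene_id): g.status for o, a in anns.items() for g in a.genes
        }
        expected = sum(
            1
            for gid, orgs in truth.items()
            if set(orgs) == set(anns)
            and all(status_of[(o, gid)] == "complete" for o in orgs)
        )
        chim = build_chimeric_alignment(anns, matrix)
        n_groups = sum(
            1
            for g in matrix.groups
            if all(matrix.df.loc[g, o] == "complete" for o in matrix.organisms)
        )
        assert n_groups == expected
        assert len(set(len(s) for s in chim.values())) == 1


class TestDateDivergences:
    def _seqs(self, rng, rate=0.01, ages=(1, 2, 3, 10)):
        from rosfam.sim import FamilyParams, evolve_sequences, simulate_family_evolution, simulate_species_history

        tree = simulate_species_history(ages)
        p = FamilyParams(initial_copies=1, clock_rate=rate, omega=1.0, n_codons=3334)
        res = simulate_family_evolution(tree, p, seed=int(rng.integers(2**31)))
        seqs = evolve_sequences(res, seed=int(rng.integers(2**31)))
        return {org: next(iter(s.values())) for org, s in seqs.items()}

    def test_calibration_node_exact(self):
        rng = np.random.default_rng(0)
        dated = date_divergences(self._seqs(rng), "outgroup", calibration_age=10.0)
        assert dated.age_of("outgroup", "grandis") == 10.0
        assert dated.calibration_age == 10.0

    def test_identical_ingroup_split_at_zero(self):
        seqs = {
            "a": "ATGGCTGCTGCTTAA",
            "b": "ATGGCTGCTGCTTAA",
            "out": "ATGTCTACTGATTAA",
        }
        dated = date_divergences(seqs, "out", calibration_age=50.0)
        assert dated.age_of("a", "b") == 0.0

    def test_zero_outgroup_distance_rejected(self):
        seqs = {"a": "ATGGCTTAA", "b": "ATGGCTTAA", "out": "ATGGCTTAA"}
        with pytest.raises(ValueError):
            date_divergences(seqs, "out")

    def test_recovers_simulated_ages(self):
        rng = np.random.default_rng(5)
        dated = date_divergences(self._seqs(rng), "outgroup", calibration_age=10.0)
        assert dated.age_of("grandis", "globulus") == pytest.approx(1.0, rel=0.25)
        assert dated.age_of("grandis", "gunnii") == pytest.approx(2.0, rel=0.25)
        assert dated.age_of("grandis", "camaldulensis") == pytest.approx(3.0, rel=0.25)

    def test_newick_output(self):
        rng = np.random.default_rng(1)
        dated = date_divergences(self._seqs(rng), "outgroup", calibration_age=10.0)
        nwk = dated.newick()
        assert "outgroup" in nwk and nwk.rstrip().endswith(";")
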