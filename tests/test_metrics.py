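"""Identity, G+C, POCP, fragment ANI, MinHash distance and NJ trees."""

import math

import numpy as np
import pytest

from protoscribe.fixtures import make_genome, make_proteome_pair, mutate
from protoscribe.metrics import (
    AniResult,
    MetricError,
    PocpResult,
    Sketch,
    fragment_ani,
    gc_percent,
    jaccard_to_mash,
    mash_distance,
    nj_tree,
    pairwise_identity,
    pocp,
    sketch,
)
from protoscribe.seqio import SequenceRecord

SEED = 77


class TestGcPercent:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 50.0), ("GGCC", 100.0), ("AATT", 0.0)])
    def test_examples(self, seq, expected):
        assert gc_percent(SequenceRecord(id="x", seq=seq)) == expected

    def test_n_excluded_from_both_counts(self):
        assert gc_percent(SequenceRecord(id="x", seq="GCNN")) == 100.0

    def test_all_ambiguous_is_an_error(self):
        with pytest.raises(MetricError):
            gc_percent(SequenceRecord(id="x", seq="NNNN"))

    def test_matches_direct_base_count_oracle(self, genome_50k):
        seq = genome_50k.seq
        expected = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
        assert gc_percent(genome_50k) == pytest.approx(expected, abs=1e-12)

    def test_reverse_complement_invariance(self, genome_50k):
        assert gc_percent(genome_50k) == pytest.approx(
            gc_percent(genome_50k.reverse_complement()), abs=1e-12
        )

    def test_generator_hits_requested_gc(self, genome_50k):
        # 3 binomial SDs at n = 50 kb
        sd = 100.0 * math.sqrt(0.489 * 0.511 / 50_000)
        assert gc_percent(genome_50k) == pytest.approx(48.9, abs=3 * sd)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        rec = make_genome(1500, 0.5, SEED, stream="pi1", id="a")
        result = pairwise_identity(rec, SequenceRecord(id="b", seq=rec.seq))
        assert result.identity == pytest.approx(100.0)
        assert result.query_coverage == pytest.approx(100.0)

    def test_substitution_only_mutant_matches_hamming_oracle(self):
        rec = make_genome(1500, 0.5, SEED, stream="pi2", id="a")
        mutant, log = mutate(rec, 0.05, indel_rate=0.0, seed=SEED, stream="pi2m")
        hamming = len(log.substitutions)
        expected = 100.0 * (len(rec.seq) - hamming) / len(rec.seq)
        result = pairwise_identity(rec, SequenceRecord(id="b", seq=mutant.seq))
        assert result.identity == pytest.approx(expected, abs=0.5)
        assert result.identity == pytest.approx(95.0, abs=1.5)

    def test_prefix_coverage(self):
        rec = make_genome(1500, 0.5, SEED, stream="pi3", id="a")
        prefix = SequenceRecord(id="p", seq=rec.seq[:750])
        # the long sequence is covered over ~half its length by its prefix
        result = pairwise_identity(rec, prefix)
        assert result.query_coverage == pytest.approx(50.0, abs=1.0)
        # the prefix itself is fully covered
        assert pairwise_identity(prefix, rec).query_coverage == pytest.approx(100.0, abs=1.0)

    def test_empty_or_non_nucleotide_rejected(self):
        prot = SequenceRecord(id="p", seq="MKLV", kind="protein")
        nuc = SequenceRecord(id="n", seq="ACGT")
        with pytest.raises(MetricError):
            pairwise_identity(prot, nuc)


class TestPocp:
    def test_formula_from_counts(self):
        assert PocpResult(c1=2, c2=3, t1=4, t2=6).pocp == pytest.approx(50.0)

    def test_identical_proteomes(self):
        rng = np.random.default_rng(SEED)
        amino = list("ACDEFGHIKLMNPQRSTVWY")
        prots = [
            SequenceRecord(id=f"p{i}", seq="".join(rng.choice(amino, size=120)), kind="protein")
            for i in range(20)
        ]
        assert pocp(prots, prots).pocp == pytest.approx(100.0)

    def test_constructed_pair_matches_truth_counts(self):
        pa, pb, truth = make_proteome_pair(
            20, 20, 20, shared_identity=0.9, seed=SEED, protein_length=100
        )
        result = pocp(pa, pb)
        assert result.pocp == pytest.approx(truth.expected_pocp, abs=1.0)
        assert result.c1 == truth.expected_c1 and result.c2 == truth.expected_c2

    def test_symmetry(self):
        pa, pb, _ = make_proteome_pair(
            10, 10, 5, shared_identity=0.9, seed=SEED + 1, protein_length=100
        )
        fwd, rev = pocp(pa, pb), pocp(pb, pa)
        assert fwd.pocp == pytest.approx(rev.pocp, abs=1e-12)
        assert (fwd.c1, fwd.c2) == (rev.c2, rev.c1)

    def test_empty_proteome_is_an_error(self):
        prot = [SequenceRecord(id="p", seq="MKLV", kind="protein")]
        with pytest.raises(MetricError):
            pocp(prot, [])


class TestFragmentAni:
    def test_self_comparison_is_100(self):
        genome = make_genome(10_000, 0.5, SEED, stream="ani1", id="g")
        result = fragment_ani(genome, genome)
        assert result.ani == pytest.approx(100.0)
        assert result.fragments_mapped == result.fragments_total

    def test_recovers_mutation_rate(self, genome_50k):
        mutant, log = mutate(genome_50k, 0.03, seed=SEED, stream="ani2")
        mutant = SequenceRecord(id="m", seq=mutant.seq)
        realized = 100.0 * (1.0 - len(log.substitutions) / len(genome_50k.seq))
        result = fragment_ani(genome_50k, mutant)
        assert result.defined
        assert result.ani == pytest.approx(realized, abs=0.5)

    def test_unrelated_genomes_undefined(self):
        a = make_genome(10_000, 0.5, SEED, stream="ani3a", id="a")
        b = make_genome(10_000, 0.5, SEED, stream="ani3b", id="b")
        result = fragment_ani(a, b)
        assert not result.defined and result.fragments_mapped == 0

    def test_symmetry_within_half_point(self, genome_50k):
        mutant, _ = mutate(genome_50k, 0.05, seed=SEED, stream="ani4")
        mutant = SequenceRecord(id="m", seq=mutant.seq)
        fwd = fragment_ani(genome_50k, mutant).ani
        rev = fragment_ani(mutant, genome_50k).ani
        assert fwd == pytest.approx(rev, abs=0.5)

    def test_too_short_genome_is_an_error(self):
        short = make_genome(1500, 0.5, SEED, stream="ani5", id="s")
        with pytest.raises(MetricError):
            fragment_ani(short, short)


class TestMashDistance:
    def test_identical_sketches_distance_zero(self):
        genome = make_genome(20_000, 0.5, SEED, stream="m1", id="g")
        assert mash_distance(sketch(genome), sketch(genome)) == 0.0

    def test_disjoint_sketches_capped_at_one(self):
        x = Sketch(k=21, s=4, hashes=(1, 2, 3, 4))
        y = Sketch(k=21, s=4, hashes=(10, 11, 12, 13))
        assert mash_distance(x, y) == 1.0

    def test_known_overlap_matches_closed_form(self):
        # bottom-100 of the union is {1..100}, of which 90 are shared
        x = Sketch(k=21, s=100, hashes=tuple(range(1, 101)))
        y = Sketch(k=21, s=100, hashes=tuple(range(11, 111)))
        expected = (1.0 / 21) * math.log(1.9 / 1.8)
        assert mash_distance(x, y) == pytest.approx(expected, abs=1e-12)

    def test_jaccard_to_mash_closed_form(self):
        assert jaccard_to_mash(0.9, 21) == pytest.approx(
            (1.0 / 21) * math.log(1.9 / 1.8), abs=1e-12
        )
        assert jaccard_to_mash(1.0, 21) == 0.0
        assert jaccard_to_mash(0.0, 21) == 1.0

    def test_monotone_decreasing_in_jaccard(self):
        values = [jaccard_to_mash(j, 21) for j in np.linspace(0.01, 1.0, 50)]
        assert all(a > b or math.isclose(a, b) for a, b in zip(values, values[1:]))

    def test_k_mismatch_rejected(self):
        x = Sketch(k=21, s=4, hashes=(1, 2, 3, 4))
        y = Sketch(k=17, s=4, hashes=(1, 2, 3, 4))
        with pytest.raises(MetricError):
            mash_distance(x, y)

    def test_related_genomes_closer_than_unrelated(self):
        base = make_genome(20_000, 0.5, SEED, stream="m2", id="g")
        close, _ = mutate(base, 0.02, seed=SEED, stream="m3")
        far = make_genome(20_000, 0.5, SEED, stream="m4", id="h")
        s0 = sketch(base)
        assert mash_distance(s0, sketch(SequenceRecord(id="c", seq=close.seq))) < mash_distance(
            s0, sketch(far)
        )


class TestNjTree:
    def test_two_taxa_split_symmetrically(self):
        assert nj_tree(["A", "B"], [[0, 0.4], [0.4, 0]]) == "(A:0.2,B:0.2);"

    def test_three_taxa_solve_three_point_formulas(self):
        d_ab, d_ac, d_bc = 0.3, 0.4, 0.5
        newick = nj_tree(["A", "B", "C"], [[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]])
        a = (d_ab + d_ac - d_bc) / 2
        b = (d_ab + d_bc - d_ac) / 2
        c = (d_ac + d_bc - d_ab) / 2
        assert newick == f"(A:{a:.10g},B:{b:.10g},C:{c:.10g});"

    def test_four_taxon_additive_tree_recovered(self):
        import dendropy

        # generating tree: ((A:1,B:2):1,(C:3,D:4))
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        newick = nj_tree(list("ABCD"), d)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (i, a), (j, b) in [
            ((0, "A"), (1, "B")), ((0, "A"), (2, "C")), ((0, "A"), (3, "D")),
            ((1, "B"), (2, "C")), ((1, "B"), (3, "D")), ((2, "C"), (3, "D")),
        ]:
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(d[i][j], abs=1e-9)

    def test_eight_taxon_additive_matrix_recovered(self):
        import dendropy

        # random additive matrix from a known tree with positive branches
        rng = np.random.default_rng(5)
        source = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
            rng=__import__("random").Random(5),
        )
        for edge in source.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(rng.uniform(0.05, 0.5))
        labels = [leaf.taxon.label for leaf in source.leaf_node_iter()]
        pdm = source.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in source.taxon_namespace}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        rebuilt = dendropy.Tree.get(
            data=nj_tree(labels, d), schema="newick",
            taxon_namespace=source.taxon_namespace,
        )
        source.is_rooted = False
        rebuilt.is_rooted = False
        source.update_bipartitions()
        rebuilt.update_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(source, rebuilt)
        assert rf == 0
        # and the patristic distances are reproduced
        pdm2 = rebuilt.phylogenetic_distance_matrix()
        for i in range(n):
            for j in range(i + 1, n):
                assert pdm2.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                ) == pytest.approx(d[i, j], abs=1e-6)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(MetricError):
            nj_tree(["A", "B"], [[0, 0.4], [0.5, 0]])

    def test_agrees_with_skbio_topology_on_noisy_matrix(self):
        import dendropy
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        n = 6
        labels = [f"t{i}" for i in range(n)]
        coords = rng.random((n, 4))
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = float(np.abs(coords[i] - coords[j]).sum())
        ours = dendropy.Tree.get(data=nj_tree(labels, d), schema="newick")
        theirs_newick = str(skbio_nj(DistanceMatrix(d, ids=labels)))
        tns = ours.taxon_namespace
        theirs = dendropy.Tree.get(data=theirs_newick, schema="newick", taxon_namespace=tns)
        ours.is_rooted = False
        theirs.is_rooted = False
        ours.update_bipartitions()
        theirs.update_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0
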