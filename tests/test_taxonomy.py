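"""Candidate ranking, validity filtering, novelty consensus, congruence."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protoscribe.config import ThresholdConfig
from protoscribe.metrics import AniResult, PocpResult
from protoscribe.seqio import ReferenceEntry, SequenceRecord
from protoscribe.taxonomy import (
    DIFFERENT_GENUS,
    KNOWN_SPECIES,
    NO_RELATIVES,
    NOVEL_FAMILY_OR_HIGHER,
    NOVEL_GENUS,
    NOVEL_SPECIES,
    SAME_GENUS,
    TaxonomyError,
    CandidateRelative,
    classify_novelty,
    filter_valid,
    normalize_species_name,
    rank_candidates,
    summarize_congruence,
)

TAX = ("Bacteria", "P", "C", "O", "F", "G")


def _entry(rid, name="Genus species", seq="ACGT" * 300, valid=True):
    return ReferenceEntry(
        id=rid, seq=seq, species_name=name, taxonomy=TAX, validly_published=valid
    )


def _cand(identity, ani=None, pocp=None, gc_delta=None, external=None, rid="r1"):
    return CandidateRelative(
        entry=_entry(rid),
        identity=identity,
        query_coverage=100.0,
        ani=None if ani is None else AniResult(ani=ani, fragments_total=100, fragments_mapped=90),
        pocp=None if pocp is None else PocpResult(
            c1=int(pocp), c2=int(pocp), t1=100, t2=100
        ),
        gc_delta=gc_delta,
        external_placement=external,
    )


class TestRankCandidates:
    def test_sixty_passing_references_truncate_to_cap(self, query_16s, reference_set, cfg):
        candidates, warnings = rank_candidates(query_16s, reference_set, cfg)
        assert len(candidates) == 50
        assert warnings == []
        identities = [c.identity for c in candidates]
        assert identities == sorted(identities, reverse=True)

    def test_small_passing_set_returned_whole(self, query_16s, reference_set, cfg):
        candidates, _ = rank_candidates(query_16s, reference_set[:10], cfg)
        assert len(candidates) == 10

    def test_low_coverage_reference_excluded(self, query_16s, reference_set, cfg):
        # a reference spanning only 75 % of the query fails the 80 % floor
        short = ReferenceEntry(
            id="short",
            seq=reference_set[0].seq[: int(len(query_16s.seq) * 0.75)],
            species_name="Shortus fragmentus",
            taxonomy=TAX,
            validly_published=True,
        )
        candidates, _ = rank_candidates(query_16s, [short, reference_set[1]], cfg)
        assert all(c.entry.id != "short" for c in candidates)

    def test_stable_under_input_permutation(self, query_16s, reference_set, cfg):
        ordered, _ = rank_candidates(query_16s, reference_set, cfg)
        shuffled = list(reference_set)
        random.Random(3).shuffle(shuffled)
        permuted, _ = rank_candidates(query_16s, shuffled, cfg)
        assert [c.entry.id for c in ordered] == [c.entry.id for c in permuted]

    def test_no_passing_reference_warns(self, cfg):
        query = SequenceRecord(id="q", seq="AT" * 750)
        unrelated = _entry("x", seq="GC" * 750)
        candidates, warnings = rank_candidates(query, [unrelated], cfg)
        assert candidates == [] and warnings == [NO_RELATIVES]


class TestFilterValid:
    def test_unvalidated_species_excluded(self):
        cands = [_cand(99.0, rid="a"), _cand(98.0, rid="b")]
        cands[0].entry.species_name = "Ruminococcus bicirculans"
        cands[1].entry.species_name = "Ruminococcus flavefaciens"
        kept, side = filter_valid(cands, {"Ruminococcus flavefaciens"})
        assert [c.entry.species_name for c in kept] == ["Ruminococcus flavefaciens"]
        assert [c.entry.species_name for c in side] == ["Ruminococcus bicirculans"]

    def test_name_normalisation(self):
        assert normalize_species_name("'Candidatus Foo bar'") == "foo bar"
        cand = _cand(99.0)
        cand.entry.species_name = "“Candidatus Foo bar”"
        kept, _ = filter_valid([cand], {"FOO BAR"})
        assert kept

    def test_counts(self):
        cands = []
        for i, name in enumerate(["A a", "B b", "C c", "D d", "E e"]):
            c = _cand(95.0, rid=f"r{i}")
            c.entry.species_name = name
            cands.append(c)
        kept, side = filter_valid(cands, {"A a", "C c", "E e"})
        assert len(kept) == 3 and len(side) == 2

    def test_empty_names_list_is_an_error(self):
        with pytest.raises(TaxonomyError):
            filter_valid([_cand(99.0)], set())


class TestClassifyNovelty:
    def test_high_identity_and_ani_is_known_species(self, cfg):
        call = classify_novelty([_cand(99.0, ani=96.2)], cfg)
        assert call.verdict_16s == "same_species"
        assert call.verdict_ani == "same_species"
        assert call.consensus == KNOWN_SPECIES

    def test_low_pocp_mid_identity_is_novel_genus(self, cfg):
        call = classify_novelty([_cand(93.0, pocp=40.0)], cfg)
        assert call.verdict_pocp == "new_genus"
        assert call.consensus == NOVEL_GENUS

    def test_very_low_identity_is_novel_family(self, cfg):
        call = classify_novelty([_cand(85.0)], cfg)
        assert call.consensus == NOVEL_FAMILY_OR_HIGHER

    def test_ani_overrides_16s_at_species_rank(self, cfg):
        # conserved 16S gene but divergent genome: a novel species
        call = classify_novelty([_cand(99.3, ani=88.8, pocp=77.5)], cfg)
        assert call.consensus == NOVEL_SPECIES
        assert ("16s", "ani") in call.conflicts

    def test_no_candidates_not_evaluable(self, cfg):
        call = classify_novelty([], cfg)
        assert call.consensus == "not_evaluable"
        assert NO_RELATIVES in call.warnings

    def test_gc_delta_is_advisory_only(self, cfg):
        with_gc = classify_novelty([_cand(99.0, ani=96.0, gc_delta=5.0)], cfg)
        without = classify_novelty([_cand(99.0, ani=96.0)], cfg)
        assert with_gc.consensus == without.consensus == KNOWN_SPECIES

    def test_conflicts_empty_iff_evaluable_verdicts_agree(self, cfg):
        agreeing = classify_novelty([_cand(99.0, ani=96.0, gc_delta=0.2)], cfg)
        assert agreeing.conflicts == []

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(identity=st.integers(600, 1000).map(lambda v: v / 10.0))
    def test_monotone_in_16s_identity(self, identity):
        cfg = ThresholdConfig()
        order = [KNOWN_SPECIES, NOVEL_SPECIES, NOVEL_GENUS, NOVEL_FAMILY_OR_HIGHER]
        lower = classify_novelty([_cand(identity)], cfg).consensus
        higher = classify_novelty([_cand(min(100.0, identity + 0.5))], cfg).consensus
        assert order.index(higher) <= order.index(lower)

    def test_boundary_recovery_by_grid_probe(self, cfg):
        # scanning a fine identity grid recovers the printed 16S boundaries
        def consensus_at(identity):
            return classify_novelty([_cand(identity)], cfg).consensus

        grid = [round(60.0 + 0.1 * i, 1) for i in range(401)]
        calls = [consensus_at(v) for v in grid]
        flips = {
            (a, b): grid[i + 1]
            for i, (a, b) in enumerate(zip(calls, calls[1:]))
            if a != b
        }
        assert flips[(NOVEL_FAMILY_OR_HIGHER, NOVEL_GENUS)] == pytest.approx(86.6)
        assert flips[(NOVEL_GENUS, NOVEL_SPECIES)] == pytest.approx(94.6)
        assert flips[(NOVEL_SPECIES, KNOWN_SPECIES)] == pytest.approx(98.8)


class TestCongruence:
    def test_all_agree_same(self):
        rows = [{"16s": SAME_GENUS, "pocp": SAME_GENUS, "ext": SAME_GENUS}] * 10
        summary = summarize_congruence(rows)
        assert summary.overall_congruence_pct == 100.0
        assert summary.congruent_same == 10

    def test_unique_different_counted_per_method(self):
        agree = {"16s": SAME_GENUS, "pocp": SAME_GENUS, "ext": SAME_GENUS}
        lone = {"16s": DIFFERENT_GENUS, "pocp": SAME_GENUS, "ext": SAME_GENUS}
        summary = summarize_congruence([agree, agree, agree, lone])
        assert summary.overall_congruence_pct == 75.0
        assert summary.unique_different["16s"] == 1
        assert summary.unique_different["pocp"] == 0

    def test_empty_table_is_an_error(self):
        with pytest.raises(TaxonomyError):
            summarize_congruence([])

    def test_inconsistent_method_sets_rejected(self):
        with pytest.raises(TaxonomyError):
            summarize_congruence(
                [{"16s": SAME_GENUS}, {"pocp": SAME_GENUS}]
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()),
            min_size=1,
            max_size=50,
        )
    )
    def test_counts_match_brute_force_recount(self, raw):
        methods = ("16s", "ext", "pocp")
        rows = [
            {
                m: DIFFERENT_GENUS if flag else SAME_GENUS
                for m, flag in zip(methods, flags)
            }
            for flags in raw
        ]
        summary = summarize_congruence(rows)
        n_same = sum(1 for f in raw if not any(f))
        n_diff = sum(1 for f in raw if all(f))
        n_unique = sum(1 for f in raw if sum(f) == 1)
        n_mixed = len(raw) - n_same - n_diff - n_unique
        assert summary.congruent_same == n_same
        assert summary.congruent_different == n_diff
        assert sum(summary.unique_different.values()) == n_unique
        assert summary.mixed_other == n_mixed
        total = (
            summary.congruent_same
            + summary.congruent_different
            + sum(summary.unique_different.values())
            + summary.mixed_other
        )
        assert total == summary.n_comparisons == len(raw)
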