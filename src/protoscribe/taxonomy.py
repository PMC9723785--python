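"""Candidate ranking, name-validity filtering and the consensus novelty call.

The decision logic codifies the published delineation boundaries: 16S rRNA
identity >98.7 % for species, >94.5 % for genus and >86.5 % for family
membership; ANI >95 % for species identity; POCP <50 % for genus
separation; and a 1-point G+C window as advisory supporting evidence.
Per-evidence verdicts are always reported alongside the consensus, with
disagreements listed explicitly: no single method should decide a
placement on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import ThresholdConfig
from .metrics import AniResult, PocpResult, pairwise_identity
from .seqio import ReferenceEntry, SequenceRecord

NO_RELATIVES = "NO_RELATIVES"

# per-evidence verdicts
SAME_SPECIES = "same_species"
SAME_GENUS_NEW_SPECIES = "same_genus_new_species"
NEW_GENUS = "new_genus"
NEW_FAMILY_OR_HIGHER = "new_family_or_higher"
NOT_EVALUABLE = "not_evaluable"

# consensus calls
KNOWN_SPECIES = "known_species"
NOVEL_SPECIES = "novel_species"
NOVEL_GENUS = "novel_genus"
NOVEL_FAMILY_OR_HIGHER = "novel_family_or_higher"

_VERDICT_NOVELTY_RANK = {
    SAME_SPECIES: 0,
    SAME_GENUS_NEW_SPECIES: 1,
    NEW_GENUS: 2,
    NEW_FAMILY_OR_HIGHER: 3,
}


class TaxonomyError(ValueError):
    pass


@dataclass
class CandidateRelative:
    entry: ReferenceEntry
    identity: float
    query_coverage: float
    ani: AniResult | None = None
    pocp: PocpResult | None = None
    gc_delta: float | None = None          # |query G+C - reference G+C|, points
    external_placement: str | None = None  # supplied placement label, never computed


@dataclass
class NoveltyCall:
    verdict_16s: str = NOT_EVALUABLE
    verdict_ani: str = NOT_EVALUABLE
    verdict_pocp: str = NOT_EVALUABLE
    verdict_gc: str = NOT_EVALUABLE
    consensus: str = NOT_EVALUABLE
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    supporting: dict[str, float | str | None] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def rank_candidates(
    query16s: SequenceRecord,
    references: Sequence[ReferenceEntry],
    cfg: ThresholdConfig,
) -> tuple[list[CandidateRelative], list[str]]:
    """Align the query against every reference and keep the top candidates.

    References passing the identity and coverage floors are sorted by
    identity descending (ties broken by reference id ascending) and
    truncated to the candidate cap.  Returns (candidates, warnings).
    """
    if not references:
        raise TaxonomyError("reference set is empty")
    passing: list[CandidateRelative] = []
    for ref in references:
        result = pairwise_identity(query16s, ref.record)
        if (
            result.identity >= cfg.candidate_identity_min
            and result.query_coverage >= cfg.candidate_coverage_min
        ):
            passing.append(
                CandidateRelative(
                    entry=ref,
                    identity=result.identity,
                    query_coverage=result.query_coverage,
                )
            )
    passing.sort(key=lambda c: (-c.identity, c.entry.id))
    if not passing:
        return [], [NO_RELATIVES]
    return passing[: cfg.candidate_cap], []


def normalize_species_name(name: str) -> str:
    """Case-insensitive comparison form: quotes stripped, 'Candidatus ' dropped."""
    cleaned = name.strip().strip("'\"‘’“”")
    if cleaned.lower().startswith("candidatus "):
        cleaned = cleaned[len("candidatus "):]
    return cleaned.casefold()


def filter_valid(
    candidates: Sequence[CandidateRelative],
    names_list: set[str],
) -> tuple[list[CandidateRelative], list[CandidateRelative]]:
    """Split candidates into (validly named, discarded).

    Only validly named candidates proceed to genome-based metrics; the
    discarded ones are kept for reporting.
    """
    if not names_list:
        raise TaxonomyError("validly published names list is empty")
    valid_forms = {normalize_species_name(n) for n in names_list}
    kept: list[CandidateRelative] = []
    side: list[CandidateRelative] = []
    for cand in candidates:
        if normalize_species_name(cand.entry.species_name) in valid_forms:
            kept.append(cand)
        else:
            side.append(cand)
    return kept, side


def _verdict_16s(identity: float, cfg: ThresholdConfig) -> str:
    if identity > cfg.s16_species:
        return SAME_SPECIES
    if identity > cfg.s16_genus:
        return SAME_GENUS_NEW_SPECIES
    if identity > cfg.s16_family:
        return NEW_GENUS
    return NEW_FAMILY_OR_HIGHER


def classify_novelty(
    candidates: Sequence[CandidateRelative],
    cfg: ThresholdConfig,
) -> NoveltyCall:
    """Combine the evidence lines into a consensus novelty decision.

    Per line, against the best candidate for that line:

    * 16S: >98.7 % same species; >94.5 % same genus; >86.5 % same family.
    * ANI: >95 % same species, else a different species (species rank only).
    * POCP: >=50 % same genus, else new genus (strict '<50 => different').
    * G+C: within 1 point is consistent with same species; advisory only.

    Precedence: ANI overrides 16S at species rank; POCP and any supplied
    external placement arbitrate genus rank; 16S alone arbitrates family
    rank.  Every disagreement between evaluable lines is recorded.
    """
    call = NoveltyCall()
    if not candidates:
        call.warnings.append(NO_RELATIVES)
        return call

    best_16s = max(candidates, key=lambda c: c.identity)
    call.verdict_16s = _verdict_16s(best_16s.identity, cfg)
    call.supporting["16s_best_identity"] = best_16s.identity
    call.supporting["16s_best_match"] = best_16s.entry.species_name

    ani_values = [
        (c, c.ani.ani) for c in candidates if c.ani is not None and c.ani.defined
    ]
    if ani_values:
        best_ani_cand, best_ani = max(ani_values, key=lambda t: t[1])
        call.verdict_ani = SAME_SPECIES if best_ani > cfg.ani_species else SAME_GENUS_NEW_SPECIES
        call.supporting["ani_best"] = best_ani
        call.supporting["ani_best_match"] = best_ani_cand.entry.species_name

    pocp_values = [(c, c.pocp.pocp) for c in candidates if c.pocp is not None]
    if pocp_values:
        best_pocp_cand, best_pocp = max(pocp_values, key=lambda t: t[1])
        call.verdict_pocp = (
            SAME_GENUS_NEW_SPECIES if best_pocp >= cfg.pocp_genus else NEW_GENUS
        )
        call.supporting["pocp_best"] = best_pocp
        call.supporting["pocp_best_match"] = best_pocp_cand.entry.species_name

    gc_deltas = [c.gc_delta for c in candidates if c.gc_delta is not None]
    if gc_deltas:
        min_delta = min(gc_deltas)
        call.verdict_gc = (
            SAME_SPECIES if min_delta <= cfg.gc_species_delta else SAME_GENUS_NEW_SPECIES
        )
        call.supporting["gc_delta_min"] = min_delta

    external = next(
        (c.external_placement for c in candidates if c.external_placement), None
    )
    if external is not None:
        call.supporting["external_placement"] = external

    # --- consensus ---------------------------------------------------------
    # species rank: ANI overrides 16S when evaluable
    if call.verdict_ani != NOT_EVALUABLE:
        species_same = call.verdict_ani == SAME_SPECIES
    else:
        species_same = call.verdict_16s == SAME_SPECIES

    # genus rank: POCP (with external placement as co-arbiter) over 16S
    if call.verdict_pocp != NOT_EVALUABLE:
        genus_same = call.verdict_pocp == SAME_GENUS_NEW_SPECIES
    elif external is not None:
        genus_same = _external_says_same_genus(external, candidates)
    else:
        genus_same = call.verdict_16s in (SAME_SPECIES, SAME_GENUS_NEW_SPECIES)

    # family rank: 16S alone
    family_same = call.verdict_16s != NEW_FAMILY_OR_HIGHER

    if species_same:
        call.consensus = KNOWN_SPECIES
    elif genus_same:
        call.consensus = NOVEL_SPECIES
    elif family_same:
        call.consensus = NOVEL_GENUS
    else:
        call.consensus = NOVEL_FAMILY_OR_HIGHER

    # G+C never flips a consensus (advisory), but disagreement is recorded.
    verdicts = {
        "16s": call.verdict_16s,
        "ani": call.verdict_ani,
        "pocp": call.verdict_pocp,
        "gc": call.verdict_gc,
    }
    evaluable = {k: v for k, v in verdicts.items() if v != NOT_EVALUABLE}
    lines = sorted(evaluable)
    for i, la in enumerate(lines):
        for lb in lines[i + 1:]:
            if _disagree(la, evaluable[la], lb, evaluable[lb]):
                call.conflicts.append((la, lb))
    return call


def _external_says_same_genus(
    external: str, candidates: Sequence[CandidateRelative]
) -> bool:
    """An external placement label supports the existing genus when it names
    the genus of any candidate relative."""
    genus = external.split(";")[-1].strip().split(" ")[0].casefold().lstrip("'\"")
    for cand in candidates:
        cand_genus = cand.entry.species_name.split(" ")[0].casefold()
        if genus and genus == cand_genus:
            return True
    return False


def _disagree(line_a: str, verdict_a: str, line_b: str, verdict_b: str) -> bool:
    """Two evidence lines disagree when both speak to a common rank and imply
    different sides of it.  ANI speaks to species only; POCP to genus only;
    G+C to species only; 16S to all ranks."""
    rank_a = _VERDICT_NOVELTY_RANK[verdict_a]
    rank_b = _VERDICT_NOVELTY_RANK[verdict_b]
    # boundaries: 0 = species membership, 1 = genus membership, 2 = family
    scope = {
        "16s": (0, 2),
        "ani": (0, 0),
        "gc": (0, 0),
        "pocp": (1, 1),
    }
    lo = max(scope[line_a][0], scope[line_b][0])
    hi = min(scope[line_a][1], scope[line_b][1])
    if lo > hi:
        return False  # no common rank to disagree about
    # compare "at least this novel" status at each shared boundary
    for boundary in range(lo, hi + 1):
        if (rank_a > boundary) != (rank_b > boundary):
            return True
    return False


# ---------------------------------------------------------------------------
# congruence summary


@dataclass
class CongruenceSummary:
    n_comparisons: int
    methods: tuple[str, ...]
    congruent_same: int
    congruent_different: int
    unique_different: dict[str, int]
    mixed_other: int

    @property
    def overall_congruence_pct(self) -> float:
        return 100.0 * (self.congruent_same + self.congruent_different) / self.n_comparisons

    @property
    def congruent_same_pct(self) -> float:
        return 100.0 * self.congruent_same / self.n_comparisons

    @property
    def congruent_different_pct(self) -> float:
        return 100.0 * self.congruent_different / self.n_comparisons


SAME_GENUS = "same_genus"
DIFFERENT_GENUS = "different_genus"


def summarize_congruence(
    pairwise_table: Sequence[Mapping[str, str]],
) -> CongruenceSummary:
    """Stratify per-pair genus calls across methods.

    Each row maps method name -> {same_genus, different_genus}.  Rows where
    all methods agree are congruent (same or different); rows where exactly
    one method says different while all others say same count as that
    method's unique-different; remaining disagreement patterns are tallied
    as mixed.
    """
    if not pairwise_table:
        raise TaxonomyError("empty congruence table")
    methods = tuple(sorted(pairwise_table[0]))
    for row in pairwise_table:
        if tuple(sorted(row)) != methods:
            raise TaxonomyError("inconsistent method sets across rows")
        for v in row.values():
            if v not in (SAME_GENUS, DIFFERENT_GENUS):
                raise TaxonomyError(f"unknown genus call {v!r}")
    congruent_same = congruent_different = mixed = 0
    unique_different = {m: 0 for m in methods}
    for row in pairwise_table:
        calls = [row[m] for m in methods]
        n_diff = sum(1 for c in calls if c == DIFFERENT_GENUS)
        if n_diff == 0:
            congruent_same += 1
        elif n_diff == len(methods):
            congruent_different += 1
        elif n_diff == 1:
            lone = next(m for m in methods if row[m] == DIFFERENT_GENUS)
            unique_different[lone] += 1
        else:
            mixed += 1
    return CongruenceSummary(
        n_comparisons=len(pairwise_table),
        methods=methods,
        congruent_same=congruent_same,
        congruent_different=congruent_different,
        unique_different=unique_different,
        mixed_other=mixed,
    )
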