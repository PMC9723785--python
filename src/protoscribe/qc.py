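"""Input quality gates.

Three checks run before any taxonomic interpretation: 16S completeness
against the closest reference (<80 % triggers a warning), a two-parent
midpoint chimera screen, and the genome completeness/contamination gate
(<95 % complete or >3 % contaminated).  Completeness and contamination are
consumed as inputs (the output of a marker-gene tool), never estimated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

from .config import ThresholdConfig
from .metrics import pairwise_identity
from .seqio import ReferenceEntry, SequenceRecord

CHIMERIC_16S = "CHIMERIC_16S"
INCOMPLETE_16S = "INCOMPLETE_16S"
INCOMPLETE_GENOME = "INCOMPLETE_GENOME"
CONTAMINATED_GENOME = "CONTAMINATED_GENOME"
VALUES_NOT_SUPPLIED = "VALUES_NOT_SUPPLIED"
CHIMERA_NOT_EVALUABLE = "CHIMERA_NOT_EVALUABLE"

CHIMERA_MIN_QUERY_LENGTH = 200
CHIMERA_DELTA_DEFAULT = 2.0  # points each half must beat the full-length best by


class QcError(ValueError):
    pass


@dataclass
class ChimeraCall:
    is_chimeric: bool
    parent_a: str | None = None          # best reference of the 5' half
    parent_b: str | None = None          # best reference of the 3' half
    identity_half_a: float | None = None
    identity_half_b: float | None = None
    identity_full: float | None = None
    full_best_id: str | None = None
    note: str = ""


@dataclass
class QcReport:
    s16_completeness: float | None = None
    chimera: ChimeraCall | None = None
    genome_completeness: float | None = None
    contamination: float | None = None
    warnings: list[str] = field(default_factory=list)


def assess_16s_completeness(
    query: SequenceRecord, best_reference: SequenceRecord
) -> float:
    """16S completeness = 100 * (aligned query span on the reference) /
    (reference length), capped at 100.

    The span is taken from the best infix placement of the shorter sequence
    on the longer one, so a query longer than its reference still scores 100.
    """
    for rec in (query, best_reference):
        if rec.kind != "nucleotide":
            raise QcError(f"record {rec.id!r} is not nucleotide")
        if not rec.seq:
            raise QcError(f"record {rec.id!r} is empty")
    # coverage of the reference = aligned query span on the reference
    result = pairwise_identity(best_reference, query)
    return min(100.0, result.query_coverage)


def _best_reference(
    query_seq: str, references: Sequence[ReferenceEntry]
) -> tuple[str, float]:
    best_id, best_identity = "", -1.0
    query = SequenceRecord(id="q", seq=query_seq, kind="nucleotide")
    for ref in references:
        result = pairwise_identity(query, ref.record)
        if result.identity > best_identity or (
            result.identity == best_identity and ref.id < best_id
        ):
            best_id, best_identity = ref.id, result.identity
    return best_id, best_identity


def screen_chimera(
    query: SequenceRecord,
    references: Sequence[ReferenceEntry],
    delta: float = CHIMERA_DELTA_DEFAULT,
) -> ChimeraCall:
    """Two-parent midpoint chimera screen.

    The query is split at its midpoint; the best-identity reference is found
    for each half and for the full sequence.  A chimera is flagged when the
    two halves' best references differ AND each half's identity exceeds the
    full-sequence best identity by at least ``delta`` points.  This is a
    desk-scale surrogate for a three-way-alignment chimera caller; an
    external caller can be plugged in via :class:`ChimeraCallerAdapter`.
    """
    if len(references) < 2:
        raise QcError("chimera screen needs at least two references")
    if len(query.seq) < CHIMERA_MIN_QUERY_LENGTH:
        return ChimeraCall(
            is_chimeric=False,
            note=f"query shorter than {CHIMERA_MIN_QUERY_LENGTH} nt; not evaluable",
        )
    mid = len(query.seq) // 2
    half_a, half_b = query.seq[:mid], query.seq[mid:]
    id_a, ident_a = _best_reference(half_a, references)
    id_b, ident_b = _best_reference(half_b, references)
    id_full, ident_full = _best_reference(query.seq, references)
    flagged = (
        id_a != id_b
        and ident_a >= ident_full + delta
        and ident_b >= ident_full + delta
    )
    return ChimeraCall(
        is_chimeric=flagged,
        parent_a=id_a,
        parent_b=id_b,
        identity_half_a=ident_a,
        identity_half_b=ident_b,
        identity_full=ident_full,
        full_best_id=id_full,
    )


def gate_genome(
    completeness: float | None,
    contamination: float | None,
    cfg: ThresholdConfig,
) -> list[str]:
    """Genome quality gate; inequalities are strict, so boundary values pass.

    Pure function of its arguments: INCOMPLETE_GENOME iff completeness is
    strictly below the minimum, CONTAMINATED_GENOME iff contamination is
    strictly above the maximum.
    """
    if completeness is None or contamination is None:
        return [VALUES_NOT_SUPPLIED]
    for name, value in (("completeness", completeness), ("contamination", contamination)):
        if not 0.0 <= value <= 100.0:
            raise QcError(f"{name} must be in [0, 100], got {value}")
    warnings: list[str] = []
    if completeness < cfg.genome_completeness_min:
        warnings.append(INCOMPLETE_GENOME)
    if contamination > cfg.contamination_max:
        warnings.append(CONTAMINATED_GENOME)
    return warnings


def run_qc(
    query16s: SequenceRecord,
    references: Sequence[ReferenceEntry],
    best_reference: SequenceRecord | None,
    cfg: ThresholdConfig,
    genome_completeness: float | None = None,
    contamination: float | None = None,
    chimera_delta: float = CHIMERA_DELTA_DEFAULT,
) -> QcReport:
    """Run every gate and collect coded warnings."""
    report = QcReport(
        genome_completeness=genome_completeness, contamination=contamination
    )
    if best_reference is not None:
        report.s16_completeness = assess_16s_completeness(query16s, best_reference)
        if report.s16_completeness < cfg.s16_completeness_min:
            report.warnings.append(INCOMPLETE_16S)
    if len(references) >= 2:
        report.chimera = screen_chimera(query16s, references, delta=chimera_delta)
        if report.chimera.is_chimeric:
            report.warnings.append(CHIMERIC_16S)
        elif report.chimera.note:
            report.warnings.append(CHIMERA_NOT_EVALUABLE)
    report.warnings.extend(gate_genome(genome_completeness, contamination, cfg))
    return report


class ChimeraCallerAdapter(Protocol):
    """Contract for plugging in an external chimera caller.

    Implementations take a query FASTA path and a reference FASTA path and
    return a :class:`ChimeraCall`.
    """

    def __call__(self, query_fasta: str, reference_fasta: str) -> ChimeraCall: ...
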