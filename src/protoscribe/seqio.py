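"""Sequence and table I/O plus the shared domain types.

Everything downstream works on :class:`SequenceRecord` objects and plain
pandas DataFrames; FASTA parsing is delegated to Biopython.  Coordinates are
0-based half-open throughout the package and only converted to 1-based in
rendered reports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("protoscribe")

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

# IUPAC ambiguity codes beyond N are squashed to N (nucleotide) / X (protein)
# rather than rejected: curated 16S reference sets routinely contain them.
_NUC_AMBIGUOUS = set("RYSWKMBDHV")
_PROT_AMBIGUOUS = set("BJZUO")


class SeqIOError(ValueError):
    """Raised for malformed sequence or table inputs."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide or protein sequence.

    ``seq`` is uppercase over {A,C,G,T,N} for nucleotides or the amino-acid
    alphabet (with X) for proteins.
    """

    id: str
    seq: str
    kind: str = "nucleotide"  # or "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record has an empty id")
        if not self.seq:
            raise SeqIOError(f"sequence record {self.id!r} has an empty sequence")
        if self.kind not in ("nucleotide", "protein"):
            raise SeqIOError(f"unknown sequence kind {self.kind!r}")
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise SeqIOError(
                f"illegal character {self.seq[pos]!r} at position {pos} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        if self.kind != "nucleotide":
            raise SeqIOError("reverse complement is defined for nucleotide records only")
        return SequenceRecord(
            id=self.id,
            seq=str(Seq(self.seq).reverse_complement()),
            kind=self.kind,
            description=self.description,
        )


@dataclass
class ReferenceEntry:
    """A 16S reference taxon with taxonomy and name-validity status."""

    id: str
    seq: str
    species_name: str
    taxonomy: tuple[str, ...]
    validly_published: bool
    type_genome_path: str | None = None
    type_proteome_path: str | None = None

    def __post_init__(self) -> None:
        if len(self.taxonomy) < 2:
            raise SeqIOError(
                f"reference {self.id!r}: taxonomy must have at least 2 ranks"
            )

    @property
    def record(self) -> SequenceRecord:
        return SequenceRecord(id=self.id, seq=self.seq, kind="nucleotide")


_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def validate_ec(ec: str) -> bool:
    """An EC string has exactly four dot-separated fields; ``-`` is accepted
    only as a trailing wildcard run (e.g. ``1.4.1.-`` or ``1.-.-.-``)."""
    m = _EC_RE.match(ec)
    if not m:
        return False
    fields = ec.split(".")
    seen_dash = False
    for f in fields:
        if f == "-":
            seen_dash = True
        elif seen_dash:
            return False  # a concrete field after a wildcard field
    return fields[0] != "-"


@dataclass
class AnnotationRow:
    locus_tag: str
    ko_id: str | None
    ec_numbers: tuple[str, ...]
    cazy_families: tuple[str, ...]
    product: str
    category: str = ""  # free-text functional category (transporter/secretion/enzyme)

    @property
    def has_wildcard_ec(self) -> bool:
        return any("-" in ec for ec in self.ec_numbers)


@dataclass
class AnnotationTable:
    rows: list[AnnotationRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.locus_tag in seen:
                raise SeqIOError(f"duplicate locus_tag {row.locus_tag!r}")
            seen.add(row.locus_tag)

    def __len__(self) -> int:
        return len(self.rows)

    def all_ecs(self) -> set[str]:
        return {ec for row in self.rows for ec in row.ec_numbers}

    def all_kos(self) -> set[str]:
        return {row.ko_id for row in self.rows if row.ko_id}


def _clean_seq(raw: str, kind: str, record_id: str) -> str:
    seq = raw.upper()
    if kind == "nucleotide":
        seq = seq.replace("U", "T")
        ambiguous = set(seq) & _NUC_AMBIGUOUS
        if ambiguous:
            logger.warning(
                "record %s: mapping ambiguity codes %s to N",
                record_id,
                "".join(sorted(ambiguous)),
            )
            seq = re.sub("[" + "".join(sorted(_NUC_AMBIGUOUS)) + "]", "N", seq)
    else:
        ambiguous = set(seq) & _PROT_AMBIGUOUS
        if ambiguous:
            logger.warning(
                "record %s: mapping ambiguous residues %s to X",
                record_id,
                "".join(sorted(ambiguous)),
            )
            seq = re.sub("[" + "".join(sorted(_PROT_AMBIGUOUS)) + "]", "X", seq)
    return seq


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; U is converted to T in nucleotide records.
    Raises on empty files, duplicate ids and illegal characters.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=_clean_seq(str(rec.seq), kind, rec.id),
                kind=kind,
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


_TRUTHY = {"true", "1", "yes"}
_FALSY = {"false", "0", "no"}


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise SeqIOError(f"{context}: cannot parse boolean from {value!r}")


def read_tsv_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Tab-separated, UTF-8, '#'-prefixed comment lines ignored."""
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
            else:
                rows.append(parts)
    if header is None:
        raise SeqIOError(f"{path}: empty table")
    return header, rows


def read_reference_set(
    fasta_path: str | Path, metadata_tsv_path: str | Path
) -> list[ReferenceEntry]:
    """Join a 16S reference FASTA with its metadata TSV.

    The TSV must carry columns ``id``, ``species_name``, ``taxonomy``
    (semicolon-separated lineage, domain->species), ``validly_published``
    and optionally ``type_genome_path`` / ``type_proteome_path``.
    Ids must match one-to-one between the two files.
    """
    records = {r.id: r for r in read_fasta(fasta_path, kind="nucleotide")}
    header, rows = read_tsv_rows(metadata_tsv_path)
    col = {name: i for i, name in enumerate(header)}
    for required in ("id", "species_name", "taxonomy", "validly_published"):
        if required not in col:
            raise SeqIOError(f"{metadata_tsv_path}: missing column {required!r}")

    entries: list[ReferenceEntry] = []
    meta_ids: set[str] = set()
    for row in rows:
        rid = row[col["id"]]
        meta_ids.add(rid)
        if rid not in records:
            continue
        entries.append(
            ReferenceEntry(
                id=rid,
                seq=records[rid].seq,
                species_name=row[col["species_name"]],
                taxonomy=tuple(t.strip() for t in row[col["taxonomy"]].split(";")),
                validly_published=_parse_bool(
                    row[col["validly_published"]], f"reference {rid}"
                ),
                type_genome_path=row[col["type_genome_path"]] or None
                if "type_genome_path" in col and len(row) > col["type_genome_path"]
                else None,
                type_proteome_path=row[col["type_proteome_path"]] or None
                if "type_proteome_path" in col and len(row) > col["type_proteome_path"]
                else None,
            )
        )
    orphans_fasta = sorted(set(records) - meta_ids)
    orphans_tsv = sorted(meta_ids - set(records))
    if orphans_fasta or orphans_tsv:
        raise SeqIOError(
            "reference FASTA/metadata mismatch; "
            f"FASTA-only ids: {orphans_fasta}; metadata-only ids: {orphans_tsv}"
        )
    return entries


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a locus-level annotation TSV.

    Columns: ``locus_tag``, optional ``ko_id``, ``ec_numbers``
    (comma-separated), ``cazy_families`` (comma-separated), ``product``,
    optional ``category``.  EC syntax is validated; ``-`` is accepted only
    as a trailing wildcard (e.g. ``1.4.1.-``).
    """
    header, rows = read_tsv_rows(path)
    col = {name: i for i, name in enumerate(header)}
    if "locus_tag" not in col:
        raise SeqIOError(f"{path}: missing column 'locus_tag'")

    def get(row: Sequence[str], name: str) -> str:
        i = col.get(name)
        return row[i] if i is not None and i < len(row) else ""

    out: list[AnnotationRow] = []
    for lineno, row in enumerate(rows, start=2):
        ecs = tuple(e.strip() for e in get(row, "ec_numbers").split(",") if e.strip())
        for ec in ecs:
            if not validate_ec(ec):
                raise SeqIOError(f"{path}: malformed EC {ec!r} at row {lineno}")
        cazy = tuple(c.strip() for c in get(row, "cazy_families").split(",") if c.strip())
        ko = get(row, "ko_id").strip() or None
        if ko and not re.match(r"^K\d{5}$", ko):
            raise SeqIOError(f"{path}: malformed KO id {ko!r} at row {lineno}")
        out.append(
            AnnotationRow(
                locus_tag=get(row, "locus_tag"),
                ko_id=ko,
                ec_numbers=ecs,
                cazy_families=cazy,
                product=get(row, "product"),
                category=get(row, "category"),
            )
        )
    return AnnotationTable(rows=out)
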