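"""Pairwise delineation metrics.

This module holds desk-scale replacements for the heavy comparison engines a
full taxonomic pipeline would shell out to:

* :func:`pairwise_identity` — free-end-gap global alignment identity, the
  16S comparison currency (identity denominator = aligned columns including
  internal gaps, terminal gaps excluded).
* :func:`pocp` — percentage of conserved proteins, 100*(C1+C2)/(T1+T2) over
  reciprocal best-hit searches with the >40 % identity / >50 % alignable
  region criteria.
* :func:`fragment_ani` — ANIb-style average nucleotide identity: the query
  genome is cut into 1,020-nt fragments, each mapped to its best infix
  location in the other genome, and the mean identity of mapped fragments is
  averaged over both directions.
* :func:`sketch` / :func:`mash_distance` — MinHash genome sketching with the
  Mash distance d = -(1/k) * ln(2j/(1+j)).
* :func:`nj_tree` — neighbour joining on a distance matrix, emitting Newick.

Adapter protocols allow external ANI/protein-search/sketching tools to stand
in for the built-ins without changing callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import SequenceRecord

# ---------------------------------------------------------------------------
# alignment results


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentResult:
    identity: float        # % matches / aligned columns, terminal gaps excluded
    query_coverage: float  # % of the query inside the aligned span
    aligned_length: int    # aligned columns


@dataclass(frozen=True)
class PocpResult:
    c1: int
    c2: int
    t1: int
    t2: int

    @property
    def pocp(self) -> float:
        return 100.0 * (self.c1 + self.c2) / (self.t1 + self.t2)


@dataclass(frozen=True)
class AniResult:
    ani: float | None      # None when too few fragments map
    fragments_total: int
    fragments_mapped: int
    reciprocal: bool = True

    @property
    def defined(self) -> bool:
        return self.ani is not None


# ---------------------------------------------------------------------------
# nucleotide identity


def _make_dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    # free terminal gaps: partial overlaps are not penalised
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_DNA_ALIGNER = _make_dna_aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> AlignmentResult:
    """Global alignment of two nucleotide records with free terminal gaps.

    Identity = matches / aligned columns, where internal gaps count as
    columns and terminal gaps are excluded.  ``query_coverage`` is the
    percentage of ``a`` spanned by the non-terminal-gap alignment region.
    """
    for rec in (a, b):
        if rec.kind != "nucleotide":
            raise MetricError(f"record {rec.id!r} is not nucleotide")
        if not rec.seq:
            raise MetricError(f"record {rec.id!r} is empty")
    aln = _DNA_ALIGNER.align(a.seq, b.seq)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return AlignmentResult(identity=0.0, query_coverage=0.0, aligned_length=0)
    # span between first and last aligned block = alignment minus terminal gaps
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    matches = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        seg_a = a.seq[sa:ea]
        seg_b = b.seq[sb:sb + (ea - sa)]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y and x != "N")
    columns = 0
    prev_a, prev_b = a_start, b_start
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        columns += (sa - prev_a) + (sb - prev_b)  # internal gaps
        columns += ea - sa                        # aligned block
        prev_a, prev_b = ea, eb
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (a_end - a_start) / len(a.seq)
    return AlignmentResult(
        identity=identity,
        query_coverage=min(coverage, 100.0),
        aligned_length=columns,
    )


def gc_percent(genome: SequenceRecord) -> float:
    """Mol% G+C over unambiguous bases; N is excluded from both counts."""
    if genome.kind != "nucleotide":
        raise MetricError("gc_percent expects a nucleotide record")
    counts = {base: genome.seq.count(base) for base in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise MetricError(f"record {genome.id!r} has no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / total


# ---------------------------------------------------------------------------
# POCP


def _make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_PROT_ALIGNER = _make_protein_aligner()

# Conserved-protein criteria of the reciprocal proteome search.
POCP_IDENTITY_MIN = 40.0   # %, strict >
POCP_ALIGNED_FRACTION_MIN = 0.5  # of the query protein length, strict >
POCP_EVALUE_MAX = 1e-5     # applied only when the backend supplies e-values


@dataclass(frozen=True)
class ProteinHit:
    target_id: str
    identity: float          # % over aligned columns
    aligned_query_fraction: float
    evalue: float | None = None

    def is_conserved(self) -> bool:
        ok = (
            self.identity > POCP_IDENTITY_MIN
            and self.aligned_query_fraction > POCP_ALIGNED_FRACTION_MIN
        )
        if self.evalue is not None:
            ok = ok and self.evalue < POCP_EVALUE_MAX
        return ok


SearchBackend = Callable[
    [Sequence[SequenceRecord], Sequence[SequenceRecord]], list[ProteinHit | None]
]


def _builtin_protein_search(
    queries: Sequence[SequenceRecord], targets: Sequence[SequenceRecord]
) -> list[ProteinHit | None]:
    """Best local BLOSUM62 hit per query.

    Applies only the identity and alignable-region criteria downstream; a raw
    aligner has no e-value model, so the e-value criterion is left to
    external search adapters.
    """
    hits: list[ProteinHit | None] = []
    target_seqs = [t.seq for t in targets]
    for q in queries:
        best_score = -math.inf
        best_idx = -1
        for i, tseq in enumerate(target_seqs):
            score = _PROT_ALIGNER.score(q.seq, tseq)
            if score > best_score:
                best_score = score
                best_idx = i
        if best_idx < 0 or best_score <= 0:
            hits.append(None)
            continue
        aln = _PROT_ALIGNER.align(q.seq, target_seqs[best_idx])[0]
        blocks_q, blocks_t = aln.aligned
        matches = 0
        columns = 0
        prev_q = int(blocks_q[0][0])
        prev_t = int(blocks_t[0][0])
        for (sq, eq), (st, et) in zip(blocks_q, blocks_t):
            columns += (sq - prev_q) + (st - prev_t) + (eq - sq)
            seg_q = q.seq[sq:eq]
            seg_t = targets[best_idx].seq[st:st + (eq - sq)]
            matches += sum(1 for x, y in zip(seg_q, seg_t) if x == y)
            prev_q, prev_t = eq, et
        q_span = int(blocks_q[-1][1]) - int(blocks_q[0][0])
        hits.append(
            ProteinHit(
                target_id=targets[best_idx].id,
                identity=100.0 * matches / columns if columns else 0.0,
                aligned_query_fraction=q_span / len(q.seq),
            )
        )
    return hits


def pocp(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
    search_backend: SearchBackend | None = None,
) -> PocpResult:
    """Percentage of conserved proteins between two proteomes.

    A protein is conserved when its best hit in the other proteome has
    identity >40 % over >50 % of the query protein length (and e-value
    <1e-5 when the backend reports one).  POCP = 100*(C1+C2)/(T1+T2); the
    formula is symmetric in the two proteomes by construction.
    """
    if not proteome_a or not proteome_b:
        raise MetricError("both proteomes must be non-empty")
    backend = search_backend or _builtin_protein_search
    hits_ab = backend(proteome_a, proteome_b)
    hits_ba = backend(proteome_b, proteome_a)
    c1 = sum(1 for h in hits_ab if h is not None and h.is_conserved())
    c2 = sum(1 for h in hits_ba if h is not None and h.is_conserved())
    return PocpResult(c1=c1, c2=c2, t1=len(proteome_a), t2=len(proteome_b))


# ---------------------------------------------------------------------------
# fragment-based ANI

ANI_FRAGMENT_LENGTH = 1020
ANI_MIN_FRAGMENT_FRACTION = 0.7
ANI_MIN_FRAGMENT_IDENTITY = 70.0   # mapping floor, rejects random hits
ANI_MIN_MAPPED_FRAGMENTS = 5


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, columns) from an edlib extended CIGAR (=/X/I/D)."""
    matches = 0
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches, columns


def _best_infix_identity(fragment: str, target: str, target_rc: str) -> float:
    """Identity (%) of the fragment's best glocal placement on either strand."""
    best = 0.0
    for t in (target, target_rc):
        res = edlib.align(fragment, t, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        matches, columns = _cigar_stats(res["cigar"])
        if columns:
            best = max(best, 100.0 * matches / columns)
    return best


def _one_direction_ani(
    query: SequenceRecord,
    target: SequenceRecord,
    fragment_length: int,
) -> tuple[list[float], int]:
    target_rc = str(Seq(target.seq).reverse_complement())
    identities: list[float] = []
    n_fragments = len(query.seq) // fragment_length
    for i in range(n_fragments):
        frag = query.seq[i * fragment_length:(i + 1) * fragment_length]
        ident = _best_infix_identity(frag, target.seq, target_rc)
        if ident >= ANI_MIN_FRAGMENT_IDENTITY:
            identities.append(ident)
    return identities, n_fragments


def fragment_ani(
    genome_a: SequenceRecord,
    genome_b: SequenceRecord,
    fragment_length: int = ANI_FRAGMENT_LENGTH,
    min_fragment_fraction: float = ANI_MIN_FRAGMENT_FRACTION,
) -> AniResult:
    """Fragment-based average nucleotide identity, averaged reciprocally.

    ``genome_a`` is cut into non-overlapping ``fragment_length``-nt pieces;
    each is aligned to its best infix location in ``genome_b`` (both
    strands).  Fragments map when their best placement reaches the identity
    floor; ANI is the mean identity of mapped fragments, averaged with the
    reciprocal direction, and undefined when fewer than
    ``ANI_MIN_MAPPED_FRAGMENTS`` fragments map in either direction.
    """
    for g in (genome_a, genome_b):
        if g.kind != "nucleotide":
            raise MetricError(f"record {g.id!r} is not nucleotide")
        if len(g.seq) < 2 * fragment_length:
            raise MetricError(
                f"genome {g.id!r} shorter than two fragments "
                f"({len(g.seq)} < {2 * fragment_length})"
            )
    del min_fragment_fraction  # infix mapping consumes the whole fragment
    ids_ab, n_ab = _one_direction_ani(genome_a, genome_b, fragment_length)
    ids_ba, n_ba = _one_direction_ani(genome_b, genome_a, fragment_length)
    mapped = len(ids_ab) + len(ids_ba)
    if len(ids_ab) < ANI_MIN_MAPPED_FRAGMENTS or len(ids_ba) < ANI_MIN_MAPPED_FRAGMENTS:
        return AniResult(ani=None, fragments_total=n_ab + n_ba, fragments_mapped=mapped)
    ani = (float(np.mean(ids_ab)) + float(np.mean(ids_ba))) / 2.0
    return AniResult(ani=ani, fragments_total=n_ab + n_ba, fragments_mapped=mapped)


# ---------------------------------------------------------------------------
# MinHash sketching and Mash distance

SKETCH_K = 21
SKETCH_SIZE = 1000

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _splitmix64(x: int) -> int:
    """64-bit finalising mixer (splitmix64); deterministic across runs."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Sketch:
    k: int
    s: int
    hashes: tuple[int, ...]  # sorted ascending, bottom-s

    def __post_init__(self) -> None:
        if len(self.hashes) > self.s:
            raise MetricError("sketch holds more than s hashes")
        if any(a > b for a, b in zip(self.hashes, self.hashes[1:])):
            raise MetricError("sketch hashes must be sorted ascending")


def sketch(genome: SequenceRecord, k: int = SKETCH_K, s: int = SKETCH_SIZE) -> Sketch:
    """Bottom-s MinHash sketch over canonical k-mers (2-bit packed, 64-bit mixed)."""
    if genome.kind != "nucleotide":
        raise MetricError("sketch expects a nucleotide record")
    seq = genome.seq
    rc = seq.translate(_COMPLEMENT)[::-1]
    n = len(seq)
    hashes: set[int] = set()
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        if "N" in fwd:
            continue
        rev = rc[n - k - i:n - i]
        kmer = min(fwd, rev)  # canonical: lexicographic min of the two strands
        code = 0
        for ch in kmer:
            code = (code << 2) | _BASE_CODE[ch]
        hashes.add(_splitmix64(code))
    bottom = sorted(hashes)[:s]
    return Sketch(k=k, s=s, hashes=tuple(bottom))


def mash_distance(x: Sketch, y: Sketch) -> float:
    """Mash distance d = -(1/k) * ln(2j / (1+j)); d = 1 when j = 0.

    The Jaccard index j is estimated from the bottom-s hashes of the merged
    hash sets, as in the MinHash bottom-sketch estimator.
    """
    if x.k != y.k or x.s != y.s:
        raise MetricError("sketches must share k and s")
    merged = sorted(set(x.hashes) | set(y.hashes))[:min(x.s, len(x.hashes) + len(y.hashes))]
    if not merged:
        raise MetricError("cannot compare empty sketches")
    both = set(x.hashes) & set(y.hashes)
    shared = sum(1 for h in merged if h in both)
    j = shared / len(merged)
    return jaccard_to_mash(j, x.k)


def jaccard_to_mash(j: float, k: int) -> float:
    """Closed-form Mash distance for a Jaccard index j; capped at 1 for j=0."""
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    return min(1.0, -(1.0 / k) * math.log(2.0 * j / (1.0 + j)))


# ---------------------------------------------------------------------------
# neighbour joining


def identity_to_distance(identity: float) -> float:
    """16S identity (%) -> tree distance d = 1 - identity/100."""
    return 1.0 - identity / 100.0


def nj_tree(labels: Sequence[str], distance_matrix: np.ndarray | Sequence[Sequence[float]]) -> str:
    """Neighbour joining on a symmetric distance matrix; returns Newick.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, so pair sums are preserved.
    """
    d = np.asarray(distance_matrix, dtype=float).copy()
    n = len(labels)
    if d.shape != (n, n):
        raise MetricError("distance matrix shape does not match labels")
    if n < 2:
        raise MetricError("need at least two taxa")
    if not np.allclose(d, d.T, atol=1e-9):
        raise MetricError("distance matrix is asymmetric beyond tolerance")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise MetricError("distance matrix diagonal must be zero")

    nodes: list[str] = [str(label) for label in labels]
    if len(set(nodes)) != len(nodes):
        raise MetricError("duplicate labels")

    active = list(range(n))
    subtrees = {i: nodes[i] for i in active}

    def _clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0.0:
            lb += la
            la = 0.0
        if lb < 0.0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_pos, j_pos = divmod(int(np.argmin(q)), m)
        if i_pos > j_pos:
            i_pos, j_pos = j_pos, i_pos
        i, j = active[i_pos], active[j_pos]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        # distances from the new node u to every other active node
        u = d.shape[0]
        new_row = np.zeros(u + 1)
        grown = np.zeros((u + 1, u + 1))
        grown[:u, :u] = d
        for k_pos, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        grown[u, :] = new_row
        grown[:, u] = new_row
        d = grown
        subtrees[u] = f"({subtrees.pop(i)}:{li:.10g},{subtrees.pop(j)}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [u]

    if len(active) == 3:
        # trifurcating root via the three-point formulas
        i, j, k = active
        la = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lb = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lc = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        la, lb = _clamp(la, lb)
        lb, lc = _clamp(lb, lc)
        return (
            f"({subtrees[i]}:{la:.10g},{subtrees[j]}:{lb:.10g},"
            f"{subtrees[k]}:{lc:.10g});"
        )
    i, j = active
    half = d[i, j] / 2.0
    return f"({subtrees[i]}:{half:.10g},{subtrees[j]}:{half:.10g});"


def write_distance_matrix(labels: Sequence[str], d: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["", *labels]) + "\n")
        for label, row in zip(labels, np.asarray(d)):
            fh.write("\t".join([label, *(f"{v:.10g}" for v in row)]) + "\n")


def read_distance_matrix(path: str) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return header, np.asarray(rows)
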