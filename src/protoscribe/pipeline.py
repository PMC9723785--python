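"""End-to-end orchestration: inputs -> QC -> evidence -> name -> report."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import ThresholdConfig
from .ecology import (
    OccurrenceStats,
    mag_matches,
    occurrence,
    qualify_hits,
    read_mag_distances,
    read_otu_table,
)
from .metrics import fragment_ani, gc_percent, pairwise_identity, pocp
from .nomenclature import NameProposal, propose_name
from .qc import QcReport, run_qc
from .report import ProtologueReport, render
from .seqio import read_annotation_table, read_fasta, read_reference_set
from .taxonomy import classify_novelty, filter_valid, rank_candidates
from .traits import evaluate_profile, load_ko_to_ec

logger = logging.getLogger("protoscribe")


def read_samples_per_env(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["environment"], df["n_samples"].astype(int)))


def read_quality_values(path: str | Path, genome_id: str | None = None):
    df = pd.read_csv(path, sep="\t", comment="#")
    if genome_id is not None and "genome_id" in df.columns:
        sub = df[df["genome_id"] == genome_id]
        if len(sub):
            df = sub
    row = df.iloc[0]
    return float(row["completeness"]), float(row["contamination"])


def run_isolate(
    s16_path: str | Path,
    genome_path: str | Path,
    refs_fasta: str | Path,
    refs_meta: str | Path,
    names_path: str | Path,
    annotation_path: str | Path | None = None,
    proteome_path: str | Path | None = None,
    otu_hits_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    mag_dist_path: str | Path | None = None,
    quality_path: str | Path | None = None,
    ko_map_path: str | Path | None = None,
    cfg: ThresholdConfig | None = None,
    seed: int = 42,
    isolation_source: str | None = None,
    max_genome_comparisons: int = 3,
) -> ProtologueReport:
    """Run the whole desk-scale workflow for one isolate.

    Genome-based metrics (ANI, POCP, G+C delta) are computed against the
    top ``max_genome_comparisons`` validly named candidates that ship type
    genome/proteome paths; the rest keep 16S evidence only.
    """
    cfg = cfg or ThresholdConfig()
    query16s = read_fasta(s16_path, kind="nucleotide")[0]
    genome = read_fasta(genome_path, kind="nucleotide")[0]
    references = read_reference_set(refs_fasta, refs_meta)
    with open(names_path, encoding="utf-8") as fh:
        names = {line.strip() for line in fh if line.strip() and not line.startswith("#")}

    candidates, warnings = rank_candidates(query16s, references, cfg)
    best_ref = candidates[0].entry.record if candidates else None

    completeness = contamination = None
    if quality_path is not None:
        completeness, contamination = read_quality_values(quality_path, genome.id)
    qc: QcReport = run_qc(
        query16s,
        references,
        best_ref,
        cfg,
        genome_completeness=completeness,
        contamination=contamination,
    )
    qc.warnings.extend(warnings)

    valid, _discarded = filter_valid(candidates, names) if candidates else ([], [])
    query_gc = gc_percent(genome)
    proteome = read_fasta(proteome_path, kind="protein") if proteome_path else None
    compared = 0
    for cand in valid:
        if compared >= max_genome_comparisons:
            break
        did_any = False
        if cand.entry.type_genome_path:
            ref_genome = read_fasta(cand.entry.type_genome_path, kind="nucleotide")[0]
            cand.ani = fragment_ani(genome, ref_genome)
            cand.gc_delta = abs(query_gc - gc_percent(ref_genome))
            did_any = True
        if proteome is not None and cand.entry.type_proteome_path:
            ref_proteome = read_fasta(cand.entry.type_proteome_path, kind="protein")
            cand.pocp = pocp(proteome, ref_proteome)
            did_any = True
        if did_any:
            compared += 1

    novelty = classify_novelty(valid or candidates, cfg) if candidates else classify_novelty([], cfg)

    ko_map = load_ko_to_ec(ko_map_path) if ko_map_path else None
    if annotation_path is not None:
        annotation = read_annotation_table(annotation_path)
        profile = evaluate_profile(annotation, ko_to_ec=ko_map)
    else:
        from .seqio import AnnotationTable

        profile = evaluate_profile(AnnotationTable(rows=[]))

    stats: OccurrenceStats | None = None
    if otu_hits_path is not None and samples_path is not None:
        table = qualify_hits(read_otu_table(otu_hits_path), cfg)
        stats = occurrence(table, read_samples_per_env(samples_path))

    mag_counts = None
    if mag_dist_path is not None:
        _kept, mag_counts = mag_matches(read_mag_distances(mag_dist_path), cfg)

    name: NameProposal | None = None
    if stats is not None:
        name = propose_name(
            stats, profile, seed=seed, isolation_source=isolation_source
        )

    return render(
        novelty=novelty,
        profile=profile,
        candidates=valid or candidates,
        qc=qc,
        occurrence=stats,
        name=name,
        gc=query_gc,
        mag_counts=mag_counts,
        isolate_id=query16s.id,
    )
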