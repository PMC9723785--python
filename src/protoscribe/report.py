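"""Protologue-style report assembly.

Renders the typed results of every analysis stage into a deterministic
plain-text overview plus a machine-readable structured twin carrying every
rendered number (so downstream systems never re-parse prose).  Percentages
are rounded to one decimal place in the text; omitted inputs yield explicit
"not assessed" lines, never silent absence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .ecology import OccurrenceStats
from .nomenclature import NameProposal
from .qc import QcReport
from .taxonomy import CandidateRelative, NoveltyCall
from .traits import PRESENT, TraitProfile

NOT_ASSESSED = "not assessed"


def _fmt(value: float | None) -> str:
    return NOT_ASSESSED if value is None else f"{value:.1f}"


@dataclass
class ProtologueReport:
    text: str
    data: dict = field(default_factory=dict)

    def write(self, text_path: str, json_path: str) -> None:
        with open(text_path, "w") as fh:
            fh.write(self.text)
        with open(json_path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def render(
    novelty: NoveltyCall,
    profile: TraitProfile,
    candidates: Sequence[CandidateRelative] = (),
    qc: QcReport | None = None,
    occurrence: OccurrenceStats | None = None,
    name: NameProposal | None = None,
    gc: float | None = None,
    mag_counts: dict[str, int] | None = None,
    isolate_id: str = "isolate",
) -> ProtologueReport:
    lines: list[str] = []
    data: dict = {"isolate_id": isolate_id}

    lines.append(f"Protologue overview for {isolate_id}")
    lines.append("=" * len(lines[-1]))
    lines.append("")

    # --- proposed name -----------------------------------------------------
    lines.append("Proposed name")
    lines.append("-------------")
    if name is not None:
        lines.append(f"{name.binomial} ({name.gender}.)")
        lines.append(f"Genus etymology: {name.etymology_genus}")
        lines.append(f"Epithet etymology: {name.etymology_species}")
        lines.append(
            f"Naming environment: {name.basis_environment} "
            f"(habitat score {name.basis_habitat_score:.1f}); "
            f"naming trait: {name.basis_trait}"
        )
        if name.flags:
            lines.append(f"Flags: {', '.join(name.flags)}")
        data["name"] = {
            "genus": name.genus_name,
            "epithet": name.species_epithet,
            "gender": name.gender,
            "environment": name.basis_environment,
            "habitat_score": round(name.basis_habitat_score, 1),
            "trait": name.basis_trait,
            "flags": list(name.flags),
        }
    else:
        lines.append(NOT_ASSESSED)
        data["name"] = None
    lines.append("")

    # --- quality -----------------------------------------------------------
    lines.append("Quality control")
    lines.append("---------------")
    if qc is not None:
        lines.append(f"16S completeness: {_fmt(qc.s16_completeness)}%")
        chim = "not evaluable"
        if qc.chimera is not None and not qc.chimera.note:
            chim = "chimeric" if qc.chimera.is_chimeric else "not chimeric"
        lines.append(f"16S chimera screen: {chim}")
        lines.append(f"Genome completeness: {_fmt(qc.genome_completeness)}%")
        lines.append(f"Genome contamination: {_fmt(qc.contamination)}%")
        lines.append(
            "Warnings: " + (", ".join(qc.warnings) if qc.warnings else "none")
        )
        data["qc"] = {
            "s16_completeness": None
            if qc.s16_completeness is None
            else round(qc.s16_completeness, 1),
            "chimera": chim,
            "genome_completeness": None
            if qc.genome_completeness is None
            else round(qc.genome_completeness, 1),
            "contamination": None
            if qc.contamination is None
            else round(qc.contamination, 1),
            "warnings": list(qc.warnings),
        }
    else:
        lines.append(NOT_ASSESSED)
        data["qc"] = None
    lines.append("")

    # --- taxonomy ----------------------------------------------------------
    lines.append("Taxonomic placement")
    lines.append("-------------------")
    data["candidates"] = []
    if candidates:
        lines.append("closest relatives (16S identity %, ANI %, POCP %, dG+C):")
        for cand in candidates[:10]:
            ani = _fmt(cand.ani.ani) if cand.ani is not None and cand.ani.defined else NOT_ASSESSED
            pocp = _fmt(cand.pocp.pocp) if cand.pocp is not None else NOT_ASSESSED
            gcd = _fmt(cand.gc_delta)
            lines.append(
                f"  {cand.entry.species_name}: {cand.identity:.1f}, {ani}, {pocp}, {gcd}"
            )
            data["candidates"].append(
                {
                    "species": cand.entry.species_name,
                    "identity": round(cand.identity, 1),
                    "ani": None
                    if cand.ani is None or not cand.ani.defined
                    else round(cand.ani.ani, 1),
                    "pocp": None if cand.pocp is None else round(cand.pocp.pocp, 1),
                    "gc_delta": None if cand.gc_delta is None else round(cand.gc_delta, 1),
                }
            )
    else:
        lines.append("closest relatives: none passed the candidate filters")
    verdicts = {
        "16S": novelty.verdict_16s,
        "ANI": novelty.verdict_ani,
        "POCP": novelty.verdict_pocp,
        "G+C": novelty.verdict_gc,
    }
    for method, verdict in verdicts.items():
        lines.append(f"{method} verdict: {verdict}")
    lines.append(f"Consensus: {novelty.consensus}")
    conflict_text = (
        "; ".join(f"{a} vs {b}" for a, b in novelty.conflicts)
        if novelty.conflicts
        else "none"
    )
    lines.append(f"Evidence conflicts: {conflict_text}")
    data["novelty"] = {
        "verdicts": {
            "16s": novelty.verdict_16s,
            "ani": novelty.verdict_ani,
            "pocp": novelty.verdict_pocp,
            "gc": novelty.verdict_gc,
        },
        "consensus": novelty.consensus,
        "conflicts": [list(c) for c in novelty.conflicts],
        "supporting": {
            k: (round(v, 1) if isinstance(v, float) else v)
            for k, v in novelty.supporting.items()
        },
    }
    lines.append("")

    # --- traits ------------------------------------------------------------
    lines.append("Functional repertoire")
    lines.append("---------------------")
    present = [
        (trait, call) for trait, call in profile.calls.items() if call.call == PRESENT
    ]
    if present:
        for trait, call in present:
            ev = ", ".join(call.evidence)
            lines.append(f"{trait}: present ({ev})")
    else:
        lines.append("no configured pathway was called present")
    lines.append(f"CAZymes identified: {profile.cazyme_count}")
    if profile.substrate_calls:
        lines.append(
            "Predicted carbohydrate substrates: " + ", ".join(profile.substrate_calls)
        )
    lines.append(
        f"KEGG categories: {profile.transporter_count} transporters, "
        f"{profile.secretion_gene_count} secretion genes and "
        f"{profile.enzyme_count} enzymes"
    )
    crispr = (
        NOT_ASSESSED
        if profile.crispr_array_count is None
        else str(profile.crispr_array_count)
    )
    lines.append(f"CRISPR arrays: {crispr}")
    data["traits"] = {
        "calls": {t: c.call for t, c in profile.calls.items()},
        "evidence": {t: list(c.evidence) for t, c in profile.calls.items()},
        "cazyme_count": profile.cazyme_count,
        "substrates": list(profile.substrate_calls),
        "transporter_count": profile.transporter_count,
        "secretion_gene_count": profile.secretion_gene_count,
        "enzyme_count": profile.enzyme_count,
        "crispr_array_count": profile.crispr_array_count,
    }
    lines.append("")

    # --- ecology -----------------------------------------------------------
    lines.append("Habitat preference")
    lines.append("------------------")
    if occurrence is not None:
        data["ecology"] = []
        for stats in occurrence.top_environments(5):
            if stats.n_positive == 0:
                continue
            lines.append(
                f"{stats.environment}: prevalence {stats.prevalence:.1f}% "
                f"({stats.n_positive}/{stats.n_samples} samples), mean relative "
                f"abundance in positive samples {stats.mean_relabund_positive:.2f}%, "
                f"habitat score {stats.habitat_score:.1f}"
            )
            data["ecology"].append(
                {
                    "environment": stats.environment,
                    "prevalence": round(stats.prevalence, 1),
                    "n_positive": stats.n_positive,
                    "n_samples": stats.n_samples,
                    "mean_relabund_positive": round(stats.mean_relabund_positive, 2),
                    "habitat_score": round(stats.habitat_score, 1),
                }
            )
        if not data["ecology"]:
            lines.append("no environment had a positive sample")
    else:
        lines.append(NOT_ASSESSED)
        data["ecology"] = None
    if mag_counts is not None:
        if mag_counts:
            counts = ", ".join(f"{env}: {n}" for env, n in sorted(mag_counts.items()))
            lines.append(f"MAG collection matches (distance < threshold): {counts}")
        else:
            lines.append("MAG collection matches: none below the distance threshold")
        data["mag_counts"] = dict(sorted(mag_counts.items()))
    else:
        lines.append(f"MAG collection matches: {NOT_ASSESSED}")
        data["mag_counts"] = None
    lines.append("")

    # --- G+C and type strain ----------------------------------------------
    if gc is not None:
        lines.append(f"The G+C content of genomic DNA is {gc:.1f}%.")
        data["gc_percent"] = round(gc, 1)
    else:
        lines.append(f"G+C content: {NOT_ASSESSED}")
        data["gc_percent"] = None
    lines.append(
        f"The type strain is {isolate_id} (= <culture collection accession "
        "pending>), isolated from <source to be stated by the describing authors>."
    )
    lines.append("")

    return ProtologueReport(text="\n".join(lines), data=data)
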