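"""Rule-based physiological trait inference from an annotation table.

Traits come in three kinds: *pathway* rules are satisfied when every
required EC pattern (trailing ``-`` fields are wildcards) is matched by at
least one annotated EC, with alternative EC sets allowed; *gene_list* rules
are satisfied when at least ``min_fraction`` of their genes are annotated;
*stub* rules are named features whose content is user configuration and
which evaluate to ``not_evaluable`` until configured.

The shipped default ruleset covers 30 features.  Its pathway EC content is
the set of short-chain-fatty-acid, amino-acid and vitamin pathways this
kind of genome-based species description reports (acetate from acetyl-CoA,
propionate from propanoyl-CoA, butyrate from butanoyl-CoA, cysteine/acetate
from sulfide+serine, glutamate from ammonia, folate, riboflavin,
cobalamin); annotation itself (the gene caller / KO assignment) is an
upstream input, never performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seqio import AnnotationTable, SeqIOError, read_tsv_rows, validate_ec

PRESENT = "present"
ABSENT = "absent"
NOT_EVALUABLE = "not_evaluable"


class TraitError(ValueError):
    pass


@dataclass(frozen=True)
class TraitRule:
    name: str
    kind: str  # pathway | gene_list | stub
    required_ec: tuple[str, ...] = ()
    alternatives: tuple[tuple[str, ...], ...] = ()
    gene_ids: tuple[str, ...] = ()
    min_fraction: float = 0.5
    citation_note: str = ""

    def __post_init__(self) -> None:
        if self.kind == "pathway":
            if not self.required_ec:
                raise TraitError(f"pathway rule {self.name!r} needs at least one EC")
            for ec in (*self.required_ec, *(e for alt in self.alternatives for e in alt)):
                if not validate_ec(ec):
                    raise TraitError(f"rule {self.name!r}: malformed EC {ec!r}")
        elif self.kind == "gene_list":
            if not self.gene_ids:
                raise TraitError(f"gene_list rule {self.name!r} needs at least one gene")
            if not 0.0 < self.min_fraction <= 1.0:
                raise TraitError(f"rule {self.name!r}: min_fraction must be in (0, 1]")
        elif self.kind != "stub":
            raise TraitError(f"unknown rule kind {self.kind!r}")


@dataclass
class TraitCall:
    call: str
    evidence: tuple[str, ...] = ()
    missing: tuple[str, ...] = ()


@dataclass
class TraitProfile:
    calls: dict[str, TraitCall] = field(default_factory=dict)
    cazyme_count: int = 0
    substrate_calls: tuple[str, ...] = ()
    transporter_count: int = 0
    secretion_gene_count: int = 0
    enzyme_count: int = 0
    crispr_array_count: int | None = None

    def present_traits(self) -> list[str]:
        return [name for name, c in self.calls.items() if c.call == PRESENT]


def ec_matches(query_ec: str, pattern_ec: str) -> bool:
    """True iff all non-wildcard fields of the pattern equal the query's."""
    if not validate_ec(query_ec) or not validate_ec(pattern_ec):
        raise TraitError(f"malformed EC in match: {query_ec!r} vs {pattern_ec!r}")
    for q, p in zip(query_ec.split("."), pattern_ec.split(".")):
        if p != "-" and p != q:
            return False
    return True


def _annotation_ecs(
    annotation: AnnotationTable, ko_to_ec: dict[str, tuple[str, ...]] | None
) -> set[str]:
    ecs = set(annotation.all_ecs())
    if ko_to_ec:
        for ko in annotation.all_kos():
            ecs.update(ko_to_ec.get(ko, ()))
    return ecs


def _annotation_genes(annotation: AnnotationTable) -> set[str]:
    """Gene symbols are matched against whitespace-delimited product tokens."""
    tokens: set[str] = set()
    for row in annotation.rows:
        tokens.update(t.casefold() for t in row.product.split())
    return tokens


def evaluate_trait(
    annotation: AnnotationTable,
    rule: TraitRule,
    ko_to_ec: dict[str, tuple[str, ...]] | None = None,
) -> TraitCall:
    """Evaluate one rule; present calls always carry their matched evidence."""
    if rule.kind == "stub":
        return TraitCall(call=NOT_EVALUABLE)
    if rule.kind == "gene_list":
        genes = _annotation_genes(annotation)
        hit = tuple(g for g in rule.gene_ids if g.casefold() in genes)
        fraction = len(hit) / len(rule.gene_ids)
        missing = tuple(g for g in rule.gene_ids if g.casefold() not in genes)
        if fraction >= rule.min_fraction:
            return TraitCall(call=PRESENT, evidence=hit, missing=missing)
        return TraitCall(call=ABSENT, evidence=hit, missing=missing)
    # pathway: any alternative EC set suffices
    ecs = _annotation_ecs(annotation, ko_to_ec)
    best_hit: tuple[str, ...] = ()
    best_missing: tuple[str, ...] | None = None
    for ec_set in (rule.required_ec, *rule.alternatives):
        hit: list[str] = []
        missing: list[str] = []
        for pattern in ec_set:
            matched = sorted(ec for ec in ecs if ec_matches(ec, pattern))
            if matched:
                hit.extend(matched)
            else:
                missing.append(pattern)
        if not missing:
            return TraitCall(call=PRESENT, evidence=tuple(hit))
        if best_missing is None or len(missing) < len(best_missing):
            best_hit, best_missing = tuple(hit), tuple(missing)
    return TraitCall(call=ABSENT, evidence=best_hit, missing=best_missing or ())


def evaluate_profile(
    annotation: AnnotationTable,
    ruleset: list[TraitRule] | None = None,
    ko_to_ec: dict[str, tuple[str, ...]] | None = None,
    cazy_substrate_map: dict[str, str] | None = None,
    crispr_array_count: int | None = None,
) -> TraitProfile:
    """Evaluate every rule and tally the annotation-level counts."""
    rules = ruleset if ruleset is not None else default_ruleset()
    if not rules:
        raise TraitError("empty ruleset")
    substrates = (
        cazy_substrate_map if cazy_substrate_map is not None else default_substrate_map()
    )
    profile = TraitProfile(crispr_array_count=crispr_array_count)
    for rule in rules:
        profile.calls[rule.name] = evaluate_trait(annotation, rule, ko_to_ec)
    profile.cazyme_count = sum(1 for row in annotation.rows if row.cazy_families)
    called: set[str] = set()
    for row in annotation.rows:
        for fam in row.cazy_families:
            base = fam.split("_")[0]
            if base in substrates:
                called.add(substrates[base])
    profile.substrate_calls = tuple(sorted(called))
    for row in annotation.rows:
        cat = row.category.strip().casefold()
        if cat == "transporter":
            profile.transporter_count += 1
        elif cat == "secretion":
            profile.secretion_gene_count += 1
        elif cat == "enzyme":
            profile.enzyme_count += 1
    return profile


# ---------------------------------------------------------------------------
# shipped configuration


def _data_path(name: str) -> Path:
    return Path(str(resources.files("protoscribe").joinpath("data", name)))


def load_ruleset(path: str | Path) -> list[TraitRule]:
    header, rows = read_tsv_rows(path)
    col = {name: i for i, name in enumerate(header)}

    def get(row: list[str], name: str) -> str:
        i = col.get(name)
        return row[i] if i is not None and i < len(row) else ""

    rules: list[TraitRule] = []
    for row in rows:
        alternatives = tuple(
            tuple(e.strip() for e in alt.split(",") if e.strip())
            for alt in get(row, "alternatives").split("|")
            if alt.strip()
        )
        rules.append(
            TraitRule(
                name=get(row, "name"),
                kind=get(row, "kind"),
                required_ec=tuple(
                    e.strip() for e in get(row, "required_ec").split(",") if e.strip()
                ),
                alternatives=alternatives,
                gene_ids=tuple(
                    g.strip() for g in get(row, "gene_ids").split(",") if g.strip()
                ),
                min_fraction=float(get(row, "min_fraction") or 0.5),
                citation_note=get(row, "note"),
            )
        )
    if len({r.name for r in rules}) != len(rules):
        raise TraitError("duplicate rule names in ruleset")
    return rules


def default_ruleset() -> list[TraitRule]:
    return load_ruleset(_data_path("trait_rules.tsv"))


def load_substrate_map(path: str | Path) -> dict[str, str]:
    header, rows = read_tsv_rows(path)
    col = {name: i for i, name in enumerate(header)}
    if "family" not in col or "substrate" not in col:
        raise SeqIOError(f"{path}: substrate map needs 'family' and 'substrate' columns")
    return {row[col["family"]]: row[col["substrate"]] for row in rows}


def default_substrate_map() -> dict[str, str]:
    return load_substrate_map(_data_path("cazy_substrates.tsv"))


def load_ko_to_ec(path: str | Path) -> dict[str, tuple[str, ...]]:
    """KO -> EC translation table (columns: ko_id, ec_numbers comma-separated)."""
    header, rows = read_tsv_rows(path)
    col = {name: i for i, name in enumerate(header)}
    if "ko_id" not in col or "ec_numbers" not in col:
        raise SeqIOError(f"{path}: KO map needs 'ko_id' and 'ec_numbers' columns")
    out: dict[str, tuple[str, ...]] = {}
    for row in rows:
        ecs = tuple(e.strip() for e in row[col["ec_numbers"]].split(",") if e.strip())
        for ec in ecs:
            if not validate_ec(ec):
                raise SeqIOError(f"{path}: malformed EC {ec!r}")
        out[row[col["ko_id"]]] = ecs
    return out
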