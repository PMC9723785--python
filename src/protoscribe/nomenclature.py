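"""Ecology- and trait-informed candidate name generation.

The genus name is built from a combining form keyed to the environment with
the highest habitat score (prevalence x mean relative abundance in positive
samples) plus a gendered stem; the species epithet is chosen from the
highest-priority present trait, with its suffix form agreeing with the
genus gender.  Gendered forms are explicit masc/fem/neut triples in the
lexicon — no Latin morphology is inflected algorithmically.  Generation is
a pure function of (stats, profile, lexicon, priority, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .ecology import OccurrenceStats
from .seqio import SeqIOError, read_tsv_rows
from .traits import TraitProfile

GENDERS = ("masc", "fem", "neut")

# SCFA products first (butyrate > propionate > acetate), then substrate
# traits, then nitrogen traits.  Configurable per call.
DEFAULT_TRAIT_PRIORITY: tuple[str, ...] = (
    "butyrate_production",
    "propionate_production",
    "acetate_production",
    "starch_utilisation",
    "cellulose_utilisation",
    "glutamate_from_ammonia",
)

FALLBACK_TRAIT = "__fallback__"


class NomenclatureError(ValueError):
    pass


@dataclass(frozen=True)
class GenusPrefix:
    environment: str
    form: str
    etymology: str  # component gloss, e.g. "L. masc. n. porcus, a piglet; ..."


@dataclass(frozen=True)
class GenusStem:
    form: str
    gender: str
    etymology: str


@dataclass(frozen=True)
class EpithetRoot:
    trait: str
    forms: dict[str, str]  # gender -> suffix form
    part_of_speech: str    # "adj" or "gen_n"
    components: str
    gloss: str

    def form_for(self, gender: str) -> str:
        return self.forms[gender]


@dataclass
class Lexicon:
    prefixes: dict[str, list[GenusPrefix]] = field(default_factory=dict)
    stems: list[GenusStem] = field(default_factory=list)
    epithets: dict[str, EpithetRoot] = field(default_factory=dict)

    def validate(self, environments: tuple[str, ...]) -> None:
        missing = [e for e in environments if not self.prefixes.get(e)]
        if missing:
            raise NomenclatureError(f"environments without prefixes: {missing}")
        if not self.stems:
            raise NomenclatureError("lexicon has no genus stems")
        for root in self.epithets.values():
            for g in GENDERS:
                if not root.forms.get(g):
                    raise NomenclatureError(
                        f"epithet root {root.trait!r} lacks a {g} form"
                    )
        if FALLBACK_TRAIT not in self.epithets:
            raise NomenclatureError("lexicon must ship a fallback epithet root")


@dataclass
class NameProposal:
    genus_name: str
    species_epithet: str
    gender: str
    etymology_genus: str
    etymology_species: str
    basis_environment: str
    basis_habitat_score: float
    basis_trait: str
    basis_evidence: tuple[str, ...]
    flags: list[str] = field(default_factory=list)

    @property
    def binomial(self) -> str:
        return f"{self.genus_name} {self.species_epithet}"


def load_lexicon(path: str | Path) -> Lexicon:
    _header, rows = read_tsv_rows(path)
    lex = Lexicon()
    for row in rows:
        section = row[0]
        if section == "prefix":
            env, form, _gender, etym = row[1], row[2], row[3], row[4]
            lex.prefixes.setdefault(env, []).append(
                GenusPrefix(environment=env, form=form, etymology=etym)
            )
        elif section == "stem":
            _key, form, gender, etym = row[1], row[2], row[3], row[4]
            if gender not in GENDERS:
                raise SeqIOError(f"stem {form!r}: unknown gender {gender!r}")
            lex.stems.append(GenusStem(form=form, gender=gender, etymology=etym))
        elif section == "epithet":
            trait, forms_str, pos, payload = row[1], row[2], row[3], row[4]
            forms = forms_str.split("|")
            if len(forms) != 3:
                raise SeqIOError(f"epithet {trait!r}: need masc|fem|neut forms")
            components, _, gloss = payload.partition("::")
            lex.epithets[trait] = EpithetRoot(
                trait=trait,
                forms=dict(zip(GENDERS, forms)),
                part_of_speech=pos,
                components=components,
                gloss=gloss or components,
            )
        else:
            raise SeqIOError(f"unknown lexicon section {section!r}")
    return lex


def default_lexicon() -> Lexicon:
    path = Path(str(resources.files("protoscribe").joinpath("data", "name_lexicon.tsv")))
    return load_lexicon(path)


def pick_environment(
    stats: OccurrenceStats, isolation_source: str | None = None
) -> tuple[str, float, list[str]]:
    """Environment with maximal habitat score; ties broken by higher
    prevalence, then label order.  Falls back to the environment of
    isolation (flagged) when every score is zero."""
    if not stats.per_environment:
        raise NomenclatureError("occurrence stats are empty")
    ranked = sorted(
        stats.per_environment.values(),
        key=lambda s: (-s.habitat_score, -s.prevalence, s.environment),
    )
    best = ranked[0]
    if best.habitat_score == 0.0:
        if isolation_source:
            return isolation_source, 0.0, ["ENVIRONMENT_FROM_ISOLATION_SOURCE"]
        return best.environment, 0.0, ["ALL_HABITAT_SCORES_ZERO"]
    return best.environment, best.habitat_score, []


def compose_genus(
    environment: str, lexicon: Lexicon, seed: int = 42
) -> tuple[str, str, str]:
    """(genus name, gender, etymology line); prefix and stem are a seeded
    random choice among the environment's lexicon entries."""
    prefixes = lexicon.prefixes.get(environment)
    if not prefixes:
        raise NomenclatureError(f"no genus prefixes for environment {environment!r}")
    rng = random.Random(seed)
    prefix = rng.choice(sorted(prefixes, key=lambda p: p.form))
    stem = rng.choice(sorted(lexicon.stems, key=lambda s: s.form))
    name = prefix.form + stem.form
    name = name[0].upper() + name[1:].lower()
    etymology = (
        f"{prefix.etymology}; {stem.etymology}; "
        f"N.L. {stem.gender}. n. {name}, a microbe frequently occurring in "
        f"{environment} samples"
    )
    return name, stem.gender, etymology


def compose_epithet(
    profile: TraitProfile,
    genus_gender: str,
    lexicon: Lexicon,
    priority: tuple[str, ...] = DEFAULT_TRAIT_PRIORITY,
    seed: int = 42,
) -> tuple[str, str, str, tuple[str, ...], list[str]]:
    """(epithet, etymology line, chosen trait, evidence, flags).

    The highest-priority present trait with a lexicon root wins; substrate
    calls count as present ``<substrate>_utilisation`` traits.  When nothing
    qualifies, a neutral fallback root is used and flagged.
    """
    if genus_gender not in GENDERS:
        raise NomenclatureError(f"unknown gender {genus_gender!r}")
    del seed  # the choice is fully determined by the priority order
    present = set(profile.present_traits())
    present.update(f"{s}_utilisation" for s in profile.substrate_calls)
    flags: list[str] = []
    chosen: str | None = None
    for trait in priority:
        if trait in present and trait in lexicon.epithets:
            chosen = trait
            break
    if chosen is None:
        chosen = FALLBACK_TRAIT
        flags.append("EPITHET_FALLBACK_NO_NAMED_TRAIT")
        evidence: tuple[str, ...] = ()
    else:
        call = profile.calls.get(chosen)
        evidence = call.evidence if call is not None else ()
        if not evidence and chosen.endswith("_utilisation"):
            evidence = (chosen.replace("_utilisation", " (CAZyme substrate call)"),)
    root = lexicon.epithets[chosen]
    form = root.form_for(genus_gender)
    if root.part_of_speech == "gen_n":
        line = f"{root.components}; L. gen. neut. n. {form}, {root.gloss}"
    else:
        line = f"{root.components}; N.L. {genus_gender}. adj. {form}, {root.gloss}"
    return form, line, chosen, evidence, flags


def propose_name(
    stats: OccurrenceStats,
    profile: TraitProfile,
    lexicon: Lexicon | None = None,
    priority: tuple[str, ...] = DEFAULT_TRAIT_PRIORITY,
    seed: int = 42,
    isolation_source: str | None = None,
) -> NameProposal:
    """End-to-end: pick the naming environment, compose genus and epithet."""
    lex = lexicon if lexicon is not None else default_lexicon()
    environment, score, env_flags = pick_environment(stats, isolation_source)
    genus, gender, etym_genus = compose_genus(environment, lex, seed=seed)
    epithet, etym_species, trait, evidence, ep_flags = compose_epithet(
        profile, gender, lex, priority=priority, seed=seed
    )
    return NameProposal(
        genus_name=genus,
        species_epithet=epithet,
        gender=gender,
        etymology_genus=etym_genus,
        etymology_species=etym_species,
        basis_environment=environment,
        basis_habitat_score=score,
        basis_trait=trait,
        basis_evidence=evidence,
        flags=env_flags + ep_flags,
    )
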