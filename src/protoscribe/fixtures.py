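"""Synthetic inputs with known ground truth.

Every generator is deterministic under its seed and returns the truth
needed to test the downstream estimator (edit logs, conserved-protein
counts, Bernoulli prevalences).  Substreams are derived from a named root
seed so adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ENVIRONMENTS
from .seqio import ReferenceEntry, SequenceRecord, write_fasta

_BASES = np.array(list("ACGT"))
_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class FixtureError(ValueError):
    pass


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generators per component under one seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def make_genome(
    length: int, gc_fraction: float, seed: int, stream: str = "genome", id: str = "genome"
) -> SequenceRecord:
    """I.i.d. bases with P(G)+P(C) = gc_fraction (split evenly G/C and A/T)."""
    if length < 1:
        raise FixtureError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise FixtureError("gc_fraction must be in [0, 1]")
    rng = _rng(seed, stream)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return SequenceRecord(id=id, seq=seq, kind="nucleotide")


@dataclass
class EditLog:
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)  # pos, old, new
    insertions: list[tuple[int, str]] = field(default_factory=list)          # pos, inserted
    deletions: list[tuple[int, str]] = field(default_factory=list)           # pos, deleted

    def replay(self, original: str) -> str:
        """Reconstruct the mutant from the original (round-trip check)."""
        seq = list(original)
        for pos, old, new in self.substitutions:
            assert seq[pos] == old
            seq[pos] = new
        # indels were recorded against original coordinates, applied right-to-left
        events: list[tuple[int, str, str]] = [
            *(("ins", pos, text) for pos, text in self.insertions),
            *(("del", pos, text) for pos, text in self.deletions),
        ]
        for kind, pos, text in sorted(events, key=lambda e: -e[1]):
            if kind == "ins":
                seq[pos:pos] = list(text)
            else:
                del seq[pos:pos + len(text)]
        return "".join(seq)


def mutate(
    record: SequenceRecord,
    substitution_rate: float,
    indel_rate: float = 0.0,
    seed: int = 42,
    stream: str = "mutate",
) -> tuple[SequenceRecord, EditLog]:
    """Per-site Bernoulli substitutions to a uniformly chosen different base,
    plus geometric-length indels at ``indel_rate`` per site."""
    for rate in (substitution_rate, indel_rate):
        if not 0.0 <= rate <= 1.0:
            raise FixtureError("rates must be in [0, 1]")
    rng = _rng(seed, stream)
    seq = list(record.seq)
    log = EditLog()
    alphabet = "ACGT" if record.kind == "nucleotide" else "".join(_AMINO)
    sub_sites = np.nonzero(rng.random(len(seq)) < substitution_rate)[0]
    for pos in sub_sites:
        old = seq[pos]
        choices = [b for b in alphabet if b != old]
        new = choices[rng.integers(len(choices))]
        seq[pos] = new
        log.substitutions.append((int(pos), old, new))
    if indel_rate > 0.0:
        indel_sites = np.nonzero(rng.random(len(seq)) < indel_rate)[0]
        for pos in indel_sites:
            size = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                text = "".join(rng.choice(list(alphabet), size=size))
                log.insertions.append((int(pos), text))
            else:
                text = record.seq[pos:pos + size]
                if text:
                    log.deletions.append((int(pos), text))
    mutant = log.replay(record.seq)
    return (
        SequenceRecord(id=f"{record.id}_mut", seq=mutant, kind=record.kind),
        log,
    )


def make_chimera(
    a: SequenceRecord, b: SequenceRecord, breakpoint_fraction: float = 0.5
) -> SequenceRecord:
    """Prefix of ``a`` up to the breakpoint joined to the suffix of ``b``."""
    if not a.seq or not b.seq:
        raise FixtureError("chimera parents must be non-empty")
    if not 0.0 < breakpoint_fraction < 1.0:
        raise FixtureError("breakpoint must be inside (0, 1)")
    cut_a = int(round(len(a.seq) * breakpoint_fraction))
    cut_b = int(round(len(b.seq) * breakpoint_fraction))
    return SequenceRecord(
        id=f"chimera_{a.id}_{b.id}",
        seq=a.seq[:cut_a] + b.seq[cut_b:],
        kind="nucleotide",
    )


def make_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AMINO, size=length))


@dataclass
class ProteomePairTruth:
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    expected_c1: int
    expected_c2: int

    @property
    def expected_pocp(self) -> float:
        t1 = self.n_shared + self.n_unique_a
        t2 = self.n_shared + self.n_unique_b
        return 100.0 * (self.expected_c1 + self.expected_c2) / (t1 + t2)


def make_proteome_pair(
    n_shared: int,
    n_unique_a: int,
    n_unique_b: int,
    shared_identity: float = 0.95,
    seed: int = 42,
    protein_length: int = 150,
) -> tuple[list[SequenceRecord], list[SequenceRecord], ProteomePairTruth]:
    """Two proteomes sharing ``n_shared`` near-identical proteins.

    Shared proteins are point-mutated copies at ``shared_identity``; unique
    proteins are independent random sequences (which cannot satisfy the
    conserved-protein criteria).  Truth counts assume every shared protein
    and no unique protein is conserved.
    """
    rng = _rng(seed, "proteome_pair")
    proteome_a: list[SequenceRecord] = []
    proteome_b: list[SequenceRecord] = []
    for i in range(n_shared):
        base = make_protein(protein_length, rng)
        partner = list(base)
        n_subs = int(round((1.0 - shared_identity) * protein_length))
        sites = rng.choice(protein_length, size=n_subs, replace=False)
        for pos in sites:
            choices = [a for a in _AMINO if a != partner[pos]]
            partner[pos] = choices[rng.integers(len(choices))]
        proteome_a.append(SequenceRecord(id=f"shared_a_{i}", seq=base, kind="protein"))
        proteome_b.append(
            SequenceRecord(id=f"shared_b_{i}", seq="".join(partner), kind="protein")
        )
    for i in range(n_unique_a):
        proteome_a.append(
            SequenceRecord(id=f"uniq_a_{i}", seq=make_protein(protein_length, rng), kind="protein")
        )
    for i in range(n_unique_b):
        proteome_b.append(
            SequenceRecord(id=f"uniq_b_{i}", seq=make_protein(protein_length, rng), kind="protein")
        )
    truth = ProteomePairTruth(
        n_shared=n_shared,
        n_unique_a=n_unique_a,
        n_unique_b=n_unique_b,
        expected_c1=n_shared,
        expected_c2=n_shared,
    )
    return proteome_a, proteome_b, truth


# ---------------------------------------------------------------------------
# 16S reference set


_GENERA = (
    "Simulomonas", "Fictivibrio", "Exemplibacter", "Mockispora", "Testicoccus",
    "Placebobacillus",
)


def make_reference_set(
    n_entries: int = 60,
    seed: int = 42,
    s16_length: int = 1500,
    invalid_fraction: float = 0.15,
) -> list[ReferenceEntry]:
    """A synthetic 16S reference family with taxonomy and validity flags.

    Entries are generated by mutating genus-level ancestors (themselves
    mutants of one family ancestor), giving a realistic identity gradient
    to any query drawn from the same family.  A fixed fraction of entries
    is marked as not validly published.
    """
    rng = _rng(seed, "reference_set")
    family_root = make_genome(s16_length, 0.55, seed, stream="ref_root", id="root")
    entries: list[ReferenceEntry] = []
    n_genera = len(_GENERA)
    per_genus = max(1, n_entries // n_genera)
    idx = 0
    while len(entries) < n_entries:
        genus = _GENERA[(idx // per_genus) % n_genera]
        genus_anchor, _ = mutate(
            family_root, 0.08, seed=seed, stream=f"genus_{genus}"
        )
        species_seq, _ = mutate(
            genus_anchor, float(rng.uniform(0.005, 0.03)), seed=seed,
            stream=f"species_{idx}",
        )
        species = f"{genus} species{idx}"
        valid = bool(rng.random() >= invalid_fraction)
        entries.append(
            ReferenceEntry(
                id=f"ref{idx:03d}",
                seq=species_seq.seq,
                species_name=species,
                taxonomy=(
                    "Bacteria", "Simulophyla", "Simulia", "Simulales",
                    "Simulaceae", genus, species,
                ),
                validly_published=valid,
            )
        )
        idx += 1
    return entries


# ---------------------------------------------------------------------------
# OTU hit tables


@dataclass
class EnvSpec:
    environment: str
    n_samples: int
    prevalence: float                # Bernoulli probability of a positive sample
    abundance_mu: float = -6.0       # log-normal location of relative abundance
    abundance_sigma: float = 1.0


def make_otu_table(
    env_specs: list[EnvSpec], seed: int = 42
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-environment Bernoulli positives with log-normal abundances.

    Returns the hit table (all hits qualify: identity/coverage above the
    default thresholds) plus the generating prevalence per environment.
    """
    rows = []
    truth: dict[str, float] = {}
    for spec in env_specs:
        if spec.environment not in ENVIRONMENTS:
            raise FixtureError(f"unknown environment {spec.environment!r}")
        if not 0.0 <= spec.prevalence <= 1.0:
            raise FixtureError("prevalence must be in [0, 1]")
        rng = _rng(seed, f"otu_{spec.environment}")
        truth[spec.environment] = spec.prevalence
        positives = rng.random(spec.n_samples) < spec.prevalence
        for i in np.nonzero(positives)[0]:
            abundance = min(1.0, float(rng.lognormal(spec.abundance_mu, spec.abundance_sigma)))
            rows.append(
                {
                    "sample_id": f"{spec.environment.replace(' ', '_')}_s{i}",
                    "environment": spec.environment,
                    "otu_id": f"OTU_{i}",
                    "identity": float(rng.uniform(97.0, 100.0)),
                    "coverage": float(rng.uniform(80.0, 100.0)),
                    "relative_abundance": abundance,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "environment", "otu_id", "identity", "coverage",
            "relative_abundance",
        ],
    )
    return df, truth


# ---------------------------------------------------------------------------
# bundle writer (CLI `protoscribe fixtures`)


def write_fixture_bundle(out_dir: str | Path, seed: int = 42) -> dict[str, str]:
    """Write a complete, coherent input bundle for an end-to-end run.

    The query is a mutated copy of one reference species (a known-species
    scenario), with genome, proteome pair, annotations, OTU hits, MAG
    distances and quality values; truth values are written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    refs = make_reference_set(seed=seed)
    # the closest reference also gets a type genome and proteome so the
    # genome-based evidence lines are exercised end to end
    refs[0].validly_published = True
    refs[0].type_genome_path = str(out / "reference_genome.fasta")
    refs[0].type_proteome_path = str(out / "reference_proteome.fasta")
    write_fasta([r.record for r in refs], out / "references.fasta")
    with open(out / "references.tsv", "w") as fh:
        fh.write(
            "id\tspecies_name\ttaxonomy\tvalidly_published\t"
            "type_genome_path\ttype_proteome_path\n"
        )
        for r in refs:
            fh.write(
                f"{r.id}\t{r.species_name}\t{';'.join(r.taxonomy)}\t"
                f"{'true' if r.validly_published else 'false'}\t"
                f"{r.type_genome_path or ''}\t{r.type_proteome_path or ''}\n"
            )
    paths["references_fasta"] = str(out / "references.fasta")
    paths["references_tsv"] = str(out / "references.tsv")

    with open(out / "valid_names.txt", "w") as fh:
        for r in refs:
            if r.validly_published:
                fh.write(r.species_name + "\n")
    paths["names"] = str(out / "valid_names.txt")

    query16s, _ = mutate(
        SequenceRecord(id="query_16s", seq=refs[0].seq, kind="nucleotide"),
        0.005, seed=seed, stream="query_16s",
    )
    query16s = SequenceRecord(id="query_16s", seq=query16s.seq, kind="nucleotide")
    write_fasta([query16s], out / "query_16s.fasta")
    paths["s16"] = str(out / "query_16s.fasta")

    genome = make_genome(60_000, 0.489, seed, stream="query_genome", id="query_genome")
    write_fasta([genome], out / "query_genome.fasta")
    paths["genome"] = str(out / "query_genome.fasta")

    ref_genome, _ = mutate(genome, 0.03, seed=seed, stream="ref_genome")
    ref_genome = SequenceRecord(id="ref_genome", seq=ref_genome.seq, kind="nucleotide")
    write_fasta([ref_genome], out / "reference_genome.fasta")
    paths["reference_genome"] = str(out / "reference_genome.fasta")

    proteome_q, proteome_r, _truth = make_proteome_pair(
        40, 20, 20, shared_identity=0.9, seed=seed, protein_length=120
    )
    write_fasta(proteome_q, out / "query_proteome.fasta")
    write_fasta(proteome_r, out / "reference_proteome.fasta")
    paths["proteome"] = str(out / "query_proteome.fasta")
    paths["reference_proteome"] = str(out / "reference_proteome.fasta")

    with open(out / "annotation.tsv", "w") as fh:
        fh.write("locus_tag\tko_id\tec_numbers\tcazy_families\tproduct\tcategory\n")
        pathway_ecs = [
            "2.3.1.8", "2.7.2.1", "2.8.3.8", "2.3.1.30", "2.5.1.47",
            "6.3.1.2", "1.4.1.4", "1.5.1.3",
        ]
        for i, ec in enumerate(pathway_ecs):
            fh.write(f"locus{i:04d}\t\t{ec}\t\tenzyme {ec}\tenzyme\n")
        for i in range(20):
            fam = "GH13" if i % 2 == 0 else "GH5"
            fh.write(f"caz{i:04d}\t\t\t{fam}\tglycoside hydrolase\tenzyme\n")
        for i in range(10):
            fh.write(f"tra{i:04d}\t\t\t\tABC transporter permease\ttransporter\n")
    paths["annotation"] = str(out / "annotation.tsv")

    env_specs = [
        EnvSpec("pig gut", 1000, 0.263, abundance_mu=-6.9),
        EnvSpec("human gut", 1000, 0.074, abundance_mu=-6.2),
        EnvSpec("soil", 1000, 0.002),
    ]
    otu, prevalence_truth = make_otu_table(env_specs, seed=seed)
    otu.to_csv(out / "otu_hits.tsv", sep="\t", index=False)
    paths["otu_hits"] = str(out / "otu_hits.tsv")

    with open(out / "samples_per_env.tsv", "w") as fh:
        fh.write("environment\tn_samples\n")
        for spec in env_specs:
            fh.write(f"{spec.environment}\t{spec.n_samples}\n")
    paths["samples"] = str(out / "samples_per_env.tsv")

    rng = _rng(seed, "mag_distances")
    with open(out / "mag_distances.tsv", "w") as fh:
        fh.write("mag_id\tenvironment\tdistance\n")
        for i in range(12):
            env = "pig gut" if i < 8 else "soil"
            dist = float(rng.uniform(0.01, 0.04)) if i < 8 else float(rng.uniform(0.1, 0.5))
            fh.write(f"MAG_{i:03d}\t{env}\t{dist:.4f}\n")
    paths["mag_dist"] = str(out / "mag_distances.tsv")

    with open(out / "quality.tsv", "w") as fh:
        fh.write("genome_id\tcompleteness\tcontamination\n")
        fh.write("query_genome\t98.5\t1.2\n")
    paths["quality"] = str(out / "quality.tsv")

    with open(out / "truth.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write("query_matches_reference\tref000\n")
        for env, p in prevalence_truth.items():
            fh.write(f"prevalence_{env.replace(' ', '_')}\t{p}\n")
    paths["truth"] = str(out / "truth.tsv")
    return paths
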