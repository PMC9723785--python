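# protoscribe

Desk-scale taxonomic delineation, trait inference and protologue drafting
for bacterial isolates.

Describing a newly cultured bacterium with a validly publishable name
requires demonstrating its taxonomic uniqueness against named relatives and
summarising its physiology and ecology in a *protologue* — the formal text
block of name, etymology and properties required under the ICNP.
`protoscribe` computes the building blocks of that description from two
inputs, the isolate's 16S rRNA gene and its genome assembly, plus optional
annotation and survey tables, and assembles a draft overview.  It targets
microbiologists who have an isolate (or a MAG linked to a 16S sequence) and
want every delineation number, trait call and habitat statistic from one
reproducible run.

## What it computes

**Taxonomic evidence.**  The query 16S gene is aligned against a reference
set of type-strain sequences; the 50 highest-scoring relatives (≥60 %
identity, ≥80 % query coverage) are ranked, relatives without validly
published names are set aside, and four evidence lines are evaluated
against the best candidates:

* 16S rRNA identity with the conventional boundaries — >98.7 % same
  species, >94.5 % same genus, >86.5 % same family;
* average nucleotide identity (ANI), fragment-based: the genome is cut into
  1,020-nt fragments, each mapped to its best location in the other genome,
  and ANI is the reciprocal mean identity of mapped fragments; >95 % means
  the same species;
* percentage of conserved proteins, POCP = 100·(C1+C2)/(T1+T2) over
  reciprocal proteome searches (a hit conserved at >40 % identity over
  >50 % of the query length); <50 % separates genera;
* G+C content of genomic DNA, advisory: conspecific genomes rarely differ
  by more than 1 percentage point.

A consensus novelty call (known species / novel species / novel genus /
novel family-or-higher) is emitted with every per-line verdict and every
disagreement listed — the consensus is a starting point for an educated
reading of all parameters, not a verdict to be consumed blindly.

**Quality gates.**  16S completeness against the closest reference (<80 %
warns), a two-parent midpoint chimera screen, and genome completeness /
contamination gating (<95 % complete or >3 % contaminated warns; values are
consumed from a marker-gene tool's output, not estimated).

**Traits.**  A 30-feature ruleset evaluated on a KO/EC annotation table:
EC-defined pathways (acetate, propionate, butyrate, cysteine/acetate from
sulfide+serine, glutamate from ammonia, folate, riboflavin, cobalamin),
gene-list features (flagella, sporulation), CAZyme counts and
CAZy-family→substrate calls.

**Ecology.**  From an OTU hit table over amplicon surveys (19 environment
labels), per-environment prevalence and mean relative abundance in positive
samples; their product is the *habitat score* that selects the naming
environment.  Genome matches against a MAG sketch collection are filtered
at Mash distance <0.05, with d = −(1/k)·ln(2j/(1+j)).

**Nomenclature.**  A candidate binomial assembled from a curated lexicon:
an environment-keyed genus prefix plus a gendered stem, and a species
epithet from the highest-priority present trait, with the epithet suffix
agreeing with the genus gender (-us/-a/-um).

## Worked example

Generate a fully synthetic input bundle and run the whole workflow:

```
protoscribe fixtures --seed 7 -o bundle
protoscribe run \
  --s16 bundle/query_16s.fasta --genome bundle/query_genome.fasta \
  --refs bundle/references.fasta --ref-meta bundle/references.tsv \
  --names bundle/valid_names.txt --annotation bundle/annotation.tsv \
  --proteome bundle/query_proteome.fasta --otu-hits bundle/otu_hits.tsv \
  --samples bundle/samples_per_env.tsv --mag-dist bundle/mag_distances.tsv \
  --quality bundle/quality.tsv --seed 7 -o out
```

The bundle's query is a near-identical relative of reference `ref000`
whose type genome was mutated at 3 %; `out/report.txt` therefore reads, in
part:

```
16S verdict: same_species
ANI verdict: same_species
POCP verdict: same_genus_new_species
Consensus: known_species
...
pig gut: prevalence 26.9% (269/1000 samples), mean relative abundance in
positive samples 0.17%, habitat score 4.5
...
The G+C content of genomic DNA is 49.4%.
```

The 16S identity of 99.5 % (>98.7) and ANI of 97.0 % (>95) both place the
query inside `ref000`'s species; the pig-gut habitat score (prevalence ×
mean relative abundance, 26.9 × 0.17 ≈ 4.5) dominates, so the proposed
genus name takes a pig-gut prefix (here *Suilimicola*, feminine) and the
butyrate pathway present in the annotation names the epithet *butyrica*,
agreeing in gender.  `out/report.json` is the machine-readable twin of the
same report.

Subcommands `metrics` (pairwise metrics only), `name` (nomenclature only)
and `congruence` (cross-method genus-call stratification) expose the
individual stages.

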