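# Methods

This note documents the models, algorithms and numerical choices behind
`protoscribe`, the assumptions they make, and what the synthetic-data tests
do and do not demonstrate about real data.

## Scope and philosophy

The package computes every quantity a genome-based species description
needs at desk scale: no external aligners, search engines or sketching
binaries are shelled out to.  Where a production pipeline would use a
dedicated tool (a k-mer ANI engine, BLASTP, a MinHash sketcher, a chimera
caller, a maximum-likelihood tree builder), `protoscribe` ships a compact
built-in algorithm with the same contract — the value and its decision
threshold — and an adapter interface so the external tool can be plugged
in.  Upstream annotation (gene calling, KO assignment, CheckM-style
completeness estimation, GTDB-style placement) is consumed as *input*,
never recomputed: those are resources, not the method.

## Sequence comparison

**Pairwise 16S identity** uses global alignment with free terminal gaps
(Biopython `PairwiseAligner`; match +2, mismatch −3, gap open −5, extend
−2, end gaps free).  Identity = matches / aligned columns, where internal
gaps count as columns and terminal gaps are excluded; this convention is
conservative for partial sequences, which matters because incomplete 16S
genes are common in MAG-linked data.  Query coverage is the fraction of the
query spanned by the non-terminal-gap region; it feeds the ≥60 % identity /
≥80 % coverage candidate filter.  The built-in aligner has no e-value
model, so the e-value criterion used by search-engine-backed candidate
filtering applies only when an external search adapter supplies one.

**16S completeness** is the aligned query span on the closest reference
divided by the reference length, capped at 100 %.  A query longer than its
reference that aligns fully scores 100.

**Chimera screen.**  The query is split at its midpoint; the best-identity
reference is found for each half and for the full sequence.  A chimera is
flagged when the halves' best references differ *and* each half beats the
full-length best identity by at least `delta` points (default 2.0).  This
two-parent midpoint screen is deliberately simple: it catches the
textbook chimera (two divergent parents joined near the middle) and never
flags a sequence drawn unmodified from the reference set, but it is blind
to multi-parent chimeras and breakpoints far from the centre.  `delta` is a
free parameter of this screen, not a published constant; an adapter
contract accepts an external chimera caller where sensitivity matters.

**G+C percent** counts G+C over unambiguous bases only; N is excluded from
numerator and denominator.  It is invariant under reverse complement.

## Genome-scale metrics

**Fragment ANI.**  The query genome is cut into non-overlapping 1,020-nt
fragments; each fragment is aligned to its best infix location in the
target (both strands) with edlib's bit-vector alignment.  A fragment maps
when its best placement reaches 70 % identity — because infix alignment
consumes the whole fragment, this satisfies the "covers ≥70 % at ≥70 %
identity" mapping floor in one criterion and rejects random placements
(two unrelated random genomes give best-infix identities near 55 %,
comfortably below the floor).  ANI is the mean identity of mapped
fragments, averaged over both directions, and undefined when fewer than 5
fragments map in either direction.  Parameter-recovery tests confirm that
genomes mutated at rate m return ANI = 100(1−m) within 0.5 points for
m ∈ {0.01, 0.03, 0.05}.

**POCP** follows the conserved-protein definition: a protein is conserved
when its best hit in the other proteome has >40 % identity over >50 % of
the query protein length; POCP = 100·(C1+C2)/(T1+T2), symmetric by
construction.  The built-in search is local alignment under BLOSUM62
(gap open −11, extend −1), best hit by score; it applies the identity and
alignable-region criteria only, because a raw aligner has no e-value
model.  The external-search adapter applies all three criteria when the
backend reports e-values.  The alignable-region denominator is the query
protein of each directional search.

**MinHash sketching.**  Canonical k-mers (lexicographic minimum of forward
and reverse complement), 2-bit packed and mixed with a splitmix64 64-bit
finaliser; the sketch keeps the bottom-s hashes (defaults k=21, s=1000).
The Jaccard index is estimated from the bottom-s of the merged hash sets
and converted to distance d = −(1/k)·ln(2j/(1+j)), with d=1 by convention
at j=0.  The closed form is verified to 1e-12 in tests.

**Neighbour joining** is implemented directly so that its clamping rule is
explicit: a negative branch length is set to zero and the deficit moved to
the sister branch, preserving the pair sum.  The final three nodes are
joined at a trifurcating root via the three-point formulas, so additive
matrices are reproduced exactly (verified against closed-form solutions at
3 taxa, generating topologies at 4–8 taxa, and an independent NJ
implementation on noisy matrices).  Trees are built on d = 1 − identity/100
for 16S and on ANI-derived distances for genomes.

## Decision engine

Thresholds (all overridable in a key=value config file): 16S 98.7 / 94.5 /
86.5 % for species/genus/family; ANI >95 % for species; POCP <50 % strictly
for genus separation (so ≥50 ⇒ same genus); G+C within 1 point consistent
with conspecificity.  The inequality directions follow the published
phrasing of each boundary.  Quality gates are strict as printed: <80 % 16S
completeness, <95 % genome completeness, >3 % contamination.

Consensus precedence: ANI overrides 16S at species rank; POCP (with any
supplied external placement label as co-arbiter) decides genus rank; 16S
alone decides family rank.  G+C never flips a consensus — it is advisory
evidence.  Every disagreement between evaluable lines is reported in a
conflicts list, because single-method placement is exactly what a
multi-evidence tool exists to prevent; when the lines genuinely contradict
each other (e.g. 16S says new genus while POCP says same genus), the
engine reports the conflict rather than pretending the precedence rule is
authoritative.

The congruence summariser stratifies per-pair genus calls across methods
into congruent-same, congruent-different, per-method unique-different, and
mixed; counts are validated against brute-force recounts.

## Traits

Rules come in three kinds.  *Pathway* rules hold EC patterns (a trailing
`-` field is a wildcard, so `1.4.1.-` matches any fourth field) and are
present when every pattern is matched by at least one annotated EC, with
alternative EC sets allowed (the propionate rule accepts either the
acetyltransferase or the 2.3.1.222 variant route).  *Gene-list* rules
(flagella n=25, sporulation n=52) are present when at least `min_fraction`
(default 0.5) of the listed genes are annotated; the 0.5 default is this
package's choice — list sizes are conventional but no published call
threshold exists, so the fraction is configuration, as are the gene
identities themselves.  *Stub* rules name the remaining assessed features
(the ten carbon sources, urease, siroheme, EPS, cytochrome c oxidase,
nitrification, sulfate assimilatory reduction, vitamins K1/K2/B7, ammonia
production) whose defining content is genome-database specific; they
evaluate to `not_evaluable` until the user supplies content, which keeps
the 30-feature vocabulary honest about what is and is not encoded.
Evaluation is monotone: adding annotation rows can never flip a present
call to absent.  CAZyme counts are rows with ≥1 CAZy family; the
family→substrate map is a shipped, editable table of textbook associations
(GH13→starch and the like), explicitly illustrative.  KO-only annotations
are translated through an optional KO→EC table before rule evaluation.

## Ecology

OTU hits qualify at ≥97 % identity and ≥80 % coverage (inclusive: the
printed figures carry no strict inequality, so the boundary value counts).
A sample's relative abundance is the *sum* over its qualifying OTU rows —
max would under-count strains split across OTUs — making occurrence
invariant to row order and row splitting.  Prevalence = positive/total
samples per environment; the habitat score is prevalence × mean relative
abundance in positive samples, and it (with prevalence, then label order,
as tie-breaks) selects the naming environment.  MAG matches are strict at
distance <0.05, matching the printed upper bound.

## Nomenclature

The lexicon is a flat text table of genus prefixes keyed by environment
(each with its component etymology), gendered genus stems (-monas fem,
-cola fem, -vivens fem, -microbium neut, -adaptatus masc), and epithet
roots with explicit masc/fem/neut triples (butyricus/-a/-um,
ammoniilyticus/-a/-um, amylophilus/-a/-um, …; *aceti* is a genitive noun
and gender-invariant).  Host-gut environments carry multiple prefixes in
established etymological style; prefixes for the non-gut environments are
package-authored combining forms intended for curation.  Prefix and stem
are chosen by a seeded RNG among the environment's entries; the epithet is
the highest-priority present trait with a lexicon root (default order:
butyrate > propionate > acetate > starch > cellulose > ammonia
utilisation — a package choice, configurable, since no canonical ordering
exists), with CAZy substrate calls standing in for the stub carbon-source
rules.  No Latin morphology is inflected algorithmically; correctness is
bought with explicit triples.  Generation is a pure function of its inputs
and seed, and gender agreement is enforced by table lookup.

## Synthetic data

The generator suite produces i.i.d. genomes at a requested G+C fraction,
point/indel mutants with a complete edit log (replaying the log
reconstructs the mutant exactly), midpoint chimeras, proteome pairs with a
known shared fraction at a known identity, 16S reference families with a
two-level (genus/species) divergence structure and name-validity flags,
and Bernoulli/log-normal OTU hit tables.  Each generator draws from a
named substream of the root seed, so adding a generator never perturbs
existing fixtures.  Default study conditions: 1,000 samples per
environment for occurrence scenarios, with pig-gut prevalence 0.263 and
log-normal abundances centred near 0.1 % in positives as the canonical
pig-gut-dominant case; 16S references of 1,500 nt; genome fixtures of
50–100 kb (large enough for ~50–100 ANI fragments per direction, small
enough for seconds-scale runs).

What the fixtures do *not* emulate: real rRNA secondary structure and
conserved/variable region layout, gene content and codon bias, correlated
mutation processes, compositional bias between lineages, or OTU
cross-mapping noise.  Passing parameter-recovery tests therefore shows the
estimators are correct on their own model assumptions (i.i.d.
substitution, Bernoulli occurrence), not that real 16S genes at 98.7 %
identity are conspecific — that calibration is inherited from the
published thresholds, not re-derived here.

## Numerical choices and degenerate inputs

Percentages are reported to one decimal in rendered text, with a
machine-readable twin carrying every number.  Ambiguity codes beyond N/X
are squashed to N/X with a logged warning rather than rejected.  Ties in
candidate ranking break by reference id, in environment choice by
prevalence then label order, in chimera parent choice by reference id —
all deterministic.  Empty sequences, empty proteomes, all-ambiguous
genomes, asymmetric distance matrices and unknown environment labels raise
typed errors; boundary threshold values follow each printed inequality's
direction exactly.  ANI is reported as undefined (never 0) when too few
fragments map; an environment with no positive samples reports prevalence
0 and mean 0 by convention.

## Known limitations

The chimera screen's sensitivity is limited by its midpoint split.  The
built-in POCP search omits the e-value criterion (documented above), which
can slightly over-count conserved proteins for short, low-complexity
sequences relative to a search engine with composition-based statistics.
Fragment ANI on highly repetitive genomes can map fragments to paralogous
copies, biasing identity upward; the reciprocal average mitigates but does
not remove this.  dDDH is deliberately not computed.  The consensus
precedence is one defensible codification among several; the per-line
verdicts and conflict list are the primary output for borderline cases
(POCP values in the 45–55 % band in particular warrant manual review).
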