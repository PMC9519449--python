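# Methods

This note documents the models, thresholds and numerical choices behind
seqcode-tools, and what the synthetic generators do and do not emulate.

## Assembly statistics

An assembly is an ordered list of uniquely named contigs over the IUPAC
nucleotide alphabet; soft-masked (lowercase) bases are treated as their
uppercase equivalents and `U` is normalized to `T` on read. Statistics:

* **N50/L50.** N50 is the smallest contig length *L* such that contigs of
  length ≥ *L* jointly cover at least half of the total length; L50 is the
  number of those contigs. Implemented as a descending sort and cumulative
  scan with the half-total threshold taken as ⌈total/2⌉, which resolves
  ties to the larger qualifying contig length. The published thresholds
  (N50 > 25 kb) name no estimator; this is the convention used by the common
  assembly-statistics tools.
* **G+C content.** 100·(G+C)/(A+C+G+T): ambiguous IUPAC codes (N, R, Y, …)
  are excluded from the denominator and counted separately, so assembly
  gaps do not bias GC. The unrounded value is kept internally; display and
  protologue use the nearest-integer percentage, matching how such values
  are reported in taxon descriptions.

## Quality control

Threshold strictness follows the printed inequalities verbatim: MAG/SAG
completeness **> 90 %** and contamination **< 5 %** (both strict — a genome
at exactly 90 % fails), isolate coverage **≥ 10×**, 16S completeness
**> 75 %**, tRNAs **> 80 %** of 20 types (so ≥ 17; 16/20 is exactly 80 %
and fails), contigs **< 100**, N50 **> 25 kb**, largest contig **> 100 kb**,
MAG/SAG coverage **≥ 10×**. Completeness/contamination are consumed as
inputs (CheckM or similar; the estimator name is recorded as free text) and
never recomputed. The raw-read deposition requirement is waived — the check
reports *not applicable* — when the effective publication date precedes
2023-01-01 (exclusive, date-only comparison), accommodating names already
published or in review when sequence-based registration began.

Absent metrics are handled by tier. A missing *required* metric fails with
a "metric absent" note, never passes silently. For *recommended* checks,
missing numeric metrics (tRNA count, coverage) yield *not evaluated*;
missing boolean confirmations (chimaera check, taxonomy concordance) warn,
because an unverified recommendation is actionable for the submitter. A
genome with no 16S data at all gets a single combined *not evaluated* entry
rather than separate completeness and chimaera warnings. Eligibility as a
nomenclatural type is the conjunction of the applicable required checks;
recommended failures are warnings only and a free-text note slot records
author-justified exceptions.

## Nomenclature

Parsing normalizes whitespace, strips italic/quote markup and a leading
*Candidatus*/*Ca.* designation (recorded on the name; stripping is run to a
fixed point so it is idempotent), and enforces part counts (species 2,
subspecies 3 with an optional `subsp.` connector, one part otherwise).
Orthography errors: characters outside ASCII Latin letters (internal
hyphens permitted only in epithets), uncapitalized genus part, non-lowercase
epithets, parts shorter than two letters. Rank suffixes: family *-aceae*,
order *-ales*, class *-ia*, phylum *-ota* are required at their ranks; a
genus ending in a reserved suffix draws only a warning, since genus names
carry no standard suffix but should avoid those of other ranks. The suffix
set is a module constant and deliberately configurable.

Latin grammar, gender agreement and declension are **not** validated — that
requires a lexicon and remains a curator's task; etymology is stored
verbatim. Homonym detection uses a casefolded, markup-free key; two names
collide iff keys are equal. Near-miss spellings are reported advisorily via
Damerau–Levenshtein distance ≤ 2 (optimal string alignment variant,
hand-implemented since the advisory check needs transpositions) and are
never auto-merged: minor orthographic variants are a curatorial decision.

## Registry

The state machine admits exactly draft → provisionally_accepted → valid and
draft/provisionally_accepted → rejected; valid and rejected are terminal.
`register_draft` enforces every automated precondition (error-free name,
rank-appropriate type designation — genome assembly for species and
subspecies, a species for a genus, a genus for higher ranks, the last by
analogy with the culture-based code's convention —, an eligible QC report
for species/subspecies, and no homonym collision with a non-rejected entry
or an external ICNP name) and promotes immediately to provisionally
accepted. Rejected entries keep their records as an audit trail but free
their homonym key.

Priority is date-only (the system records no finer granularity): ascending
priority date, and on a tie the entry validated here sorts before an
external ICNP name, then ascending label — so an ICNP name participates
with its own date but can never displace an equal-or-earlier entry. Ties
within one source are a curator-review situation; the deterministic label
order merely stabilizes output.

DOIs are validated syntactically only (`10.<prefix>/<suffix>`), keeping the
package fully offline. The superscript type-species marker is rendered as
ASCII `^Ts` in plain text. Protologues are built from ordered blocks (name +
etymology; optional description; type-designation sentence); the wording
templates are this package's own, fixed by golden-file tests.

Registry JSON is schema-versioned (`1.0`) with ISO-8601 dates; import
validates field-by-field and reports every offending field at once. The
schema checks are hand-rolled rather than delegated to a JSON-Schema
engine: the document is small, and explicit checks give precise error
paths.

## ANI estimation and dereplication

The built-in estimator is Mash-style MinHash: canonical 2-bit-packed k-mers
(k = 21 by default; windows containing ambiguous bases are dropped), hashed
with a fixed splitmix64 finalizer (so sketches are deterministic without a
seed parameter), bottom sketch of the 5,000 smallest distinct hashes.
Jaccard similarity *j* is estimated on the bottom sketch of the union of
two sketches; the distance is d = −ln(2j/(1+j))/k and ANI = 100·(1−d),
clamped to [0, 100]. When sketches share nothing the estimate is *absent*
rather than 0 — unrelated genomes have no meaningful ANI. A genome against
itself gives exactly 100 for any inputs. Under the substitution-only
mutation model the estimator recovers 100·(1−rate) to within a few tenths
of a point at rates ≤ 0.05 with these defaults; a small negative bias of
order 100·r²/2 (from d = −ln(1−r) ≈ r + r²/2) is inherent to the distance
formula and well inside the ±0.5-point recovery tolerance used in the
tests. External ANI tables (first three FastANI output columns, header
optional) are consumed verbatim with asymmetric pairs averaged and
self-pairs forced to 100.

Species clusters are the connected components of the graph with edges
where ANI **strictly exceeds** the threshold (default 95 %). Single linkage
was chosen because reported practice is simple > 95 % clusters with
monophyly checked externally; the threshold is a parameter, and raising it
can only split clusters, never merge them. Representatives maximize
completeness − 5 × contamination (the standard dereplication score), ties
broken by ascending id for determinism.

## Synthetic generators

`generate_assembly` draws bases i.i.d. with P(G) = P(C) = gc/200 and contig
lengths from a lognormal law (default mean 10.5, sigma 0.8 in log-bases,
i.e. a median contig of ~36 kb, floored at 100 bp) or an explicit list; at
≥ 100 kb total the realized GC is within ±1 percentage point of target
(binomial standard error ≈ 0.16 points at 100 kb). `mutate_genome` applies
independent per-site substitutions, always to a different base, so the
expected identity is exactly 1 − rate; there are no indels, no rate
heterogeneity and no repeat structure. `type_genome_standin` reconstructs
the worked type genome's dimensions (27 contigs, 1,277,965 bp, 52 % GC)
for offline testing; it shares nothing with the real assembly beyond those
statistics. Registry fixtures plant a homonym pair, a *Candidatus* intake
set and a distinct-date priority ordering, and emit the answer key
alongside. Fixture names are built from Latinate syllables; they exercise
orthography checks but carry no taxonomic meaning.

Consequently, passing tests demonstrate correctness of the statistics,
thresholds, state machine and estimators on idealized inputs; they do not
validate behaviour on real assemblies with repeats, indel divergence,
skewed k-mer spectra or binning artefacts, nor the quality of upstream
completeness/contamination estimates, which this package treats as given.

## Problem sizes

The test suite and the acceptance script use deliberately modest sizes —
500 kb genomes for ANI recovery, a 22-genome/11-species panel (sketch
2,000) for clustering, 10,000 random metric vectors for the QC truth table,
1,000 replayed event logs and 100-entry registries — chosen so the whole
battery runs in well under a minute on one CPU while keeping every
estimator inside its documented tolerance.

## Known limitations

* No Latin lexicon: grammatical agreement and etymology quality are not
  machine-checked.
* The MinHash estimator is an approximation; alignment-based ANI (FastANI,
  skani) should be preferred for borderline species decisions and can be
  supplied via the ANI-table route.
* INSDC deposition is taken from the metadata flags; no live accession
  lookups are performed.
* The registry is a local, single-writer store: no authentication, curator
  messaging or web service.
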