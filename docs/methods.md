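# Methods

## Procedure

`enzpam` standardizes enzyme annotations across prokaryotic genomes in
five file-to-file steps (harvest → dbbuild → [annotate] → reference →
match → matrix). The central assumption is that the annotator (Prokka or
a compatible drop-in) copies the custom database's EC/gene/product fields
verbatim into its output, so the product string of an annotated CDS is a
faithful carrier of the database synonym that won the similarity search.
Everything downstream of the annotator is therefore *lexical*: a genome
"has" an enzyme iff at least one of its CDS products matches one of the
enzyme's compiled synonyms and survives curation. No copy-number
semantics are attached — counts are preserved in the provenance sidecar
for users who want abundance.

## Name normalization

All equality and containment tests operate on `normalize_name(text)`:
case-folded, whitespace runs collapsed, `(EC x.x.x.x)` decorations
removed anywhere, and trailing bracketed qualifiers (`[NADH]`,
`(fragment)`) stripped *to a fixpoint* — the fixpoint loop is what makes
the function idempotent, which in turn makes matching insensitive to how
often a string has passed through the pipeline. Interior punctuation is
preserved because it is semantically load-bearing in enzyme nomenclature
("catechol 1,2-dioxygenase" vs "catechol 2,3-dioxygenase").

A consequence worth stating explicitly: `(EC …)` decorations are
invisible to *exact* matching, not only to substring matching, because
normalization removes them. The fixture jitter log classifies transforms
accordingly (case, whitespace and EC-decoration are
"normalization-safe"; `putative`-wrapping is not).

## Matching modes

* **exact** (default): `normalize_name(product)` equals a reference
  synonym. Conservative; misses products wrapped in qualifiers the
  normalizer does not strip.
* **substring**: a synonym occurs inside the normalized product with word
  boundaries on both ends (`(?<!\w) … (?!\w)`). The anchoring stops
  "oxygenase" from firing inside "dioxygenase"; without it a synonym grep
  over annotation output is wildly over-permissive. Every exact positive
  is by construction also a substring positive.

Synonyms claimed by more than one enzyme are kept for *all* claimants,
flagged ambiguous in the match output and listed in the reference file's
collision section; silently assigning them to one enzyme would bias the
matrix, and the curation list is the sanctioned resolution path. A
curated line excludes a match when it equals either the matched synonym
or the whole normalized product.

## Synonym harvesting

KO identifiers are queried first, then EC numbers (most-specific first);
results are unioned and deduplicated on `(enzyme_id, norm_name)` with the
first retrieval winning, and the standard name itself is always a synonym
of its own enzyme (the "self-synonym floor" — an enzyme can never vanish
from the reference just because the source missed it). Wildcard ECs
(`1.14.12.-`) match any record agreeing on all specified components.
Whether KO- and EC-derived sets should be unioned or prioritized is not
settled by any authority; union was chosen as the non-lossy option and
the provenance column (`retrieved_via`) keeps the distinction auditable.

Record sources are pluggable: a snapshot directory of flat-file stanzas
(`ENTRY`/`NAME`/`EC` lines, names `;`-separated) plus a `proteins.fasta`
for sequence lookup, or a REST endpoint that writes every response into a
snapshot-shaped cache before use, so any second run is fully offline. The
test suite touches only snapshot sources.

## Custom database

Headers follow the `<seq_id> <EC>~~~<gene>~~~<product>` convention
because that is what Prokka's `--proteins` option parses — external-tool
interoperability is the entire point of the database step. Sequences are
wrapped at 60 columns; `~~~` is forbidden inside any field; per-synonym
sequence retrieval is capped (`max_seqs_per_synonym`, default 5, taken in
snapshot order) to keep databases from ballooning on generic names.
Retrieved sequences keep their source accession (suffixed on reuse); the
per-pathway FASTAs are a reporting convenience, the merged FASTA is what
the annotator consumes.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `match_mode` | `exact` | lexical matching rule (see above) |
| `max_seqs_per_synonym` | 5 | sequences attached per synonym, snapshot order |
| `spec_dialect` | `tsv` | spec-table format (`csv` supports quoted names) |
| multi-value delimiter | `;` | splits EC/KO cells and joins them on output |
| `rate_limit` | 3 req/s | REST source throttle |
| `annotation_format` | `auto` | prefer the feature table, fall back to GFF3 |

Enzyme identifiers are derived (`slug(pathway)__slug(standard_name)`)
rather than user-supplied so matrix rows stay stable across runs and
edits.

## The synthetic-data generator

Fixture bundles emulate the target situation — a handful of draft genomes
(MAG-like) screened for a few degradation pathways — at a default scale
of 3 pathways × 5 enzymes × 4 synonyms over 6 genomes, plant probability
0.5, 20 decoy CDS per genome. Design choices:

* **Compositional synonym grammar.** Each enzyme gets a unique invented
  substrate word (syllable product, e.g. "benzoraate") crossed with a real
  enzyme-class vocabulary ("1,2-dioxygenase", "hydroxylase", …). Decoy
  products draw on a disjoint vocabulary (ribosomal proteins,
  transporters, …), so the guarantee that no decoy contains a synonym
  word-bounded is structural; a brute-force scan re-checks it before any
  bundle is emitted. The class vocabulary was screened so that no class
  name contains another as a word-bounded substring.
* **Jitter log.** Product-name noise (random case, padded whitespace,
  appended `(EC …)`, `putative`-prefix) is applied per planted CDS with
  probability 0.5 per enabled transform, and every application is logged.
  Expected matrix outcomes under each match mode are therefore *computed*
  from the log, making the noise tests exact instead of statistical.
* **Annotator output only.** Bundles contain Prokka-style TSV and GFF3
  generated from the same internal records (so the two parsers can be
  cross-checked), never genome sequences: gene calling and similarity
  search belong to the external annotator, upstream of everything this
  package computes.

What passing fixture tests does *not* show: robustness to real KEGG
record quirks beyond the flat-file grammar modelled here, to annotator
products that paraphrase rather than copy database entries, or to
biological false positives (a sequence annotated with a name whose
function it does not have). Those are exactly the failure modes the
manual-curation loop exists for.

## Numerical and procedural choices

* Determinism everywhere: snapshot files are read in sorted order,
  matches and matrix rows follow spec/input order, all fixture
  randomness flows from one `random.Random(seed)`; identical inputs give
  byte-identical outputs (asserted in tests).
* Degenerate inputs: an empty spec table is valid (empty matrix); an
  empty synonym set cannot occur (self-synonym floor); overlap fractions
  with a zero denominator are reported as not-applicable (`None`/null),
  never 0 or NaN.
* Matrix comparison reports **both** normalizations
  (`frac_of_b_reproduced = n_shared / n_pos_b`,
  `frac_only_a = n_only_a / n_pos_a`) because pre/post-curation overlap
  can be normalized either way and neither direction is privileged;
  the conservation identities `n_shared + n_only_a = n_pos_a` and
  `n_shared + n_only_b = n_pos_b` are property-tested against brute-force
  set arithmetic.
* The acceptance study sizes (50 noise-free bundles, 20 noisy bundles,
  100 curation extensions, 1000 random matrix pairs) were chosen to give
  dense coverage of the seeded configuration space while keeping a full
  run in seconds.

## Known limitations

* Lexical matching inherits the annotator's vocabulary: a genuinely
  present enzyme annotated under a name outside the synonym set is a
  false negative until the user adds the synonym (manual-synonyms TSV).
* EC "validation" is syntactic only; existence against a live authority
  is deliberately out of scope.
* The REST source models a KEGG-like `get/<id>` API shape; exotic
  endpoints need a thin adapter or a pre-built snapshot.
* No pathway-completeness scoring, KO-module logic or phylogenetic
  profiling: the output is presence/absence with provenance, intended as
  input to such downstream analyses.
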