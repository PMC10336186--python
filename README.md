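# enzpam

**Custom enzyme-annotation databases and standardized presence–absence
matrices for prokaryotic genomes.**

## The problem

Functional annotation of prokaryotic genomes and metagenome-assembled
genomes (MAGs) is plagued by nomenclature drift: the same enzyme appears in
public repositories under many free-text product names ("catechol
1,2-dioxygenase", "catA", "pyrocatechase", …). When you want to ask a
simple comparative question — *which of my genomes encode which enzymes of
the pathways I care about?* — you first have to reconcile all of those
synonyms against a single standard name per enzyme.

`enzpam` automates that reconciliation as a transparent, file-to-file
workflow. Starting from a user table of standard enzyme names with their
EC numbers, KEGG Orthology (KO) identifiers and pathway labels, it:

1. **harvests synonyms** for every enzyme from a KEGG-style record source
   (an offline snapshot directory, or a cache-first REST endpoint);
2. **builds a custom protein database** — a FASTA whose headers carry
   `EC~~~gene~~~product` descriptions, the convention a Prokka-compatible
   annotator accepts as its priority reference (`--proteins`);
3. **cross-references** every synonym back to its standard name and
   identifiers in a per-pathway reference TSV;
4. **matches** the annotator's per-genome output (Prokka-style TSV or
   GFF3) against the synonyms — exact normalized equality, or word-bounded
   substring containment — honouring a user-maintained curation list of
   product names that must *not* count;
5. **emits the presence–absence matrix**: one row per enzyme (grouped by
   pathway), one 0/1 column per genome, with the supporting locus tags
   recorded per positive cell.

For a pair of matrices (say, before and after a round of manual curation)
`compare_matrices` partitions the positive cells into shared / only-A /
only-B and reports both overlap fractions.

The matching core is deliberately *lexical*. The sequence-similarity
search already happened inside the annotator; what remains is the
standardization problem, and for that the unit of evidence is the product
string. Presence means: at least one annotated CDS in that genome whose
product matched one of the enzyme's synonyms and was not curated out.

Gene calling, similarity search and the annotator itself are out of scope:
`enzpam` writes the annotator's input database and parses its output, and
can optionally shell out to an installed annotator through a command
template.

## Worked example

Real runs need a KEGG snapshot and annotator outputs; the built-in fixture
generator produces a fully synthetic, seeded stand-in with a planted truth
matrix, which is also how the test suite validates the pipeline:

```bash
enzpam fixtures --out bundle --seed 42 --noise
```

Write a config and run every step:

```yaml
# config.yaml (unlisted keys take their defaults)
workdir: run
spec_table: bundle/enzymes.tsv
source_kind: snapshot
source_location: bundle/snapshot
annotations_dir: bundle/genomes
match_mode: substring
```

```bash
enzpam run --config config.yaml
```

Each step prints the interchange files it wrote (`run/synonyms.tsv`,
`run/custom_db.faa`, `run/reference.tsv`, `run/matches.tsv`,
`run/matrix.tsv`, …). The matrix starts:

```
pathway	enzyme_id	standard_name	genome01	genome02	genome03	genome04	genome05	genome06
pathway-01 degradation	pathway-01-degradation__benzoraate-1-2-dioxygenase	benzoraate 1,2-dioxygenase	0	1	1	1	0	1
pathway-01 degradation	pathway-01-degradation__benzoraol-1-2-dioxygenase	benzoraol 1,2-dioxygenase	0	0	0	0	0	1
```

— row `benzoraate 1,2-dioxygenase`, column `genome02` reads 1: that genome
contains at least one CDS whose product matched one of the enzyme's
synonyms (the locus tags are in `run/matrix_provenance.tsv`). Comparing
against the planted truth:

```bash
enzpam compare run/matrix.tsv bundle/truth_matrix.tsv
```

```json
{
  "frac_of_b_reproduced": 1.0,
  "frac_only_a": 0.0,
  "n_only_a": 0,
  "n_only_b": 0,
  "n_pos_a": 46,
  "n_pos_b": 46,
  "n_shared": 46
}
```

All 46 planted positives were recovered and no spurious cell appeared:
`frac_of_b_reproduced` is the fraction of B's positives that A shares
(here 1.0), `frac_only_a` the fraction of A's positives absent from B.
This bundle was generated with all product-name jitters enabled; substring
matching sees through every one of them, while `match_mode: exact` would
recover only the cells whose jitter normalization undoes (case,
whitespace, `(EC …)` decorations) and miss the `putative`-wrapped ones.

Because every step reads and writes only plain files, the curation loop is
just: edit `curation.txt` (one unwanted product name per line) or the
manual-synonyms TSV, then re-run `enzpam match` and `enzpam matrix`.

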