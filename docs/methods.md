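# Methods

This note documents the models and procedures `prokann` implements, the
defaults it ships, the design choices that were genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Coordinate model

All coordinates are 1-based and inclusive at both ends, the native
convention of GFF3 and of NCBI feature tables (TBL). Converters own
every off-by-one adjustment: the TBL reader/writer handles that
format's minus-strand coordinate reversal (a minus-strand feature is
written `end TAB start` on disk and normalised to `start ≤ end` with
strand `-` in memory), and nothing downstream ever shifts a coordinate.
Keeping a single internal convention removes the dominant bug class in
annotation plumbing.

## Consensus gene calling

Prokaryotic ab initio callers disagree mostly about start codons and
rarely about stops, so calls are clustered by the stable coordinate:
the key (contig, strand, stop), where "stop" is `end` on `+` and
`start` on `-`. One consensus gene is emitted per cluster.

Start selection within a cluster:

1. **Majority vote** — each predictor votes once per distinct start it
   called for this stop.
2. **Tie → longest ORF.** Two distinct starts sharing a stop always
   differ in length, so this step is decisive whenever votes tie.
3. **Residual tie → predictor priority order**, then the numerically
   smallest start. These last resorts exist so the result is a total,
   deterministic function of the input set, independent of input
   ordering (property-tested).

Parameters (`consensus:` config block):

| parameter | default | meaning |
|---|---|---|
| `min_cds_len` | 90 nt | minimum consensus CDS length (30 aa, a conventional prokaryotic small-ORF floor); partial genes at contig edges are exempt |
| `start_vote` | majority | or `longest` to always take the longest ORF |
| `orphan_policy` | keep | keep or drop clusters supported by one predictor |
| `max_rna_overlap` | 0 nt | tolerated CDS overlap with the RNA mask |
| `predictor_priority` | empty | tie-break order |

The minimum length is applied to every consensus gene, not only
single-predictor clusters: a too-short gene is no more credible for
being called twice.

RNA genes are handled before protein genes: rRNA/tRNA intervals are
unioned into a strandless per-contig mask (overlapping or abutting
intervals merged), and any consensus CDS whose overlap with a mask
interval exceeds the tolerance is removed, with the overlap length
logged. RNA genes are never removed. The mask is applied to predictor
*outputs* rather than to the genome sequence, because predictor outputs
are this layer's inputs; with a zero tolerance the two formulations
select the same gene set.

## Product assignment

The goal is to minimise uninformative product names while never
inventing function. For each gene, databases are scanned in precedence
order (default `uniprot > nr > kegg > cdd`, mirroring the order the
searches are typically run); within a database, hits are ranked by
(bitscore desc, e-value asc, subject asc) and must pass

* e-value ≤ `max_evalue` (default 1e-5),
* percent identity ≥ `min_identity` (default 30),
* query coverage ≥ `min_query_cov` (default 0.5, enforced only when the
  query length is known).

These are community-standard homology-annotation thresholds, kept
configurable. The first passing hit whose *cleaned* name is
non-hypothetical supplies the product. Cleanup rules strip database
formatting (`MULTISPECIES: `, `RecName: Full=`, trailing `[organism]`
brackets, UniProt `AltName` tails) so that formatting artifacts never
leak into product names or fool the hypothetical test.

Fallback chain when no database yields an informative name:
best InterPro-integrated domain → `"<signature description>-family
protein"`; else the best passing hit's name even if hypothetical; else
`hypothetical protein` with source `none`. The functional/hypothetical
status is always recomputed from the final name against the
case-insensitive substring list
`{hypothetical, uncharacterized, uncharacterised, unknown function,
predicted protein, DUF}` (configurable). The `DUF` pattern
intentionally treats "domain of unknown function" families as
uninformative even when a domain was found.

Functional + orphan always equals the number of assignments; the tally
covers whatever set the caller passes (the pipeline passes CDS only —
whether RNA genes count as functional is the caller's choice).

## Contig taxonomy voting

Each gene with at least one species-resolvable hit contributes exactly
one vote: the species of its top-ranked hit. The ranked list below the
top participates only through the tie-break: when two species tie on
votes within a scope, the winner is the species with the larger total
alignment length summed over *all* of its hits among the scope's
genes' hit lists. A residual tie falls to lexicographic order so the
result is total and deterministic. Species are taken from an explicit
species column when present, else from the last `[...]` group of the
subject description (the NCBI defline convention); optional binomial
truncation keeps two tokens, three for *Candidatus* names. One
designated database (config `gbt.db`, default `nr`) feeds the vote.

The vote is evidence about contig origin (useful for spotting
contamination or chimeric assemblies), not a verdict; no taxonomy
database lookups or LCA computations are attempted.

## Benchmarking semantics

Reference genes partition into three categories. A candidate pair must
share contig, strand and feature type and overlap by ≥ 1 nt — the
offset rule alone would let a gene kilobases away with a coincidentally
equal coordinate delta count, so co-location is required. Then:

* **identical** — both coordinate deltas are 0;
* **similar** — |Δstart| ≤ offset **or** |Δend| ≤ offset (default 50);
  the disjunction means a gene sharing its stop with a start shifted
  beyond the offset is still similar;
* **not detected** — everything else.

Matching is one-to-one so that false negatives (= not detected) and
false positives (unmatched test genes) are well-defined counts.
Identical pairs are fixed first; the remaining reference genes are
matched to similar-eligible test genes by a maximum-cardinality
assignment that, among equally large matchings, minimises the total
coordinate displacement Σ(|Δstart|+|Δend|) (solved as a min-cost
rectangular assignment where a forbidden pair costs more than all real
pairs combined, which makes cardinality lexicographically dominant).
The similar-phase cardinality is verified against exhaustive
enumeration on small random instances.

A consequence of the disjunction worth noting: at `offset=0` a
non-identical pair sharing one exact coordinate is still similar;
shrinking the offset converts to not-detected only those pairs with no
exactly matching coordinate.

Percentages are of the reference total, rounded to 2 decimals with
ties away from zero (the rounding used everywhere a percentage is
reported). `identical + similar + not_detected` equals the reference
total exactly; the three percentages sum to 100 within rounding slack.

## Summaries and statistics

**Hierarchies.** Per-gene lineage paths (COG categories, GO slims,
taxonomy, domain families — supplied as flat paths, not parsed from
ontology files) roll up into a counted tree with set-union semantics: a
node counts *distinct* genes in its subtree, so a gene reached via two
paths through one node counts once there. The Krona text rendering is
one `count TAB level1 TAB level2 …` row per leaf, lexicographically
sorted.

**Completeness.** 100 · |observed ∩ core| / |core| against a
domain-specific core-COG list. The shipped lists are clearly labelled
placeholders; completeness is meaningful only relative to a curated
list supplied in config.

**Pathways.** Naive KO-membership counting: a gene counts once per
pathway reachable through any of its KOs. No parsimony-based pathway
pruning is applied, and the report header says so. Highlight URLs
target the public KEGG `show_pathway` endpoint with sorted,
deduplicated KOs so equal gene sets give byte-equal URLs.

**Enrichment.** For each term carried by ≥ 1 list gene, the p-value is
the exact upper hypergeometric tail P[X ≥ k] (population N = background
genes, K carriers, n draws). Corrections: Bonferroni (multiply by the
number of tested terms, cap at 1) or Benjamini–Hochberg step-up. The
tail is verified against exact rational-arithmetic enumeration of all
C(N, n) draws for N ≤ 12.

## Synthetic data

The generator is a pure function of a seeded spec; regeneration is
byte-identical. Defaults describe a small draft genome: 2 contigs,
50 genes (4 RNA), gene lengths 300–1500 nt, intergenic gaps 50–200 nt,
uniform base composition with planted ATG/TAA codons (strand-aware).
The perturbed "test" annotation applies 5 frame-preserving start shifts
of ≤ 50 nt (inward, so the gene keeps its stop and overlaps the
original), 3 deletions and 4 spurious intergenic ORFs — chosen so every
planted change maps to exactly one benchmark category and the expected
report (42, 5, 3, 4) is exact by construction. Homology tables plant a
70/30 species mixture; top-hit species are apportioned per contig by
largest remainder and shuffled, so a fraction above 0.5 is a
*guaranteed* per-contig majority rather than an expectation. Three
derived predictor call sets (one exact, one with ~20 % starts shifted
3 nt, one missing ~10 % of genes) make the majority-vote consensus
provably equal to the truth.

What the fixtures do **not** emulate: real codon statistics, overlapping
genes (common in dense prokaryotic genomes), frameshifted pseudogenes,
phylogenetically structured hit lists, or e-value/bitscore correlations
of real searches. Passing tests therefore demonstrate the correctness
of the integration arithmetic and tie-break logic under controlled
conditions, not end-to-end annotation accuracy on real genomes — the
latter depends on the upstream tools and databases, which this package
deliberately does not run.

## Numerical choices

* Percentages: 2 decimals, ties away from zero (decimal arithmetic, not
  binary-float `round`).
* Hit ranking: (bitscore desc, e-value asc, subject id asc) — a total
  order, so permuting input rows never changes results.
* All voting/tie chains end in a lexicographic or positional key; every
  reported result is a deterministic function of the input *set*.
* Assignment solver: `scipy.optimize.linear_sum_assignment` with the
  forbidden-pair cost set above the sum of all real pair costs.
* Seeded randomness: `numpy.random.default_rng` with stream-separated
  seed sequences per generator, so adding hits does not perturb gene
  placement.

## Known limitations

* The warehouse XML schema is a minimal explicit entity/attribute model
  (organism, contig, gene, protein, GO/pathway/domain references by
  identifier only), not a full data-warehouse genomic model.
* TBL output covers gene/CDS/rRNA/tRNA with locus_tag/product
  qualifiers; full INSDC qualifier coverage is out of scope, as are
  GenBank flat files and submission (`.sqn`) processing.
* Translation-table inference, operon/promoter/terminator finding and
  running the upstream predictors/searches themselves are out of scope.
* Benchmark problem sizes in the shipped tests (50-gene fixtures,
  ≤ 8-gene exhaustive instances, N ≤ 12 enrichment enumeration) were
  chosen so the oracles stay exhaustive; all scale linearly or better
  in practice.
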