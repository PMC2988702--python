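# Methods

## Problem setting and model

The package operationalises a simple contrast: a gene is *associated* with a
literature topic when documents about the topic mention it more often than
comparable documents that are not about the topic.  The unit of evidence is
the **document frequency** — the fraction of corpus documents mentioning a
target at least once.  Mentions are binarised per document: a review that
names a gene forty times and a paper that names it once contribute equally,
which keeps the statistics insensitive to within-document repetition and
lets every comparison reduce to 2×2 tables of document counts.

### Dictionary tagging

Targets are found by literal dictionary matching, not learned NER.  A match
string hits the text only between word boundaries (a boundary is any
transition between ASCII alphanumeric and anything else, so hyphenated
synonyms like `TNF-alpha` match literally and `CAT` never fires inside
`CATALOG`).  Overlapping candidate matches are resolved greedily — longest
first, then leftmost, ties by lexicon order — except that candidates with an
*identical* span co-attribute: a surface form claimed by several targets (a
symbol collision) counts for all of them, and collisions are reported for
manual blacklisting rather than disambiguated contextually.  The blacklist
is applied after matching; an entry `(string, context)` suppresses a match
when the context substring co-occurs in the text (empty context or `*`
suppresses unconditionally), modelling manual curation of systematic false
hits.

Case handling defaults to a symbol heuristic: strings of length ≤ 4 or
containing a digit are matched case-sensitively (they behave like gene
symbols), longer plain strings case-insensitively (they behave like common
nouns).  Explicit per-string flags in the lexicon file override this.

Tagging quality is summarised as recall against a curated document–gene
gold standard.  Precision is reported only when the gold set is asserted to
be exhaustive; curated-link databases list true associations but not all of
them, so precision against a non-exhaustive gold set would be meaningless
and is returned as NaN.  The F-measure uses the harmonic mean
`2PR/(P + R)`.  Curated genes missed by the tagger are merged into the
working target set, with the merge bookkeeping
(identified / gold / overlap / merged counts) reported.

### Issue-matched backgrounds

The choice of background corpus dominates what "over-represented" means.
Sampling from the whole literature would conflate topic signal with venue
and era effects; this package instead matches each foreground document with
one random document from the *same journal, volume and issue* that carries
none of the topic index terms.  Sampling is without replacement within a
set (a background document serves at most one foreground document — sets
are document sets, and duplicates would distort frequencies), and
independent sets are drawn with distinct seeds, so the same document may
recur across sets.  A foreground document whose issue offers no index-free
companion is handled by a configurable fallback: `skip` (default; drop the
pair and log it), `strict` (error), or `widen_volume` (relax matching to
the same journal and volume).  The foreground document itself is never
eligible, even if index-free.

Exchangeability of the background sets is verified before use: for every
target and every pair of sets, a two-sided exact test on documents-with vs
documents-without, one BH adjustment across all (target, pair) tests, and
the expectation that nothing is significant at 0.05.

### Over-representation and the consensus rule

Per background set, every target observed in either corpus gets the 2×2
table (a, b; c, d) = (foreground with, foreground without; background with,
background without) and a two-sided Fisher exact p; BH is applied across all
targets of that one comparison (each foreground-vs-background comparison is
its own multiple-testing family).  Two-sided testing is used at this stage
because the screen asks whether frequencies *differ*; the enrichment stage,
which asks only about over-representation, is one-sided.

The consensus rule selects a target iff its raw p < α_raw in **all** k
comparisons and its BH-adjusted p < α_BH in ≥ 2 of them (both thresholds
0.05).  A configuration switch drops the all-raw condition, giving the
laxer adjusted-only reading.  Selected targets are ranked by the ascending
geometric mean of the k raw p-values (floored at 1e-300 to avoid log 0),
with ties broken by foreground document count descending, then symbol; the
exact sort key of such rankings is a free choice and the geometric mean is
monotone with any single comparison's p when the others are comparable.

### Network connectivity null

The coherence of a selected target set is probed in an undirected
interaction network with four statistics of the target-induced subgraph:
targets with ≥ 1 edge to any node, targets with ≥ 1 edge to another target,
within-set edge count, and maximum induced degree.  Maximum degree is
computed on the *induced subgraph*, not the whole network: only the induced
reading is consistent with random equal-size sets exhibiting small
null means at realistic densities.  The null distribution draws equal-size
gene sets uniformly without replacement from a gene universe that may
include genes absent from the network — such genes count as isolated, which
mirrors drawing from a full nomenclature list rather than from network
nodes only.

Three comparisons are reported per statistic: a Z-score against the null
mean and SD (upper-tail normal p on |Z|); a one-sample t-test treating the
null draws as the sample and the observed value as the reference mean
(hence *negative* t when the observation exceeds the null mean, df = n − 1);
and the add-one empirical p `(1 + #{null ≥ obs})/(n + 1)`, which cannot
reach zero at finite n.  Extreme tail probabilities are evaluated through
log survival functions, and log10 p is carried alongside p so that
statistics of magnitude several hundred report finite log-probabilities
instead of a flat underflowed zero.

### Enrichment

Term-level over-representation uses the upper-tail hypergeometric
probability of k annotated targets among n, given K annotated genes in a
universe of N, with fold enrichment (k/n)/(K/N).  BH runs within each
annotation namespace (biological-process terms form one family, pathways
another, and so on), matching how catalogs are conventionally reported.
The default universe is the full target lexicon; annotated genes outside
the universe are dropped with a logged count.  When the target list *is*
the universe the table degenerates and p = 1, fold = 1 by construction.

## Statistical kernels

* **Fisher's exact test** sums the conditional hypergeometric mass over the
  support of cell *a* with margins fixed (the mass itself comes from
  `scipy.stats.hypergeom`).  The two-sided p totals all tables whose point
  mass does not exceed the observed one, with a relative tie tolerance of
  1e-7 — floating-point equality of masses is ill-defined, and the
  tolerance makes tie handling explicit and testable.  Sums within 1e-9 of
  1 are snapped to exactly 1 (whole-support sums land at 1 − O(ε)).
  Degenerate column margins return p = 1 with a flag.  The implementation
  is validated exhaustively against an exact-rational enumeration oracle
  for every margin-fixed table with N ≤ 30, and against
  `scipy.stats.fisher_exact` on random tables.  Note that under the
  minimum-likelihood two-sided definition the folk bound
  "two-sided p ≤ 2·min(one-sided p)" is *false* (e.g. table (6, 10; 1, 11)
  gives 0.184 > 2 × 0.0908); the tests assert the true relations instead.
* **Benjamini–Hochberg** is the step-up map q(i) = min_{j≥i} p(j)·m/j over
  the ascending order, capped at 1, returned in input order; validated
  against a naive O(m²) evaluation of the definition and against
  `statsmodels.stats.multitest.multipletests`.
* **Z and one-sample t** are the textbook quantities; both are invariant
  under common affine rescaling of their inputs, which the tests assert.

## Synthetic data: what it emulates, and what it does not

Documents are bags of the mentioned targets' match strings separated by
filler tokens from a fixed non-matching vocabulary.  No natural-language
realism is attempted: the analysis consumes only occurrence structure, so
the generator guarantees that the tagger can recover the planted truth
table *exactly* (synonyms are embedded verbatim), and tagger correctness is
tested against generator truth, never the reverse.  Consequently, passing
tests demonstrate the statistics and the plumbing, not robustness to real
text phenomena — abbreviation ambiguity, species homonyms, OCR noise and
hedged mentions are all outside what these tests can show.

The reference study conditions (the generator defaults) are: a
3,000-document universe organised as 10 journals × 5 volumes × 6 issues ×
10 documents; a 300-document foreground defined by carrying the excluded
index terms, spread so no issue is more than half foreground (guaranteeing
every foreground document an index-free companion even under
no-replacement sampling); 300 lexicon targets with 1–3 synonyms; baseline
mention probability 0.03 per target per document; 12 planted targets at
foreground probability 0.15 vs background 0.0375 (a 4× ratio, chosen as a
clearly recoverable but not overwhelming effect at these corpus sizes);
40% of documents carry a full-text unit, and mentions in such documents
reach the abstract with probability 0.6 (so abstract-only tagging finds
strictly less, emulating the value of full text); a 2,000-gene interaction
network at background edge probability 0.005 with the planted targets as a
module at 0.05 (10×); and a 50-term annotation catalog (sizes 10–40) plus
one planted term whose members are 60% planted targets.  The synthetic
gold standard samples 30% of true foreground links and adds two
extra-lexicon genes, so recall is high but below 1 and the merge step is
exercised.

Test and acceptance runs use these conditions or documented scaled-down
variants (e.g. 200-document, 100-target mention-model replicates for
calibration at 200 repetitions; a 90-document fixture with a stronger
planted contrast for fast end-to-end checks) — sizes chosen so each suite
runs in minutes on a single CPU.

## Numerical and design choices

* p-values are floored at the smallest positive float and never reported as
  0; log10 p accompanies extreme values.
* The consensus screen's tested universe is the union of targets observed
  in the foreground or any background; zero-count cells are legitimate
  exact-test inputs.
* Within one pipeline run, per-stage seeds are derived from the run seed by
  fixed offsets; reruns with the same config and seed are byte-identical in
  the report body.
* The empirical-p add-one estimator bounds p away from 0 at
  1/(n_iterations + 1); at the default 100 iterations the finest resolvable
  empirical p is ≈ 0.0099.
* The published tagging benchmark's F-measure (75.8% at recall 87.1%,
  precision 71.3%) is inconsistent with the harmonic-mean formula, which
  gives 78.4%; the formula is implemented as stated and this discrepancy is
  recorded here rather than resolved (it is consistent with per-document
  macro-averaging in the original tool).

## Known limitations

* No contextual disambiguation of colliding symbols; collisions are only
  logged for manual blacklisting.
* Background matching controls journal/volume/issue but not article type,
  length or citation stratum.
* The consensus rule is a hard filter, not a combined meta-analytic test;
  borderline targets (raw p ≈ 0.05 in one comparison) flip with the
  background draw.
* The network null draws uniform gene sets; it does not preserve degree
  sequences, so hub-heavy target sets gain significance partly from degree
  alone.
* GMT catalogs are taken as pre-propagated; no ontology-graph reasoning.
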