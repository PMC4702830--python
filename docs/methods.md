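# Methods

kbforge builds topic-specific literature knowledgebases from a MEDLINE-like
corpus of titles and abstracts, then derives statistically enriched
concepts, concept–concept associations, transitive (ABC) hypotheses,
annotation-set enrichments and exploration networks. This note documents
the model behind each stage, the tunable parameters, the synthetic-data
machinery the tests rest on, and the design decisions taken where the
design was genuinely open.

## Concept model and dictionary cleaning

A *concept* is a normalized entity: one stable identifier covering a set of
synonym surface strings (*terms*) inside one named, categorized
*dictionary*. Normalization at load applies Unicode NFKC, collapses
whitespace and drops punctuation-only tokens, so typographic variants of
the same term collide onto one stored form.

Three cleaning mechanisms operate per dictionary:

- **Ambiguity exclusion.** A surface claimed by two or more concepts of the
  *same* dictionary cannot be attributed and is excluded from matching
  (logged with reason `ambiguous`). The concept remains reachable through
  its other synonyms; a concept whose term set empties is retained with a
  stable identifier but flagged unmatchable. Sharing across *different*
  dictionaries is deliberately preserved — each dictionary indexes the
  surface independently, and downstream stages treat
  `(concept_id, dictionary)` as the unit of identity.
- **Stoplist.** Case-insensitive removal of common words (reason
  `stopword`).
- **Promiscuity report.** Corpus document frequency per surface, with a
  flag above `max_doc_fraction` (default 0.01, i.e. a term hitting more
  than 1% of all documents carries little topical signal). The report is
  advisory: removal is a curation decision, executed by feeding flagged
  surfaces back through the stoplist mechanism.

Case policy: surfaces of length ≥ 4 match case-insensitively; shorter
surfaces (gene symbols such as "ACE") match exactly. This is a documented
package decision — short-symbol case-folding is a notorious source of
false positives, and no principled universal rule exists.

## Matching and the global index

Each document field (title, abstract) is tokenized into maximal
alphanumeric runs; a term matches a run of consecutive tokens whose
separators consist only of whitespace and hyphens, making
"beta-lactamase" and "beta lactamase" interchangeable. Matches always
respect token boundaries. Within one dictionary, overlapping candidates
resolve leftmost-longest (the Aho–Corasick reporting convention); ties on
an identical span resolve to the lexicographically smallest concept.
Dictionaries never compete with each other.

The production matcher scans token positions through a first-token lookup
table. Its conformance contract is behavioural: it must agree exactly with
a quadratic brute-force matcher (every term attempted at every character
position, same selection rule), and the test suite enforces this on
adversarial random documents. Matching runs per field without sentence
segmentation; a sentence-splitting variant would only shrink span extents,
not document-level counts, and document-level counts are all that the
statistics consume.

The global index stores character-level spans (for highlighting) and
document-level occurrence sets (a concept counts once per document
regardless of mention count). It persists as sorted TSVs plus a JSON
manifest with content hashes of corpus and dictionaries, so staleness is
detectable and rebuilds are byte-identical. A knowledgebase (KB) is the
restriction of the index to a topic-defining document-id list.

## Enrichment statistics

For a concept in `k` of the `n` KB documents and `K` of the `N` corpus
documents, the enrichment p-value is the upper hypergeometric tail
P(X ≥ k), X ~ Hypergeom(N, K, n). Tail sums are accumulated from log-pmf
terms via log-sum-exp (falling back to the closed-form survival function
only for tails longer than 20 000 terms), and reported values are clipped
to [1e-300, 1]. Benjamini–Hochberg step-up correction runs across all
tested concepts of a KB jointly (not per dictionary — one FDR scale per KB
view); concepts with FDR ≤ alpha (default 0.05) are reported. Concepts
absent from the KB are not tested: they cannot be enriched and would only
dilute the correction.

Associations are scored between enriched concepts only. For a pair with
`n_ab` joint KB documents and KB marginals `n_a`, `n_b`:

- PMI = log2(n_ab · n / (n_a · n_b)) in bits, with KB document frequencies
  as probability estimates. Base 2 is a convention; it rescales but never
  reorders.
- Significance, two modes:
  - `background="corpus"` (default): P(X ≥ n_ab) drawing `n` of the `N`
    corpus documents with the pair's whole-corpus co-occurrence count as
    successes — "is this pair over-represented in the KB relative to the
    literature at large?"
  - `background="kb"`: P(X ≥ n_ab) for X ~ Hypergeom(n, n_a, n_b) —
    conditional independence of the two concepts *within* the KB.

  The two modes answer different questions. The corpus mode inherits the
  marginal enrichment of both members: two strongly enriched but mutually
  independent concepts can pass it. The KB mode isolates dependence. Both
  are exposed; validation uses the corpus mode for pair recovery (the
  default reading) and the KB mode where the measured property is the
  dependence structure itself (bridge sets of chain hypotheses, below).
- BH across all candidate pairs; pairs that never co-occur are never
  scored.

## Transitive hypotheses

Over the graph of significant associations, a pair (A, C) is a hypothesis
when it has at least one common neighbor B (the *bridge*), no direct
association, and zero direct co-occurrence — by default zero within the KB,
optionally zero in the whole corpus (`scope="corpus"`). Bridges must pass
the association FDR threshold on both sides; mere co-occurrence does not
qualify. Role filters restrict A/B/C to dictionaries (drug–gene–disease
style screens).

Ranking is this package's own convention, isolated so it can be swapped:
bridge count descending, ties broken by the strongest bridge's weaker-side
PMI, then lexicographic pair order for determinism.

## Annotation-set enrichment

Given an external gene→category map, the sample is the intersection of the
KB's enriched gene concepts with the annotated background; each category is
tested hypergeometrically (sample hits vs background membership) with BH
across all categories having at least one background gene. The background
is all genes in the supplied annotation file; taxon-specific analyses are
obtained by pre-filtering the annotation set (`restrict_background`), which
is provably equivalent. Genes mentioned in the KB but absent from the
annotation cannot inform the test and are dropped from the sample.

## Networks

Exploration sessions grow from a single seed concept by expanding nodes
against chosen dictionaries. After adding a node's partners, the graph is
closed over the association list: every association whose two endpoints are
both present becomes an edge, including edges between new and pre-existing
nodes. (Closure restricted to newly added nodes was the alternative; it was
rejected because a drug reached through a fungus would then not connect to
an already-present enzyme it is significantly associated with, breaking the
expand-and-inspect workflow.) Edge attributes are the co-occurring document
count, PMI and FDR; node identity is `(concept_id, dictionary)`, and the
dictionary is exported as a categorical attribute rather than a color.
Every step is appended to a history sufficient to replay the session
deterministically. Exports: SIF with an edge-attribute sidecar, lossless
GraphML, plain edge TSV.

## Synthetic corpora and ground truth

The generator emits documents as bags of filler pseudo-words with concept
terms embedded, plus dictionary TSVs, a topic id list and a machine-readable
ground truth. Its parameters define the validation study conditions:

- Each concept has a document probability inside the topic subset (`p_kb`)
  and outside it (`p_background`). A concept is truly enriched iff its
  expected within-KB frequency exceeds the background one. KB membership is
  deterministic by document-id prefix, so KB counts are exactly
  controllable.
- A planted pair co-occurs within the KB with joint probability
  `excess · p_a · p_b`. When the requested excess exceeds what the
  marginals admit (e.g. excess 4 at marginals 0.3 implies a joint of 0.36 >
  0.3), the joint probability saturates at `min(p_a, p_b)` — perfect
  nesting, the strongest dependence those marginals allow. Outside the KB
  the members are independent.
- A planted chain draws its two endpoints mutually exclusively (never in
  one document, anywhere in the corpus) and boosts the bridge to
  probability 0.8 in any document carrying an endpoint.
- Filler words and concept terms come from disjoint pseudo-word pools, so
  matcher correctness and statistical behaviour are testable independently.
  A fixed seed makes generation byte-identical.

Canned designs used by the validation suite and `scripts/acceptance.py`:

- *null corpora*: 500 documents, KB fraction 0.2, 20 concepts with
  `p_kb = p_background` spread over 0.05–0.3 — every reported concept or
  pair is a false discovery. Over 200 replicates the mean false discovery
  proportion at alpha 0.05 must stay within 0.05 + 3·SE.
- *pair power*: one pair at within-KB marginals 0.3, joint excess 4
  (saturated as above), background probability 0.05, KB of 200 documents in
  a 600-document corpus, 10 null bystander concepts; recovery required in
  ≥ 90% of 100 seeds.
- *chain power*: endpoints at `p_kb` 0.3, bridge baseline 0.1, bridge boost
  0.8, same corpus shape; the (A, C) hypothesis with bridge set exactly
  {B} required in ≥ 90% of 100 seeds, scored with the KB-conditional
  background (see above).

What passing these tests does **not** show about real literature: documents
here are exchangeable bags of words with independent concepts unless
planted — no topical drift, no correlated vocabularies, no synonymy beyond
the dictionary, no mention-frequency effects, no time structure. The tests
certify the machinery (counting, tail probabilities, correction, graph
logic), not the scientific validity of any particular association mined
from PubMed.

## Numerical and determinism policy

All iteration over sets is sorted before anything user-visible is emitted;
ties everywhere break by identifier. P-values live in [1e-300, 1]; BH uses
a stable argsort so tied p-values share adjusted values. Indexing involves
no randomness; generation is fully driven by one integer seed. Every
artifact (index TSVs, tables, GraphML) rebuilt from identical inputs is
byte-identical, which the test suite checks with file comparison.

Problem sizes in the validation suite (200 null replicates of 500
documents, 100 power seeds of 600 documents, the exhaustive 6-node graph
sweep) were chosen so the complete suite and the acceptance script each run
in well under a minute of CPU beyond the statistical minimums the checks
require, while keeping Monte-Carlo standard errors small relative to the
thresholds tested.

## Known limitations

- Matching is surface-based: no abbreviation expansion, no morphological
  variation beyond case and hyphen/space, no disambiguation of terms that
  are ambiguous *across* dictionaries (by design, they index in each).
- The corpus-background pair test conflates marginal enrichment with
  dependence (discussed above); users screening for mechanistic links
  should prefer `background="kb"`.
- Hypothesis ranking has no external validation; bridge count is a
  transparent but crude prior.
- The highlight markup cannot round-trip text that itself contains the
  literal sequence `]]`.
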