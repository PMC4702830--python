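# kbforge

Topic-specific literature knowledgebases from a document corpus: dictionary
tagging, concept enrichment, association networks, and literature-based
discovery.

Researchers exploring a domain — say, microbial production of a compound —
face a corpus far too large to read. kbforge builds a *knowledgebase* (KB)
for a topic: it tags every title and abstract of a MEDLINE-like corpus
against controlled vocabularies (taxa, genes, chemicals, functional
annotations, …), restricts the resulting index to a topic-defining list of
document ids, and asks which concepts and which concept *pairs* are
statistically over-represented in the topic relative to the whole corpus.
On top of the significant pairs it generates transitive hypotheses and
incremental exploration networks.

## Statistics at the core

For a concept appearing in $k$ of the $n$ KB documents and $K$ of the $N$
corpus documents, enrichment is the upper hypergeometric tail

$$p = P(X \ge k), \qquad X \sim \mathrm{Hypergeom}(N, K, n),$$

corrected across all tested concepts by Benjamini–Hochberg; concepts with
FDR ≤ 0.05 (default) form the KB's concept table. Pairs of enriched
concepts co-occurring in $n_{ab}$ KB documents are scored by pointwise
mutual information

$$\mathrm{PMI} = \log_2 \frac{n_{ab}\, n}{n_a\, n_b} \text{ (bits)}$$

and by a hypergeometric co-occurrence test (against the whole corpus by
default, or conditionally within the KB), again BH-corrected. Swanson's
ABC scheme then proposes hidden links: if A–B and B–C are significant but
A and C never share a document, (A, C) becomes a ranked hypothesis with B
as its bridge. A KOBAS-style module tests external gene→pathway
annotations for over-representation among the KB's genes.

Documents count once per concept no matter how many mentions they contain;
matching is character-exact (for highlighting) but all statistics run on
document-level counts.

## Worked example

A small built-in corpus encodes a drug-repositioning scenario: an enzyme
co-occurs with a fungus and with a bacterium, the fungus and the enzyme
co-occur with a drug, but the drug and the bacterium never share a
document.

```python
from kbforge.fixtures import repositioning_demo
from kbforge.pipeline import run_pipeline

fx = repositioning_demo()
res = run_pipeline(fx.corpus, fx.dictionaries, fx.topic_ids)
for e in res.enriched:
    print(e.preferred_name, e.dictionary, e.kb_count, e.corpus_count, f"{e.fdr:.3g}")
```

```
isocitrate lyase        Enzymes    20     20   2.97e-18
saccharomyces modelus   Fungi      13     13   6.79e-11
fenicolin               Drugs       9      9   1.78e-07
mycobacterium demoensis Bacteria    6      6   3.78e-05
```

All four concepts appear only inside the 25-document topic subset of the
125-document corpus, so each is strongly enriched (the FDR column is the
BH-adjusted hypergeometric tail). The association stage keeps the four
genuinely co-occurring pairs with their document counts:

```
ENZ1--FUN1  n_ab=8  pmi=-0.379  fdr=3.68e-06
BAC1--ENZ1  n_ab=6  pmi=0.322   fdr=7.55e-05
DRG1--FUN1  n_ab=5  pmi=0.095   fdr=0.000302
DRG1--ENZ1  n_ab=4  pmi=-0.848  fdr=0.00131
```

and the hypothesis stage proposes exactly the two pairs that are bridged
but never co-occur — including the repositioning candidate, drug–bacterium
through the shared enzyme:

```
hypothesis BAC1--FUN1 via ['ENZ1'] score=1
hypothesis BAC1--DRG1 via ['ENZ1'] score=1
```

Seeding a network at the enzyme, expanding it by the taxon dictionaries
and expanding the fungus by drugs reproduces this structure as a graph
whose edge labels are the co-occurrence counts above
(`kbforge.network.seed_network` / `expand_node` / `export_network`, or the
`kbforge network` CLI command).

## Command line

```sh
kbforge simulate --spec spec.yaml --out data/          # synthetic corpus + truth
kbforge index --corpus corpus.tsv --dicts d1.tsv,d2.tsv --out idx/
kbforge build-kb --index idx/ --ids topic_ids.txt --name mytopic
kbforge concepts --index idx/ --kb mytopic --out concepts.tsv
kbforge associations --index idx/ --kb mytopic --rank pmi --out assoc.tsv
kbforge hypotheses --index idx/ --kb mytopic --a-dict Drugs --c-dict Taxa --out hyp.tsv
kbforge network --index idx/ --kb mytopic --seed 'Enzymes::E1' --expand Fungi --out net.graphml
```

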