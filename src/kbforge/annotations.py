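"""Annotation-set (pathway) enrichment over KB gene mentions.

Given an external gene→category annotation map (e.g. gene-to-pathway
assignments), the genes mentioned in a knowledgebase form the *sample* and
all annotated genes form the *background*; each category is tested for
over-representation of sample genes by the upper-tail hypergeometric
probability, with BH correction across all categories. Genes mentioned in
the KB but absent from the annotation file cannot inform the test and are
dropped from the sample (the intersection rule).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .errors import FormatError, UsageError
from .stats import EnrichedConcept, bh_adjust, hypergeom_sf


@dataclass
class AnnotationSet:
    mapping: dict[str, set[str]]  # gene_concept_id -> category_ids
    category_names: dict[str, str]
    background_genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.background_genes:
            self.background_genes = set(self.mapping)

    def restrict_background(self, genes) -> "AnnotationSet":
        """Pre-filter to a gene subset (e.g. one taxon's genes)."""
        keep = set(genes)
        return AnnotationSet(
            mapping={g: set(cats) for g, cats in self.mapping.items() if g in keep},
            category_names=dict(self.category_names))

    def genes_in_category(self, category_id: str) -> set[str]:
        return {g for g, cats in self.mapping.items() if category_id in cats}


def load_annotations(path) -> AnnotationSet:
    """TSV `gene_concept_id  category_id  category_name`, one row per pair."""
    required = ("gene_concept_id", "category_id", "category_name")
    mapping: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise FormatError(f"{path}: empty annotation file") from None
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        col = {c: header.index(c) for c in required}
        for row in reader:
            if not row or all(not f.strip() for f in row):
                continue
            gene = row[col["gene_concept_id"]].strip()
            cat = row[col["category_id"]].strip()
            if not gene or not cat:
                continue
            mapping.setdefault(gene, set()).add(cat)
            names.setdefault(cat, row[col["category_name"]].strip())
    if not mapping:
        raise FormatError(f"{path}: no annotation rows parsed")
    return AnnotationSet(mapping=mapping, category_names=names)


@dataclass(frozen=True)
class CategoryEnrichment:
    category_id: str
    category_name: str
    sample_count: int
    background_count: int
    p_value: float
    fdr: float


def enrich_annotations(kb_genes, ann: AnnotationSet, alpha: float = 0.05
                       ) -> list[CategoryEnrichment]:
    """Categories over-represented among KB genes at FDR <= alpha.

    sample = kb_genes ∩ background; per category,
    p = P(X >= |sample ∩ category|) for X ~ Hypergeom(|background|,
    |background ∩ category|, |sample|). The BH family is every category with
    at least one background gene. A gene annotated to several categories
    counts once in each.
    """
    sample = set(kb_genes) & ann.background_genes
    if not sample:
        raise UsageError(
            "no KB gene appears in the annotation background; "
            "supply an annotation file covering the KB's gene dictionaries")
    N = len(ann.background_genes)
    n = len(sample)
    cats = sorted({c for cats in ann.mapping.values() for c in cats})
    p_values = []
    rows = []
    for cat in cats:
        members = ann.genes_in_category(cat)
        K = len(members)
        if K == 0:
            continue
        k = len(sample & members)
        p_values.append(hypergeom_sf(k, K, n, N))
        rows.append((cat, k, K))
    fdrs = bh_adjust(p_values)
    out = []
    for (cat, k, K), p, q in zip(rows, p_values, fdrs):
        if q <= alpha:
            out.append(CategoryEnrichment(
                category_id=cat, category_name=ann.category_names.get(cat, cat),
                sample_count=k, background_count=K, p_value=p, fdr=q))
    out.sort(key=lambda r: (r.fdr, r.category_id))
    return out


def genes_from_enriched(enriched: list[EnrichedConcept], gene_dictionaries) -> set[str]:
    """Concept ids of enriched concepts belonging to gene dictionaries.

    The KB's gene sample is taken from the *enriched* concept table (not raw
    mentions), restricting to the named dictionaries.
    """
    wanted = set(gene_dictionaries)
    return {e.concept_id for e in enriched if e.dictionary in wanted}


def write_annotation_tsv(items: list[CategoryEnrichment], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category_id\tcategory_name\tsample_count\t"
                 "background_count\tp_value\tfdr\n")
        for r in items:
            fh.write(f"{r.category_id}\t{r.category_name}\t{r.sample_count}\t"
                     f"{r.background_count}\t{r.p_value:.6g}\t{r.fdr:.6g}\n")
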