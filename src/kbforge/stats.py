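"""Statistical core: hypergeometric enrichment, BH correction, PMI associations.

A concept appearing in ``k`` of the ``n`` KB documents and in ``K`` of the
``N`` corpus documents is tested for over-representation with the upper-tail
hypergeometric probability P(X >= k), X ~ Hypergeom(N, K, n) — the chance of
seeing at least k hits if the KB were an arbitrary n-document subset of the
corpus. P-values are corrected across all tested concepts jointly by the
Benjamini–Hochberg step-up procedure; concepts with FDR <= alpha (default
0.05) make up the KB's concept table.

Associations are scored between *enriched* concepts only: for a pair with
n_ab joint KB documents, pointwise mutual information (in bits, with KB
document frequencies as probability estimates)

    PMI = log2( n_ab * n_kb / (n_a * n_b) )

measures the strength of the dependence, and a hypergeometric test (against
the whole corpus by default, or within-KB) with BH correction measures its
significance. Pairs that never co-occur are not scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .errors import DomainError, IntegrityError, UsageError
from .index import ConceptRef, GlobalIndex, KnowledgeBase, check_kb_against_index, \
    iter_kb_concept_sets

P_FLOOR = 1e-300

#: tail sums with at most this many terms are accumulated exactly in log
#: space; longer tails fall back to the closed-form survival function
_LOGSPACE_MAX_TERMS = 20_000


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, K, n).

    Drawing n documents from a corpus of N that contains K marked ones:
    the probability of at least k marked documents in the draw. Computed in
    log space for numerical stability; the result is clipped to
    [1e-300, 1].
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v:
            raise DomainError(f"{name} must be an integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or K < 0 or n < 0 or K > N or n > N:
        raise DomainError(f"invalid population: K={K}, n={n}, N={N}")
    if k < 0 or k > min(K, n):
        raise DomainError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k <= 0:
        return 1.0
    hi = min(K, n)
    if hi - k + 1 <= _LOGSPACE_MAX_TERMS:
        ks = np.arange(k, hi + 1)
        logp = hypergeom.logpmf(ks, N, K, n)
        p = float(math.exp(logsumexp(logp)))
    else:
        p = float(hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(P_FLOOR, p))


def bh_adjust(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, input order preserved.

    q_(i) = min_{j >= i} ( m * p_(j) / j ) over the sorted p-values, capped
    at 1. Ties are handled by a stable sort, which leaves tied p-values with
    identical adjusted values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q.tolist()


def pmi(n_ab: int, n_a: int, n_b: int, N: int) -> float:
    """Pointwise mutual information in bits from document frequencies."""
    if n_ab < 1:
        raise DomainError("PMI is undefined for pairs with zero co-occurrence")
    if n_ab > min(n_a, n_b) or max(n_a, n_b) > N:
        raise DomainError(
            f"inconsistent counts: n_ab={n_ab}, n_a={n_a}, n_b={n_b}, N={N}")
    return math.log2((n_ab * N) / (n_a * n_b))


@dataclass(frozen=True)
class EnrichedConcept:
    concept_id: str
    dictionary: str
    preferred_name: str
    kb_count: int
    corpus_count: int
    p_value: float
    fdr: float

    @property
    def ref(self) -> ConceptRef:
        return ConceptRef(self.concept_id, self.dictionary)


@dataclass(frozen=True)
class Association:
    concept_a: ConceptRef
    concept_b: ConceptRef
    n_ab: int
    n_a: int
    n_b: int
    pmi: float
    p_value: float
    fdr: float

    @property
    def pair(self) -> tuple[ConceptRef, ConceptRef]:
        return (self.concept_a, self.concept_b)


def _preferred_names(dictionaries) -> dict[ConceptRef, str]:
    names: dict[ConceptRef, str] = {}
    for d in dictionaries or []:
        for cid, c in d.concepts.items():
            names[ConceptRef(cid, d.name)] = c.preferred_name
    return names


def enrich_concepts(kb: KnowledgeBase, index: GlobalIndex, dictionaries=None,
                    alpha: float = 0.05) -> list[EnrichedConcept]:
    """Concepts over-represented in the KB at FDR <= alpha, sorted by FDR.

    Every concept with at least one KB document is tested; the BH family is
    all tested concepts across all dictionaries jointly. Concepts absent
    from the KB are not tested (they cannot be enriched and would only
    dilute the correction).
    """
    check_kb_against_index(kb, index)
    names = _preferred_names(dictionaries)
    refs = sorted(kb.kb_occurrences)
    if not refs:
        return []
    p_values = []
    for ref in refs:
        k = len(kb.kb_occurrences[ref])
        K = len(index.occurrences[ref])
        p_values.append(hypergeom_sf(k, K, kb.n_docs, index.n_docs))
    fdrs = bh_adjust(p_values)
    out = []
    for ref, p, q in zip(refs, p_values, fdrs):
        if q <= alpha:
            out.append(EnrichedConcept(
                concept_id=ref.concept_id, dictionary=ref.dictionary,
                preferred_name=names.get(ref, ref.concept_id),
                kb_count=len(kb.kb_occurrences[ref]),
                corpus_count=len(index.occurrences[ref]),
                p_value=p, fdr=q))
    out.sort(key=lambda e: (e.fdr, e.concept_id, e.dictionary))
    return out


RANK_MODES = ("fdr", "kb_frequency", "corpus_frequency", "alphabetic")


def rank_concepts(items: list[EnrichedConcept], mode: str = "fdr"
                  ) -> list[EnrichedConcept]:
    """Stable re-ranking of the concept table; ties break by concept_id."""
    if mode == "fdr":
        key = lambda e: (e.fdr, e.concept_id)
    elif mode == "kb_frequency":
        key = lambda e: (-e.kb_count, e.concept_id)
    elif mode == "corpus_frequency":
        key = lambda e: (-e.corpus_count, e.concept_id)
    elif mode == "alphabetic":
        key = lambda e: (e.preferred_name.casefold(), e.concept_id)
    else:
        raise UsageError(f"unknown rank mode {mode!r}; choose from {RANK_MODES}")
    return sorted(items, key=key)


def score_associations(kb: KnowledgeBase, enriched: list[EnrichedConcept],
                       index: GlobalIndex, alpha: float = 0.05,
                       background: str = "corpus") -> list[Association]:
    """Significant pairwise associations among enriched concepts.

    Candidates are unordered pairs of enriched concepts co-occurring in at
    least one KB document. PMI uses KB counts. The enrichment p-value of a
    pair compares its KB co-occurrence count against the whole corpus
    (``background="corpus"``, the default) or against independence within
    the KB (``background="kb"``); BH correction runs across all candidate
    pairs. Pairs with FDR <= alpha are returned sorted by FDR.
    """
    if background not in ("corpus", "kb"):
        raise UsageError(f"unknown background {background!r}")
    check_kb_against_index(kb, index)
    refs = {e.ref for e in enriched}
    for ref in refs:
        if ref not in kb.kb_occurrences:
            raise IntegrityError(
                f"enriched concept {ref} has no KB occurrences in this index")
    pair_counts: dict[tuple[ConceptRef, ConceptRef], int] = {}
    for _, present in iter_kb_concept_sets(kb, restrict=refs):
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                pair = (present[i], present[j])
                pair_counts[pair] = pair_counts.get(pair, 0) + 1
    if not pair_counts:
        return []
    pairs = sorted(pair_counts)
    p_values = []
    records = []
    for a, b in pairs:
        n_ab = pair_counts[(a, b)]
        n_a = len(kb.kb_occurrences[a])
        n_b = len(kb.kb_occurrences[b])
        if background == "corpus":
            corpus_ab = len(index.occurrences[a] & index.occurrences[b])
            p = hypergeom_sf(n_ab, corpus_ab, kb.n_docs, index.n_docs)
        else:
            p = hypergeom_sf(n_ab, n_a, n_b, kb.n_docs)
        p_values.append(p)
        records.append((a, b, n_ab, n_a, n_b))
    fdrs = bh_adjust(p_values)
    out = []
    for (a, b, n_ab, n_a, n_b), p, q in zip(records, p_values, fdrs):
        if q <= alpha:
            out.append(Association(
                concept_a=a, concept_b=b, n_ab=n_ab, n_a=n_a, n_b=n_b,
                pmi=pmi(n_ab, n_a, n_b, kb.n_docs), p_value=p, fdr=q))
    out.sort(key=lambda x: (x.fdr, x.concept_a, x.concept_b))
    return out


ASSOCIATION_RANK_MODES = ("fdr", "pmi", "n_ab")


def rank_associations(items: list[Association], mode: str = "fdr"
                      ) -> list[Association]:
    if mode == "fdr":
        key = lambda x: (x.fdr, x.concept_a, x.concept_b)
    elif mode == "pmi":
        key = lambda x: (-x.pmi, x.concept_a, x.concept_b)
    elif mode == "n_ab":
        key = lambda x: (-x.n_ab, x.concept_a, x.concept_b)
    else:
        raise UsageError(
            f"unknown rank mode {mode!r}; choose from {ASSOCIATION_RANK_MODES}")
    return sorted(items, key=key)


def write_concepts_tsv(items: list[EnrichedConcept], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concept_id\tdictionary\tpreferred_name\tkb_count\t"
                 "corpus_count\tp_value\tfdr\n")
        for e in items:
            fh.write(f"{e.concept_id}\t{e.dictionary}\t{e.preferred_name}\t"
                     f"{e.kb_count}\t{e.corpus_count}\t{e.p_value:.6g}\t{e.fdr:.6g}\n")


def write_associations_tsv(items: list[Association], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concept_a\tdictionary_a\tconcept_b\tdictionary_b\t"
                 "n_ab\tn_a\tn_b\tpmi\tp_value\tfdr\n")
        for x in items:
            fh.write(f"{x.concept_a.concept_id}\t{x.concept_a.dictionary}\t"
                     f"{x.concept_b.concept_id}\t{x.concept_b.dictionary}\t"
                     f"{x.n_ab}\t{x.n_a}\t{x.n_b}\t{x.pmi:.6g}\t"
                     f"{x.p_value:.6g}\t{x.fdr:.6g}\n")
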