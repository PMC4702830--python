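"""Transitive (ABC) hypothesis generation over the association graph.

Swanson's literature-based discovery scheme: if A is significantly associated
with B, and B with C, but A and C never appear together in any KB document
(and carry no direct association), then A–C is a candidate hidden link and B
is its *bridge*. A hypothesis collects all bridges supporting one (A, C)
pair.

Role filters restrict each position to a dictionary (e.g. A ∈ drugs,
B ∈ genes, C ∈ diseases), mirroring the drug–protein–disease repositioning
pattern. By default "never appear together" is checked within the KB; with
``scope="corpus"`` the exclusion extends to the whole corpus (requires the
global index).

The ranking score — bridge count, ties broken by the strongest bridge's
weaker-side PMI — is this package's own convention and is deliberately
isolated in :func:`rank_hypotheses` so alternatives can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UsageError
from .index import ConceptRef, GlobalIndex, KnowledgeBase
from .stats import Association


@dataclass(frozen=True)
class RoleFilter:
    """Dictionary constraints for the A / bridge / C positions (None = any)."""

    a_dictionary: str | None = None
    b_dictionary: str | None = None
    c_dictionary: str | None = None


@dataclass(frozen=True)
class Hypothesis:
    concept_a: ConceptRef
    concept_c: ConceptRef
    bridges: frozenset[ConceptRef]
    n_bridges: int
    best_min_pmi: float  # max over bridges of min(PMI(a,b), PMI(b,c))
    direct_cooccurrence: int  # always 0 by construction

    @property
    def score(self) -> float:
        return float(self.n_bridges)


def _role_ok(ref: ConceptRef, dictionary: str | None) -> bool:
    return dictionary is None or ref.dictionary == dictionary


def generate_hypotheses(associations: list[Association], kb: KnowledgeBase,
                        constraints: RoleFilter | None = None,
                        scope: str = "kb",
                        index: GlobalIndex | None = None) -> list[Hypothesis]:
    """All (A, C) pairs linked only through bridges.

    A pair qualifies when it (i) shares at least one association-graph
    neighbor, (ii) has no direct association, and (iii) co-occurs in zero
    documents (KB documents by default; the whole corpus with
    ``scope="corpus"``). An empty association list yields an empty result.
    """
    if scope not in ("kb", "corpus"):
        raise UsageError(f"unknown scope {scope!r}")
    if scope == "corpus" and index is None:
        raise UsageError('scope="corpus" requires the global index')
    constraints = constraints or RoleFilter()

    adjacency: dict[ConceptRef, set[ConceptRef]] = {}
    pmi_of: dict[tuple[ConceptRef, ConceptRef], float] = {}
    assoc_pairs: set[frozenset[ConceptRef]] = set()
    for x in associations:
        adjacency.setdefault(x.concept_a, set()).add(x.concept_b)
        adjacency.setdefault(x.concept_b, set()).add(x.concept_a)
        pmi_of[(x.concept_a, x.concept_b)] = x.pmi
        pmi_of[(x.concept_b, x.concept_a)] = x.pmi
        assoc_pairs.add(frozenset((x.concept_a, x.concept_b)))

    def occ(ref: ConceptRef) -> set[str]:
        if scope == "corpus":
            return index.occurrences.get(ref, set())
        return kb.kb_occurrences.get(ref, set())

    # collect candidate (a, c) pairs through their shared neighbors
    bridges_of: dict[tuple[ConceptRef, ConceptRef], set[ConceptRef]] = {}
    for b, neighbors in adjacency.items():
        if not _role_ok(b, constraints.b_dictionary):
            continue
        ns = sorted(neighbors)
        for i in range(len(ns)):
            for j in range(i + 1, len(ns)):
                a, c = ns[i], ns[j]
                if frozenset((a, c)) in assoc_pairs:
                    continue
                bridges_of.setdefault((a, c), set()).add(b)

    out = []
    for (a, c), bridges in bridges_of.items():
        oriented = None
        if _role_ok(a, constraints.a_dictionary) and _role_ok(c, constraints.c_dictionary):
            oriented = (a, c)
        elif _role_ok(c, constraints.a_dictionary) and _role_ok(a, constraints.c_dictionary):
            oriented = (c, a)
        if oriented is None:
            continue
        if occ(a) & occ(c):
            continue
        best = max(min(pmi_of[(oriented[0], b)], pmi_of[(b, oriented[1])])
                   for b in bridges)
        out.append(Hypothesis(
            concept_a=oriented[0], concept_c=oriented[1],
            bridges=frozenset(bridges), n_bridges=len(bridges),
            best_min_pmi=best, direct_cooccurrence=0))
    return rank_hypotheses(out)


def rank_hypotheses(items: list[Hypothesis]) -> list[Hypothesis]:
    """Descending by bridge count, then by best min-PMI over bridges, then
    lexicographic (a, c) for a fully deterministic order."""
    return sorted(items, key=lambda h: (-h.n_bridges, -h.best_min_pmi,
                                        h.concept_a, h.concept_c))


def write_hypotheses_tsv(items: list[Hypothesis], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concept_a\tdictionary_a\tconcept_c\tdictionary_c\t"
                 "n_bridges\tbridges\tscore\tbest_min_pmi\n")
        for h in items:
            bridges = ";".join(f"{b.concept_id}" for b in sorted(h.bridges))
            fh.write(f"{h.concept_a.concept_id}\t{h.concept_a.dictionary}\t"
                     f"{h.concept_c.concept_id}\t{h.concept_c.dictionary}\t"
                     f"{h.n_bridges}\t{bridges}\t{h.score:.6g}\t"
                     f"{h.best_min_pmi:.6g}\n")
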