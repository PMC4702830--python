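"""Synthetic demonstration fixture: a drug-repositioning-style corpus.

A small, fully deterministic corpus built so that its co-occurrence
structure is known exactly: an enzyme co-occurs with a fungus and with a
bacterium, the fungus co-occurs with a drug, the drug also co-occurs with
the enzyme — but the drug and the bacterium never share a document. Seeding
a network at the enzyme, expanding by the taxon dictionaries and then
expanding the fungus by drugs must therefore link the drug to the fungus and
the enzyme while leaving it disconnected from the bacterium; the
drug–bacterium pair surfaces only as a transitive hypothesis.

All documents and counts are constructed literally (no randomness); the
topic subset is every document that mentions at least one concept, padded
corpus is filler. Entity names are fictional stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import Document
from .dictionaries import Concept, Dictionary

ENZ = "ENZ1"
FUN = "FUN1"
BAC = "BAC1"
DRG = "DRG1"

_TERMS = {
    ENZ: ("isocitrate lyase", "Enzymes", "chemicals"),
    FUN: ("saccharomyces modelus", "Fungi", "taxonomy"),
    BAC: ("mycobacterium demoensis", "Bacteria", "taxonomy"),
    DRG: ("fenicolin", "Drugs", "chemicals"),
}

#: (concept subset, number of KB documents) — the fixture's co-occurrence design
KB_DESIGN = (
    ((ENZ, FUN), 8),
    ((ENZ, BAC), 6),
    ((FUN, DRG), 5),
    ((ENZ, DRG), 4),
    ((ENZ,), 2),
)

N_BACKGROUND = 100

_FILLER = ("culture growth medium assay protocol measurement replicate "
           "sample batch reactor substrate yield analysis baseline control").split()


@dataclass
class DemoFixture:
    corpus: list[Document]
    dictionaries: list[Dictionary]
    topic_ids: list[str]
    #: designed KB co-occurrence counts, sorted concept-id pair -> n documents
    pair_counts: dict[tuple[str, str], int]


def expected_pair_counts() -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for members, n in KB_DESIGN:
        if len(members) == 2:
            counts[tuple(sorted(members))] = n
    return counts


def repositioning_demo() -> DemoFixture:
    docs: list[Document] = []
    i = 0
    for members, n in KB_DESIGN:
        for _ in range(n):
            phrases = [f"studies of {_TERMS[m][0]} were reported" for m in members]
            filler = " ".join(_FILLER[(i + j) % len(_FILLER)] for j in range(8))
            docs.append(Document(
                doc_id=f"KB{i:04d}",
                title=f"report {i} on {_TERMS[members[0]][0]}",
                abstract=". ".join(phrases) + ". " + filler))
            i += 1
    topic_ids = [d.doc_id for d in docs]
    for j in range(N_BACKGROUND):
        filler = " ".join(_FILLER[(j + k) % len(_FILLER)] for k in range(12))
        docs.append(Document(doc_id=f"BG{j:04d}",
                             title=f"background report {j}", abstract=filler))

    dicts: dict[str, Dictionary] = {}
    for cid, (term, dict_name, category) in _TERMS.items():
        d = dicts.setdefault(dict_name, Dictionary(name=dict_name, category=category))
        d.concepts[cid] = Concept(concept_id=cid, preferred_name=term,
                                  dictionary=dict_name, category=category,
                                  terms={term})
    dictionaries = [dicts[name] for name in sorted(dicts)]
    return DemoFixture(corpus=docs, dictionaries=dictionaries,
                       topic_ids=topic_ids, pair_counts=expected_pair_counts())
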