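"""The global index and topic knowledgebases.

The *global index* tags the whole corpus against every dictionary once, at
two granularities: character-level spans per document (for highlighting) and
document-level occurrence sets per concept (for counting — a concept counts
once per document no matter how often it is mentioned). A *knowledgebase*
(KB) is the restriction of the global index to a topic-defining list of
document ids; all downstream statistics compare KB counts against the whole
corpus as background.

Because the same term can be indexed by several dictionaries, concepts are
identified throughout by the pair ``(concept_id, dictionary)``
(:class:`ConceptRef`).

The index persists as a directory of TSVs (``occurrences.tsv``,
``spans.tsv``, ``doc_ids.txt``) plus a JSON manifest carrying content hashes
of the corpus and dictionaries, so a stale index is detectable when inputs
change. All files are written in sorted order; rebuilding from identical
inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .corpus import Document
from .dictionaries import Dictionary, match_key
from .errors import FormatError, IntegrityError, UsageError
from .matching import MatchSpan, compile_dictionaries, match_document

FORMAT_VERSION = 1


class ConceptRef(NamedTuple):
    """Identity of a concept within one dictionary's index records."""

    concept_id: str
    dictionary: str


def _sha256_items(items) -> str:
    h = hashlib.sha256()
    for item in items:
        h.update(repr(item).encode("utf-8"))
    return h.hexdigest()


def corpus_hash(docs: list[Document]) -> str:
    return _sha256_items(sorted((d.doc_id, d.title, d.abstract) for d in docs))


def dictionary_hash(d: Dictionary) -> str:
    return _sha256_items(d.content_hash_items())


@dataclass
class GlobalIndex:
    occurrences: dict[ConceptRef, set[str]]
    spans: dict[str, list[MatchSpan]]
    doc_ids: set[str]
    n_docs: int
    dictionaries: tuple[str, ...]
    manifest: dict = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GlobalIndex):
            return NotImplemented
        return (self.occurrences == other.occurrences
                and self.spans == other.spans
                and self.doc_ids == other.doc_ids
                and self.n_docs == other.n_docs
                and self.dictionaries == other.dictionaries)

    def term_doc_frequency(self, dictionary: str) -> dict[str, int]:
        """match_key(term) -> number of documents with >= 1 span of that term."""
        per_term: dict[str, set[str]] = {}
        for doc_id, spans in self.spans.items():
            for s in spans:
                if s.dictionary == dictionary:
                    per_term.setdefault(match_key(s.term), set()).add(doc_id)
        return {t: len(ds) for t, ds in per_term.items()}


def build_global_index(corpus: list[Document], dictionaries: list[Dictionary]
                       ) -> GlobalIndex:
    """Tag every document against every dictionary; derive occurrence sets."""
    if not corpus:
        raise UsageError("cannot index an empty corpus")
    if not dictionaries:
        raise UsageError("cannot index without at least one dictionary")
    compiled = compile_dictionaries(dictionaries)
    occurrences: dict[ConceptRef, set[str]] = {}
    spans: dict[str, list[MatchSpan]] = {}
    doc_ids: set[str] = set()
    for doc in corpus:
        doc_ids.add(doc.doc_id)
        doc_spans = match_document(doc, dictionaries, compiled=compiled)
        if doc_spans:
            spans[doc.doc_id] = doc_spans
        for s in doc_spans:
            occurrences.setdefault(ConceptRef(s.concept_id, s.dictionary),
                                   set()).add(doc.doc_id)
    manifest = {
        "format_version": FORMAT_VERSION,
        "n_docs": len(doc_ids),
        "corpus_hash": corpus_hash(corpus),
        "dictionaries": {d.name: dictionary_hash(d) for d in dictionaries},
    }
    return GlobalIndex(occurrences=occurrences, spans=spans, doc_ids=doc_ids,
                       n_docs=len(doc_ids),
                       dictionaries=tuple(d.name for d in dictionaries),
                       manifest=manifest)


# --- persistence ------------------------------------------------------------

def save_index(index: GlobalIndex, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest = dict(index.manifest)
    manifest.setdefault("format_version", FORMAT_VERSION)
    manifest["n_docs"] = index.n_docs
    manifest["dictionary_order"] = list(index.dictionaries)
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(directory, "doc_ids.txt"), "w", encoding="utf-8") as fh:
        for doc_id in sorted(index.doc_ids):
            fh.write(doc_id + "\n")
    with open(os.path.join(directory, "occurrences.tsv"), "w", encoding="utf-8") as fh:
        fh.write("concept_id\tdictionary\tn_docs\tdoc_ids\n")
        for ref in sorted(index.occurrences):
            docs = sorted(index.occurrences[ref])
            fh.write(f"{ref.concept_id}\t{ref.dictionary}\t{len(docs)}\t{','.join(docs)}\n")
    with open(os.path.join(directory, "spans.tsv"), "w", encoding="utf-8") as fh:
        fh.write("doc_id\tfield\tstart\tend\tdictionary\tconcept_id\tterm\tsurface\n")
        for doc_id in sorted(index.spans):
            for s in index.spans[doc_id]:
                fh.write(f"{doc_id}\t{s.field}\t{s.start}\t{s.end}\t"
                         f"{s.dictionary}\t{s.concept_id}\t{s.term}\t{s.surface}\n")


def load_index(directory) -> GlobalIndex:
    try:
        with open(os.path.join(directory, "manifest.json"), encoding="utf-8") as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"{directory}: not an index directory (no manifest.json)") from None
    with open(os.path.join(directory, "doc_ids.txt"), encoding="utf-8") as fh:
        doc_ids = {line.strip() for line in fh if line.strip()}
    occurrences: dict[ConceptRef, set[str]] = {}
    with open(os.path.join(directory, "occurrences.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            cid, dname, _, docs = line.rstrip("\n").split("\t")
            occurrences[ConceptRef(cid, dname)] = set(docs.split(",")) if docs else set()
    spans: dict[str, list[MatchSpan]] = {}
    with open(os.path.join(directory, "spans.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            doc_id, fieldname, start, end, dname, cid, term, surface = \
                line.rstrip("\n").split("\t")
            spans.setdefault(doc_id, []).append(MatchSpan(
                doc_id=doc_id, field=fieldname, start=int(start), end=int(end),
                surface=surface, term=term, concept_id=cid, dictionary=dname))
    for doc_spans in spans.values():
        doc_spans.sort(key=MatchSpan.sort_key)
    index = GlobalIndex(
        occurrences=occurrences, spans=spans, doc_ids=doc_ids,
        n_docs=manifest["n_docs"],
        dictionaries=tuple(manifest.get("dictionary_order",
                                        sorted(manifest.get("dictionaries", {})))),
        manifest=manifest)
    _check_consistency(index)
    return index


def _check_consistency(index: GlobalIndex) -> None:
    derived: dict[ConceptRef, set[str]] = {}
    for doc_id, doc_spans in index.spans.items():
        for s in doc_spans:
            derived.setdefault(ConceptRef(s.concept_id, s.dictionary), set()).add(doc_id)
    if derived != index.occurrences:
        raise IntegrityError("occurrences.tsv disagrees with spans.tsv")


# --- knowledgebases ---------------------------------------------------------

@dataclass
class KnowledgeBase:
    name: str
    doc_ids: set[str]
    kb_occurrences: dict[ConceptRef, set[str]]
    n_docs: int
    provenance: str = ""
    n_unknown_ids: int = 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (self.name == other.name and self.doc_ids == other.doc_ids
                and self.kb_occurrences == other.kb_occurrences)


def create_kb(index: GlobalIndex, doc_id_list, name: str,
              provenance: str = "") -> KnowledgeBase:
    """Restrict the global index to a topic-defining document-id list.

    ``doc_id_list`` may be a path (plain text, one id per line) or an
    iterable of ids. Ids absent from the corpus are counted as warnings; an
    empty intersection is an error.
    """
    if isinstance(doc_id_list, (str, os.PathLike)):
        provenance = provenance or str(doc_id_list)
        with open(doc_id_list, encoding="utf-8") as fh:
            ids = [line.strip() for line in fh if line.strip()]
    else:
        ids = [str(i) for i in doc_id_list]
    if not ids:
        raise UsageError("topic document-id list is empty")
    wanted = set(ids)
    doc_ids = wanted & index.doc_ids
    if not doc_ids:
        raise UsageError("topic list matches no corpus document")
    kb_occ = {}
    for ref, docs in index.occurrences.items():
        hit = docs & doc_ids
        if hit:
            kb_occ[ref] = hit
    return KnowledgeBase(name=name, doc_ids=doc_ids, kb_occurrences=kb_occ,
                         n_docs=len(doc_ids), provenance=provenance,
                         n_unknown_ids=len(wanted - index.doc_ids))


def save_kb(kb: KnowledgeBase, path) -> None:
    payload = {
        "name": kb.name,
        "provenance": kb.provenance,
        "n_unknown_ids": kb.n_unknown_ids,
        "doc_ids": sorted(kb.doc_ids),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_kb(path, index: GlobalIndex) -> KnowledgeBase:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    kb = create_kb(index, payload["doc_ids"], payload["name"],
                   provenance=payload.get("provenance", ""))
    kb.n_unknown_ids = payload.get("n_unknown_ids", kb.n_unknown_ids)
    return kb


def check_kb_against_index(kb: KnowledgeBase, index: GlobalIndex) -> None:
    if not kb.doc_ids <= index.doc_ids:
        raise IntegrityError(
            f"knowledgebase {kb.name!r} contains doc ids outside the index")


def load_doc_ids(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def iter_kb_concept_sets(kb: KnowledgeBase, restrict: set[ConceptRef] | None = None
                         ) -> Iterable[tuple[str, list[ConceptRef]]]:
    """Per KB document, the sorted list of concepts present (optionally
    restricted to a concept subset). Used for co-occurrence counting."""
    per_doc: dict[str, list[ConceptRef]] = {d: [] for d in kb.doc_ids}
    for ref, docs in kb.kb_occurrences.items():
        if restrict is not None and ref not in restrict:
            continue
        for d in docs:
            per_doc[d].append(ref)
    for d in sorted(per_doc):
        yield d, sorted(per_doc[d])
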