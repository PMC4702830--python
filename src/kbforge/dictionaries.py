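"""Controlled vocabularies: loading, normalization, cleaning, validation.

A *dictionary* is a named, categorized vocabulary of *concepts*; each concept
carries one stable identifier, a preferred name and a set of synonym *terms*
(surface strings matchable in text). Vocabularies arrive as TSV in a unified
format, one row per term:

    concept_id  dictionary_name  dictionary_category  preferred_name  term  source_id

Cleaning steps mirror standard text-mining practice: surfaces shared by two
or more concepts *within the same dictionary* are ambiguous and excluded from
matching (the concept stays reachable through its other synonyms); common
English words are removed via a stoplist; terms that hit a large fraction of
the corpus ("promiscuous" terms) are flagged in an advisory report for manual
removal. Sharing a surface *across* dictionaries is allowed — each dictionary
indexes it independently.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError, FormatError

REQUIRED_COLUMNS = (
    "concept_id",
    "dictionary_name",
    "dictionary_category",
    "preferred_name",
    "term",
    "source_id",
)

#: terms at least this long match case-insensitively; shorter surfaces
#: (gene symbols like "ACE") keep their case to avoid false positives
CASEFOLD_MIN_LEN = 4

_WS_RE = re.compile(r"\s+")


def normalize_surface(surface: str) -> str:
    """Canonicalize a surface string for storage and matching.

    Applies Unicode compatibility normalization (NFKC), collapses internal
    whitespace, and drops tokens that contain no alphanumeric character
    (stray punctuation). Returns "" when nothing survives.
    """
    s = unicodedata.normalize("NFKC", surface)
    s = _WS_RE.sub(" ", s).strip()
    tokens = [t for t in s.split(" ") if any(c.isalnum() for c in t)]
    return " ".join(tokens)


def match_key(surface: str) -> str:
    """The string under which a surface competes for matches.

    Case-folded for surfaces of length >= CASEFOLD_MIN_LEN, verbatim for
    shorter ones. Ambiguity detection operates on this key.
    """
    return surface.casefold() if len(surface) >= CASEFOLD_MIN_LEN else surface


@dataclass(frozen=True)
class Term:
    surface: str
    concept_id: str
    dictionary: str


@dataclass
class Concept:
    concept_id: str
    preferred_name: str
    dictionary: str
    category: str
    source_ids: list[str] = field(default_factory=list)
    terms: set[str] = field(default_factory=set)
    unmatchable: bool = False

    def copy(self) -> "Concept":
        return replace(self, source_ids=list(self.source_ids), terms=set(self.terms))


@dataclass
class LoadReport:
    rows: int = 0
    duplicates: int = 0
    row_errors: list[str] = field(default_factory=list)

    @property
    def n_row_errors(self) -> int:
        return len(self.row_errors)


@dataclass
class Dictionary:
    """A named vocabulary plus the audit trail of everything removed from it."""

    name: str
    category: str
    concepts: dict[str, Concept] = field(default_factory=dict)
    excluded_terms: set[tuple[str, str]] = field(default_factory=set)  # (surface, reason)
    normalized: bool = True
    load_report: LoadReport = field(default_factory=LoadReport)

    def copy(self) -> "Dictionary":
        return Dictionary(
            name=self.name,
            category=self.category,
            concepts={cid: c.copy() for cid, c in self.concepts.items()},
            excluded_terms=set(self.excluded_terms),
            normalized=self.normalized,
            load_report=self.load_report,
        )

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_terms(self) -> int:
        return sum(len(c.terms) for c in self.concepts.values())

    def active_terms(self) -> set[str]:
        out: set[str] = set()
        for c in self.concepts.values():
            out |= c.terms
        return out

    def surface_to_concepts(self) -> dict[str, set[str]]:
        """match_key -> set of concept_ids claiming it (for ambiguity scans)."""
        out: dict[str, set[str]] = {}
        for c in self.concepts.values():
            for t in c.terms:
                out.setdefault(match_key(t), set()).add(c.concept_id)
        return out

    def content_hash_items(self) -> list[tuple]:
        items = []
        for cid in sorted(self.concepts):
            c = self.concepts[cid]
            items.append((cid, c.preferred_name, tuple(sorted(c.terms))))
        return items


def load_dictionary(path, name: str | None = None, category: str | None = None) -> Dictionary:
    """Read a dictionary from unified-format TSV.

    The header names the columns, so column order is free. Rows with an empty
    concept_id are collected as row-level errors and skipped; exact duplicate
    (concept_id, term) rows are deduplicated and counted. The preferred name
    is always included among a concept's terms.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty dictionary file") from None
        header = [h.strip() for h in header]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        col = {c: header.index(c) for c in REQUIRED_COLUMNS}

        report = LoadReport()
        concepts: dict[str, Concept] = {}
        seen: set[tuple[str, str]] = set()
        n_data_rows = 0
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            n_data_rows += 1
            report.rows += 1
            if len(row) < len(header):
                row = row + [""] * (len(header) - len(row))
            cid = row[col["concept_id"]].strip()
            if not cid:
                report.row_errors.append(f"line {lineno}: empty concept_id")
                continue
            dict_name = row[col["dictionary_name"]].strip()
            dict_cat = row[col["dictionary_category"]].strip()
            if name is None:
                name = dict_name
            if category is None:
                category = dict_cat
            pref = normalize_surface(row[col["preferred_name"]])
            surface = normalize_surface(row[col["term"]])
            source_id = row[col["source_id"]].strip()
            if not surface:
                report.row_errors.append(f"line {lineno}: empty term after normalization")
                continue
            c = concepts.get(cid)
            if c is None:
                c = Concept(concept_id=cid, preferred_name=pref or surface,
                            dictionary=name, category=category or "")
                concepts[cid] = c
            if source_id and source_id not in c.source_ids:
                c.source_ids.append(source_id)
            key = (cid, surface)
            if key in seen:
                report.duplicates += 1
                continue
            seen.add(key)
            c.terms.add(surface)

        if n_data_rows == 0:
            raise FormatError(f"{path}: dictionary file has a header but no rows")

    for c in concepts.values():
        if c.preferred_name:
            c.terms.add(c.preferred_name)

    return Dictionary(name=name or "", category=category or "", concepts=concepts,
                      load_report=report)


def exclude_ambiguous_terms(dictionary: Dictionary) -> Dictionary:
    """Remove every surface claimed by two or more concepts of this dictionary.

    Exclusions are logged with reason "ambiguous". Concepts whose term set
    empties out are retained (stable identifiers across rebuilds) but flagged
    unmatchable. Pure: returns a new Dictionary. Idempotent.
    """
    out = dictionary.copy()
    shared = {k for k, cids in out.surface_to_concepts().items() if len(cids) >= 2}
    if not shared:
        return out
    for c in out.concepts.values():
        ambiguous = {t for t in c.terms if match_key(t) in shared}
        for t in ambiguous:
            out.excluded_terms.add((t, "ambiguous"))
        c.terms -= ambiguous
        if not c.terms:
            c.unmatchable = True
    return out


def apply_stoplist(dictionary: Dictionary, stoplist) -> Dictionary:
    """Drop terms matching the stoplist case-insensitively (reason "stopword")."""
    stop = {normalize_surface(s).casefold() for s in stoplist}
    stop.discard("")
    out = dictionary.copy()
    if not stop:
        return out
    for c in out.concepts.values():
        hits = {t for t in c.terms if t.casefold() in stop}
        for t in hits:
            out.excluded_terms.add((t, "stopword"))
        c.terms -= hits
        if not c.terms:
            c.unmatchable = True
    return out


def load_stoplist(path) -> set[str]:
    """One term per line, UTF-8, '#' starts a comment line."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.add(line.casefold())
    return out


@dataclass(frozen=True)
class PromiscuityRow:
    surface: str
    doc_frequency: int
    fraction: float
    flagged: bool


def promiscuity_report(dictionary: Dictionary, index, max_doc_fraction: float = 0.01
                       ) -> list[PromiscuityRow]:
    """Corpus document frequency of every active surface, with a flag for
    surfaces hitting more than ``max_doc_fraction`` of documents.

    Advisory only: nothing is removed here. To act on it, feed the flagged
    surfaces back through :func:`apply_stoplist` (the removal step is a
    curation decision).
    """
    if dictionary.name not in index.dictionaries:
        raise ConfigurationError(
            f"index was not built with dictionary {dictionary.name!r}")
    freq = index.term_doc_frequency(dictionary.name)
    rows = []
    n = index.n_docs
    for surface in sorted(dictionary.active_terms()):
        df = freq.get(match_key(surface), 0)
        frac = df / n if n else 0.0
        rows.append(PromiscuityRow(surface, df, frac, frac > max_doc_fraction))
    return rows


def write_exclusion_report(dictionaries: list[Dictionary], path) -> None:
    """TSV of everything removed during cleaning: surface, dictionary, reason."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("surface\tdictionary\treason\n")
        for d in dictionaries:
            for surface, reason in sorted(d.excluded_terms):
                fh.write(f"{surface}\t{d.name}\t{reason}\n")
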