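"""Dictionary-term tagging of document text at the character level.

Every document field (title and abstract, indexed separately) is tokenized
into maximal alphanumeric runs; a term matches a run of consecutive tokens
whose separators consist only of whitespace and hyphens, so "beta-lactamase"
and "beta lactamase" are interchangeable. Matches therefore always respect
token boundaries. Within one dictionary, overlapping candidate matches are
resolved leftmost-longest (the classical Aho–Corasick reporting convention);
candidates from different dictionaries never compete — each dictionary tags
the text independently and overlaps across dictionaries are kept.

Case policy follows :mod:`kbforge.dictionaries`: surfaces of length >= 4
match case-insensitively, shorter surfaces (gene symbols) exactly.

The matcher here scans token positions through a first-token lookup table;
a quadratic brute-force matcher with the same reporting rules serves as its
conformance oracle in the test suite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus import Document
from .dictionaries import CASEFOLD_MIN_LEN, Dictionary
from .errors import IntegrityError

FIELDS = ("title", "abstract")

# maximal alphanumeric runs; underscore is a separator, not a word character
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass(frozen=True)
class MatchSpan:
    doc_id: str
    field: str  # "title" | "abstract"
    start: int  # 0-based character offset into the field text
    end: int    # exclusive
    surface: str  # the exact text slice
    term: str     # the dictionary surface that matched (canonical form)
    concept_id: str
    dictionary: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (FIELDS.index(self.field), self.start, self.end,
                self.dictionary, self.concept_id)


def tokenize(text: str) -> list[tuple[int, int, str]]:
    """(start, end, token_text) for each maximal alphanumeric run."""
    return [(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(text)]


def _term_tokens(surface: str) -> tuple[str, ...]:
    return tuple(_TOKEN_RE.findall(surface))


def _separator_ok(text: str, a: int, b: int) -> bool:
    """Inter-token gap text[a:b] must be whitespace/hyphens only."""
    if b <= a:
        return False
    return all(c.isspace() or c == "-" for c in text[a:b])


class CompiledDictionary:
    """Per-dictionary lookup table: casefolded first token -> candidate terms."""

    def __init__(self, dictionary: Dictionary):
        self.name = dictionary.name
        self.table: dict[str, list[tuple[tuple[str, ...], bool, str, str]]] = {}
        entries = []
        for cid in sorted(dictionary.concepts):
            concept = dictionary.concepts[cid]
            for surface in sorted(concept.terms):
                tokens = _term_tokens(surface)
                if not tokens:
                    continue
                case_sensitive = len(surface) < CASEFOLD_MIN_LEN
                entries.append((tokens, case_sensitive, surface, cid))
        for tokens, cs, surface, cid in entries:
            key = tokens[0].casefold()
            # (compare_tokens, case_sensitive, canonical surface, concept_id)
            cmp_tokens = tokens if cs else tuple(t.casefold() for t in tokens)
            self.table.setdefault(key, []).append((cmp_tokens, cs, surface, cid))


def compile_dictionaries(dictionaries: list[Dictionary]) -> list[CompiledDictionary]:
    return [CompiledDictionary(d) for d in dictionaries]


def _candidates_in_field(text: str, tokens, compiled: CompiledDictionary):
    """All boundary-respecting raw matches of one dictionary in one field."""
    out = []
    n = len(tokens)
    for i, (t_start, t_end, t_text) in enumerate(tokens):
        bucket = compiled.table.get(t_text.casefold())
        if not bucket:
            continue
        for cmp_tokens, cs, surface, cid in bucket:
            k = len(cmp_tokens)
            if i + k > n:
                continue
            ok = True
            prev_end = None
            for j in range(k):
                s, e, txt = tokens[i + j]
                if prev_end is not None and not _separator_ok(text, prev_end, s):
                    ok = False
                    break
                probe = txt if cs else txt.casefold()
                if probe != cmp_tokens[j]:
                    ok = False
                    break
                prev_end = e
            if ok:
                out.append((t_start, tokens[i + k - 1][1], surface, cid))
    return out


def _leftmost_longest(cands):
    """Greedy leftmost-longest selection among overlapping candidates.

    Candidates sharing the same span are collapsed to the lexicographically
    smallest (concept_id, term) for determinism.
    """
    cands = sorted(cands, key=lambda c: (c[0], -(c[1] - c[0]), c[3], c[2]))
    kept = []
    last_end = -1
    for start, end, surface, cid in cands:
        if start >= last_end:
            kept.append((start, end, surface, cid))
            last_end = end
    return kept


def match_document(doc: Document, dictionaries, compiled=None) -> list[MatchSpan]:
    """Tag one document against every dictionary.

    Pass ``compiled`` (from :func:`compile_dictionaries`) to reuse lookup
    tables across documents; otherwise the dictionaries are compiled on the
    fly. Returns spans sorted by (field, start).
    """
    if compiled is None:
        compiled = compile_dictionaries(dictionaries)
    spans: list[MatchSpan] = []
    for fieldname in FIELDS:
        text = doc.field_text(fieldname)
        if not text:
            continue
        tokens = tokenize(text)
        if not tokens:
            continue
        for cd in compiled:
            for start, end, surface, cid in _leftmost_longest(
                    _candidates_in_field(text, tokens, cd)):
                spans.append(MatchSpan(
                    doc_id=doc.doc_id, field=fieldname, start=start, end=end,
                    surface=text[start:end], term=surface, concept_id=cid,
                    dictionary=cd.name))
    spans.sort(key=MatchSpan.sort_key)
    return spans


# --- highlighting -----------------------------------------------------------

_OPEN_RE = re.compile(r"\[\[[^|\[\]]+\|[^|\[\]]+\|")
_CLOSE = "]]"


def highlight_document(doc: Document, spans: list[MatchSpan]) -> dict[str, str]:
    """Inline markup ``[[dictionary|concept_id|<matched text>]]`` per span.

    Returns {"title": ..., "abstract": ...}. Where spans from different
    dictionaries overlap, the longer span nests outside. Stripping the markup
    (:func:`strip_markup`) recovers the original field text exactly.
    """
    out = {}
    for fieldname in FIELDS:
        text = doc.field_text(fieldname)
        field_spans = [s for s in spans if s.field == fieldname]
        for s in field_spans:
            if s.doc_id != doc.doc_id:
                raise IntegrityError(f"span doc_id {s.doc_id!r} != {doc.doc_id!r}")
            if not (0 <= s.start < s.end <= len(text)):
                raise IntegrityError(
                    f"span [{s.start},{s.end}) outside {fieldname} of {doc.doc_id}")
        # insertion events: (position, order, string)
        events = []
        for s in field_spans:
            open_tag = f"[[{s.dictionary}|{s.concept_id}|"
            # at equal positions: closes before opens; longer spans open first
            # (outside) and close last
            events.append((s.start, 1, s.length, s.dictionary, open_tag))
            events.append((s.end, 0, -s.length, s.dictionary, _CLOSE))
        events.sort(key=lambda e: (e[0], e[1], -e[2], e[3]))
        parts = []
        pos = 0
        for p, _, _, _, tag in events:
            parts.append(text[pos:p])
            parts.append(tag)
            pos = p
        parts.append(text[pos:])
        out[fieldname] = "".join(parts)
    return out


def strip_markup(text: str) -> str:
    """Remove highlight markup, recovering the raw text."""
    return _OPEN_RE.sub("", text).replace(_CLOSE, "")
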