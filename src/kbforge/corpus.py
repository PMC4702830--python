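"""MEDLINE-like document corpora: one record per document, title + abstract.

Accepted on disk as TSV (`doc_id  title  abstract`, with header) or JSONL
(one object per line with those keys). Document identifiers must be unique;
empty abstracts are allowed, but a record with neither title nor abstract is
rejected.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

from .errors import FormatError


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract: str

    def field_text(self, fieldname: str) -> str:
        if fieldname == "title":
            return self.title
        if fieldname == "abstract":
            return self.abstract
        raise KeyError(fieldname)


def _finalize(records: list[tuple[str, str, str]], origin) -> list[Document]:
    seen: set[str] = set()
    dups: list[str] = []
    docs: list[Document] = []
    empty: list[str] = []
    for doc_id, title, abstract in records:
        if doc_id in seen:
            dups.append(doc_id)
            continue
        seen.add(doc_id)
        if not title.strip() and not abstract.strip():
            empty.append(doc_id)
            continue
        docs.append(Document(doc_id=doc_id, title=title, abstract=abstract))
    if dups:
        raise FormatError(f"{origin}: duplicate doc_id(s): {', '.join(sorted(set(dups)))}")
    if empty:
        raise FormatError(
            f"{origin}: document(s) with empty title and abstract: {', '.join(empty)}")
    if not docs:
        raise FormatError(f"{origin}: no documents parsed")
    return docs


def load_corpus(path) -> list[Document]:
    """Parse a corpus file, auto-detecting TSV vs JSONL."""
    with open(path, encoding="utf-8") as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == "{":
            return _load_jsonl(fh, path)
        return _load_tsv(fh, path)


def _load_jsonl(fh, origin) -> list[Document]:
    records = []
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{origin}: line {lineno} is not valid JSON: {exc}") from None
        missing = [k for k in ("doc_id", "title", "abstract") if k not in obj]
        if missing:
            raise FormatError(
                f"{origin}: line {lineno} missing key(s): {', '.join(missing)}")
        records.append((str(obj["doc_id"]), str(obj["title"]), str(obj["abstract"])))
    return _finalize(records, origin)


def _load_tsv(fh, origin) -> list[Document]:
    reader = csv.reader(fh, delimiter="\t")
    try:
        header = [h.strip() for h in next(reader)]
    except StopIteration:
        raise FormatError(f"{origin}: empty corpus file") from None
    required = ("doc_id", "title", "abstract")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{origin}: missing required column(s): {', '.join(missing)}")
    col = {c: header.index(c) for c in required}
    records = []
    for row in reader:
        if not row or all(not f.strip() for f in row):
            continue
        if len(row) < len(header):
            row = row + [""] * (len(header) - len(row))
        records.append((row[col["doc_id"]].strip(), row[col["title"]], row[col["abstract"]]))
    return _finalize(records, origin)


def write_corpus(docs: list[Document], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("doc_id\ttitle\tabstract\n")
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")
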