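"""Independent reference implementations used only by the test suite.

Deliberately naive: quadratic all-position regex matching, exact rational
combinatorics, cubic triple enumeration. They share no code with the package
paths they check.
"""

from __future__ import annotations

import itertools
import re
from fractions import Fraction
from math import comb

# --- quadratic brute-force matcher -----------------------------------------

_WORD = r"[^\W_]"


def _term_pattern(surface: str, case_sensitive: bool) -> re.Pattern:
    tokens = re.findall(r"[^\W_]+", surface)
    body = r"[\s\-]+".join(re.escape(t) for t in tokens)
    pattern = rf"(?<!{_WORD}){body}(?!{_WORD})"
    flags = 0 if case_sensitive else re.IGNORECASE
    return re.compile(pattern, flags)


def brute_force_candidates(text: str, dictionary):
    """Every (start, end, term, concept_id) at every character position."""
    out = []
    for cid in sorted(dictionary.concepts):
        concept = dictionary.concepts[cid]
        for surface in sorted(concept.terms):
            if not re.findall(r"[^\W_]+", surface):
                continue
            pat = _term_pattern(surface, case_sensitive=len(surface) < 4)
            for pos in range(len(text) + 1):
                m = pat.match(text, pos)
                if m and m.end() > m.start():
                    out.append((m.start(), m.end(), surface, cid))
    return sorted(set(out))


def leftmost_longest_select(candidates):
    """Pick leftmost candidate, prefer longer, tie-break (concept_id, term);
    discard everything overlapping the pick; repeat."""
    remaining = sorted(set(candidates))
    kept = []
    while remaining:
        best = min(remaining, key=lambda c: (c[0], -(c[1] - c[0]), c[3], c[2]))
        kept.append(best)
        remaining = [c for c in remaining if c[1] <= best[0] or c[0] >= best[1]]
    return sorted(kept)


def brute_force_match_field(text: str, dictionary):
    """(start, end, term, concept_id) matches of one dictionary in one field."""
    return leftmost_longest_select(brute_force_candidates(text, dictionary))


# --- exact hypergeometric tail ----------------------------------------------

def hypergeom_sf_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational via the combinatorial closed form."""
    if k <= 0:
        return Fraction(1)
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def hypergeom_sf_by_draws(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by literally enumerating all C(N, n) draws (tiny N only)."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x in marked) >= k:
            hits += 1
    return Fraction(hits, total)


# --- cubic ABC enumeration --------------------------------------------------

def swanson_brute_force(nodes, edges, cooccur):
    """All (a, c) hypothesis pairs by triple enumeration.

    ``edges``: set of frozenset node pairs with a significant association;
    ``cooccur(a, c)``: direct document co-occurrence count. Returns
    {sorted (a, c): set of bridges}.
    """
    nodes = sorted(nodes)
    out = {}
    for a, c in itertools.combinations(nodes, 2):
        if frozenset((a, c)) in edges:
            continue
        if cooccur(a, c) > 0:
            continue
        bridges = {b for b in nodes
                   if b not in (a, c)
                   and frozenset((a, b)) in edges
                   and frozenset((b, c)) in edges}
        if bridges:
            out[(a, c)] = bridges
    return out
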