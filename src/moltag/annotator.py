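"""Document model, sentence scoping, and free-text dictionary matching.

A document is a title plus an abstract.  Matching runs over one of three
scopes — the title only; the title plus the first and last sentences of the
abstract (objectives tend to sit in the first sentence, conclusions in the
last); or the title plus the full abstract.  Every word-boundary-anchored
dictionary hit inside the scoped regions becomes a candidate
:class:`Mention`; overlaps are resolved longest-match-first, then left-most.

Matching is always performed sentence-by-sentence (the title counts as one
region), so no mention crosses a region boundary and the narrower scopes
yield exact subsets of the wider ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Sequence

from .vocabulary import ChemicalDictionary, normalize_name

__all__ = [
    "Document",
    "Scope",
    "Mention",
    "split_sentences",
    "match_terms",
    "find_name_occurrences",
    "scope_monotonicity_check",
    "context_tokens",
]

DEFAULT_ABBREVIATIONS = (
    "e.g.",
    "i.e.",
    "cf.",
    "vs.",
    "ca.",
    "et al.",
    "al.",
    "Fig.",
    "approx.",
)


@dataclass(frozen=True)
class Document:
    """One corpus record: an identifier, a title and an abstract.

    ``gold_concepts`` holds the manually indexed concept ids when available
    (training and evaluation need them; plain annotation does not).
    """

    doc_id: str
    title: str
    abstract: str
    gold_concepts: frozenset[str] | None = None

    def validate(self) -> "Document":
        if not self.title.strip() or not self.abstract.strip():
            raise ValueError(
                f"document {self.doc_id!r}: title and abstract must be non-empty"
            )
        return self


class Scope(Enum):
    """Which text regions are scanned for chemical names."""

    TITLE_ONLY = "title"
    TITLE_FIRST_LAST = "title-fl"
    FULL = "full"

    @classmethod
    def parse(cls, value: "str | Scope") -> "Scope":
        if isinstance(value, Scope):
            return value
        for member in cls:
            if member.value == value or member.name.lower() == value.lower():
                return member
        raise ValueError(
            f"unknown scope {value!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


@dataclass
class Mention:
    """One dictionary match in a document.

    Offsets are 0-based half-open Unicode codepoint positions within the
    containing field (the title or the abstract); ``surface`` always equals
    that field's slice ``[start, end)``.  ``concept_ids`` keeps every
    concept sharing the matched name — ambiguity is preserved.
    ``filter_flags`` records which cascade stage rejected the mention, and
    under which rule.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    concept_ids: frozenset[str]
    region: str  # title | first_sentence | last_sentence | body
    field_name: str = "abstract"  # title | abstract
    sentence_start: int = 0
    sentence_end: int = 0
    sentence_text: str = ""
    filter_flags: list[tuple[str, str]] = field(default_factory=list)
    status: str = "kept"

    @property
    def rejected(self) -> bool:
        return self.status != "kept"

    def reject(self, stage: str, rule: str) -> None:
        self.filter_flags.append((stage, rule))
        if not self.rejected:
            self.status = f"filtered:{stage}"

    def key(self) -> tuple:
        """Identity of the match, independent of filter state."""
        return (
            self.doc_id,
            self.field_name,
            self.start,
            self.end,
            tuple(sorted(self.concept_ids)),
        )


# -- sentence segmentation ---------------------------------------------------

_TERMINAL_RE = re.compile(r"[.?!]+")


def split_sentences(
    text: str,
    *,
    abbreviation_aware: bool = True,
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> list[tuple[int, int]]:
    """Split an abstract into ordered, non-overlapping sentence spans.

    A sentence ends at a run of terminal punctuation ([.?!]) followed by
    whitespace.  With ``abbreviation_aware`` (the default) the break
    additionally requires the next non-space character to be an uppercase
    letter or a digit, and is suppressed after a listed abbreviation; with
    it off, every terminal-punctuation-plus-whitespace position breaks.
    Spans are trimmed of surrounding whitespace and cover all non-whitespace
    text; the first and last span define the FT/LT scoping regions.
    """
    spans: list[tuple[int, int]] = []
    abbrevs = tuple(a.lower() for a in abbreviations) if abbreviation_aware else ()
    start = 0
    pos = 0
    n = len(text)
    for match in _TERMINAL_RE.finditer(text):
        end = match.end()
        if end >= n or not text[end].isspace():
            continue
        if abbreviation_aware:
            nxt = end
            while nxt < n and text[nxt].isspace():
                nxt += 1
            if nxt < n and not (text[nxt].isupper() or text[nxt].isdigit()):
                continue
            prefix = text[:end].lower()
            if any(prefix.endswith(a) for a in abbrevs):
                continue
        if end > pos:
            spans.append((start, end))
            start = end
            pos = end
    if start < n and text[start:].strip():
        spans.append((start, n))
    # trim whitespace off each span
    trimmed: list[tuple[int, int]] = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            trimmed.append((s, e))
    return trimmed


# -- matching ----------------------------------------------------------------


def _is_boundary_char(ch: str | None) -> bool:
    # a hyphen is not alphanumeric, so hyphen-joined fragments expose their
    # inner dictionary terms to matching (they are then judged by the
    # token-context rules rather than silently unmatched)
    return ch is None or not ch.isalnum()


@lru_cache(maxsize=65536)
def _key_pattern(key: str, case_sensitive: bool) -> "re.Pattern[str]":
    # internal whitespace in a normalized name matches any whitespace run
    pattern = r"\s+".join(re.escape(part) for part in key.split(" "))
    return re.compile(pattern, 0 if case_sensitive else re.IGNORECASE)


def _find_key_spans(
    text: str, key: str, *, case_sensitive: bool
) -> Iterable[tuple[int, int]]:
    rx = _key_pattern(key, case_sensitive)
    pos = 0
    while True:
        m = rx.search(text, pos)
        if m is None:
            break
        s, e = m.span()
        before = text[s - 1] if s > 0 else None
        after = text[e] if e < len(text) else None
        if _is_boundary_char(before) and _is_boundary_char(after):
            yield s, e
        pos = s + 1


def _candidates(text: str, dictionary: ChemicalDictionary) -> list[tuple[int, int, frozenset[str]]]:
    found: dict[tuple[int, int], set[str]] = {}
    for key, ids in dictionary.case_insensitive_index.items():
        for span in _find_key_spans(text, key, case_sensitive=False):
            found.setdefault(span, set()).update(ids)
    for key, ids in dictionary.case_sensitive_index.items():
        for span in _find_key_spans(text, key, case_sensitive=True):
            found.setdefault(span, set()).update(ids)
    return [(s, e, frozenset(ids)) for (s, e), ids in found.items()]


def resolve_overlaps(
    candidates: list[tuple[int, int, frozenset[str]]],
) -> list[tuple[int, int, frozenset[str]]]:
    """Longest match wins; ties go left-most, then to the lexicographically
    smallest concept-id set (for determinism)."""
    ordered = sorted(
        candidates, key=lambda c: (-(c[1] - c[0]), c[0], tuple(sorted(c[2])))
    )
    taken: list[tuple[int, int, frozenset[str]]] = []
    for cand in ordered:
        if all(cand[1] <= t[0] or cand[0] >= t[1] for t in taken):
            taken.append(cand)
    return sorted(taken, key=lambda c: c[0])


def _regions(document: Document, scope: Scope) -> list[tuple[str, str, int, int]]:
    """(field_name, region_label, start, end) of each scanned sentence."""
    regions = [("title", "title", 0, len(document.title))]
    if scope is Scope.TITLE_ONLY:
        return regions
    spans = split_sentences(document.abstract)
    if not spans:
        return regions
    last = len(spans) - 1
    for i, (s, e) in enumerate(spans):
        if i == 0:
            label = "first_sentence"
        elif i == last:
            label = "last_sentence"
        else:
            label = "body"
        if scope is Scope.TITLE_FIRST_LAST and label == "body":
            continue
        regions.append(("abstract", label, s, e))
    return regions


def match_terms(
    document: Document,
    dictionary: ChemicalDictionary,
    scope: Scope | str = Scope.FULL,
) -> list[Mention]:
    """Free-text dictionary matching over the scoped regions of a document.

    Returns every word-boundary-anchored match, longest-first non-overlapping,
    each carrying all concept ids that share the matched name.  Output order
    is title first, then abstract sentences, left to right; identical inputs
    yield identical mention lists.
    """
    scope = Scope.parse(scope)
    mentions: list[Mention] = []
    for field_name, label, s, e in _regions(document, scope):
        source = document.title if field_name == "title" else document.abstract
        segment = source[s:e]
        for rs, re_, ids in resolve_overlaps(_candidates(segment, dictionary)):
            mentions.append(
                Mention(
                    doc_id=document.doc_id,
                    start=s + rs,
                    end=s + re_,
                    surface=segment[rs:re_],
                    concept_ids=ids,
                    region=label,
                    field_name=field_name,
                    sentence_start=s,
                    sentence_end=e,
                    sentence_text=segment,
                )
            )
    return mentions


def find_name_occurrences(text: str, names: Iterable[str]) -> list[tuple[int, int]]:
    """Word-boundary occurrences of any of ``names`` in ``text``.

    Uses the same boundary and longest-match semantics as the dictionary
    matcher (short names match case-sensitively).  Used for the negative
    protein/gene vocabulary.
    """
    from .vocabulary import CASE_SENSITIVE_MAX_LEN

    spans: set[tuple[int, int]] = set()
    for name in names:
        norm = normalize_name(name)
        if not norm:
            continue
        cs = len(norm) <= CASE_SENSITIVE_MAX_LEN
        spans.update(_find_key_spans(text, norm, case_sensitive=cs))
    resolved = resolve_overlaps([(s, e, frozenset(("x",))) for s, e in spans])
    return [(s, e) for s, e, _ in resolved]


def scope_monotonicity_check(
    document: Document, dictionary: ChemicalDictionary
) -> bool:
    """True iff mention multisets are nested TITLE ⊆ TITLE_FIRST_LAST ⊆ FULL."""
    from collections import Counter

    def keys(scope: Scope) -> Counter:
        return Counter(m.key() for m in match_terms(document, dictionary, scope))

    title = keys(Scope.TITLE_ONLY)
    fl = keys(Scope.TITLE_FIRST_LAST)
    full = keys(Scope.FULL)
    return title <= fl <= full


# -- filter context ----------------------------------------------------------

_CONTEXT_SPLIT_RE = re.compile(r"[\s,;()\[\]/\-]+")
_STRIP_EDGE_RE = re.compile(r"^[\W_]+|[\W_]+$")


def _tokenize_context(text: str) -> list[str]:
    out = []
    for raw in _CONTEXT_SPLIT_RE.split(text):
        tok = _STRIP_EDGE_RE.sub("", raw)
        if tok:  # skip punctuation-only tokens
            out.append(tok)
    return out


def context_tokens(mention: Mention, window: int = 2) -> tuple[list[str], list[str]]:
    """Up to ``window`` word tokens before and after a mention, within its
    sentence.  Hyphen- and parenthesis-joined fragments count as tokens;
    punctuation-only fragments are skipped."""
    rel_start = mention.start - mention.sentence_start
    rel_end = mention.end - mention.sentence_start
    before = _tokenize_context(mention.sentence_text[:rel_start])
    after = _tokenize_context(mention.sentence_text[rel_end:])
    return before[-window:] if window else [], after[:window] if window else []
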