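"""Per-concept true-positive ratio estimation.

Some vocabulary terms ("lead", "water", homonyms of common English words,
short acronyms) match text constantly but are rarely what an indexer would
annotate.  The *TP ratio* of a concept quantifies this propensity from a
gold-annotated training corpus:

    ratio = C / A

where A is the number of training abstracts containing a free-text match of
the concept (binary per document: multiple occurrences still count once)
and C is the number of those abstracts whose manual annotations endorse the
concept — directly or at an ancestor level, under the same relative-node
expansion used for evaluation.  Concepts never matched in text (A = 0)
have no ratio and are absent from the table.

The ratio feeds the tunable TP-ratio filter stage: at threshold t, matches
whose every candidate concept has ratio < t are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .annotator import Document, Scope, match_terms
from .vocabulary import ChemicalDictionary

__all__ = [
    "RatioEntry",
    "RatioTable",
    "tp_ratio",
    "estimate_ratios",
    "round_sig_figs",
]


def tp_ratio(A: int, C: int) -> float:
    """The ratio C/A; undefined (an error) when A = 0."""
    if A < 1:
        raise ValueError(f"ratio undefined for A={A} (no free-text matches)")
    if not 0 <= C <= A:
        raise ValueError(f"invariant 0 <= C <= A violated: A={A}, C={C}")
    return C / A


def round_sig_figs(x: float, figures: int = 2) -> float:
    """Round to a number of significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + figures - 1)


@dataclass(frozen=True)
class RatioEntry:
    """Training counts for one concept; ratio = C/A exactly."""

    concept_id: str
    A: int
    C: int

    def __post_init__(self) -> None:
        tp_ratio(self.A, self.C)  # validates A >= 1 and 0 <= C <= A

    @property
    def ratio(self) -> float:
        return tp_ratio(self.A, self.C)


@dataclass
class RatioTable:
    """concept_id -> RatioEntry; concepts with A = 0 are never stored."""

    entries: dict[str, RatioEntry] = field(default_factory=dict)
    training_doc_count: int = 0

    def get(self, concept_id: str) -> RatioEntry | None:
        return self.entries.get(concept_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RatioEntry]:
        return iter(self.entries.values())

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.entries

    # -- TSV round trip ------------------------------------------------------

    HEADER = ("concept_id", "A", "C", "ratio")

    def write_tsv(self, path: str | Path) -> None:
        """concept_id, A, C, ratio (full precision; A and C round-trip)."""
        lines = ["\t".join(self.HEADER)]
        for cid in sorted(self.entries):
            e = self.entries[cid]
            lines.append(f"{cid}\t{e.A}\t{e.C}\t{e.ratio!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RatioTable":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or tuple(lines[0].split("\t")) != cls.HEADER:
            raise ValueError(f"{path}: not a ratio table (bad header)")
        table = cls()
        for line in lines[1:]:
            if not line.strip():
                continue
            cid, a, c, _ratio = line.split("\t")
            table.entries[cid] = RatioEntry(concept_id=cid, A=int(a), C=int(c))
        return table


def _gold_credits(
    concept_id: str,
    gold: frozenset[str],
    expansions: Mapping[str, frozenset[str]],
) -> bool:
    return bool(expansions[concept_id] & gold)


def estimate_ratios(
    corpus: Iterable[Document],
    dictionary: ChemicalDictionary,
    *,
    scope: Scope | str = Scope.FULL,
) -> RatioTable:
    """Estimate TP ratios from a gold-annotated corpus.

    Per concept, A counts documents with at least one unfiltered free-text
    match (per-document binary) and C counts the subset whose gold
    annotations credit the concept under relative-node expansion.  Every
    document must carry gold annotations.  The estimate is invariant to
    document order and to duplicate mentions within a document.
    """
    from .evaluation import expand_relative_nodes

    scope = Scope.parse(scope)
    A: dict[str, int] = {}
    C: dict[str, int] = {}
    expansions: dict[str, frozenset[str]] = {}
    n_docs = 0
    for doc in corpus:
        if doc.gold_concepts is None:
            raise ValueError(
                f"document {doc.doc_id!r} has no gold annotations; "
                "cannot estimate TP ratios"
            )
        n_docs += 1
        matched: set[str] = set()
        for mention in match_terms(doc, dictionary, scope):
            matched.update(mention.concept_ids)
        for cid in matched:
            if cid not in expansions:
                expansions[cid] = expand_relative_nodes(cid, dictionary)
            A[cid] = A.get(cid, 0) + 1
            if _gold_credits(cid, doc.gold_concepts, expansions):
                C[cid] = C.get(cid, 0) + 1
    table = RatioTable(training_doc_count=n_docs)
    for cid in sorted(A):
        table.entries[cid] = RatioEntry(concept_id=cid, A=A[cid], C=C.get(cid, 0))
    return table
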