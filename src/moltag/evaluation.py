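"""Hierarchy-aware comparison of system annotations against gold annotations.

Human indexers often annotate a *more general* concept than the one named
in the text — "Penicillins" where the abstract says "Penicillin G".  A
prediction is therefore credited (TP) when its *relative-node expansion* —
the concept itself, every ancestor along its tree numbers, and, for
substance records, each mapped heading plus that heading's ancestors —
intersects the document's gold set.  Credit runs in that direction only: a
gold concept more specific than the prediction earns nothing.

False negatives are split by textual presence: a missed gold concept that
had a pre-filter free-text match (directly or via a descendant) is
"in text, not found"; otherwise it is "not in text" (typically mentioned
only in the paper's body, which the annotator never sees) — an upper bound
on true absence, since a term may also be missed for spelling or synonymy
reasons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotator import Document, Scope, match_terms
from .filters import FilterConfig, apply_cascade
from .vocabulary import (
    ChemicalDictionary,
    TokenDictionary,
    apply_structure_filter,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "expand_relative_nodes",
    "compare",
    "precision",
    "recall",
    "f_measure",
    "evaluate_corpus",
    "write_metrics_tsv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-corpus TP/FP/FN, with FN split by textual presence."""

    tp: int = 0
    fp: int = 0
    fn_in_text: int = 0
    fn_not_in_text: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn_in_text, self.fn_not_in_text) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def fn_total(self) -> int:
        return self.fn_in_text + self.fn_not_in_text

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn_in_text=self.fn_in_text + other.fn_in_text,
            fn_not_in_text=self.fn_not_in_text + other.fn_not_in_text,
        )


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn_total
    return counts.tp / denom if denom else 0.0


def f_measure(p: float, r: float) -> float:
    """Harmonic mean 2pr/(p+r); 0 when p + r = 0."""
    return 2 * p * r / (p + r) if p + r else 0.0


def expand_relative_nodes(
    concept_id: str,
    dictionary: ChemicalDictionary,
    _seen: set[str] | None = None,
) -> frozenset[str]:
    """The concept itself, its ancestors along every tree number (ancestors
    are tree-number prefixes), and, for substances, each mapped heading plus
    that heading's ancestors."""
    entry = dictionary.concept(concept_id)  # KeyError on unknown concept
    seen = _seen if _seen is not None else set()
    if concept_id in seen:
        return frozenset()
    seen.add(concept_id)
    out = {concept_id}
    for tn in entry.tree_numbers:
        parts = tn.split(".")
        for k in range(1, len(parts)):
            ancestor = dictionary.concept_for_tree_number(".".join(parts[:k]))
            if ancestor is not None:
                out.add(ancestor)
    for mid in entry.mapped_concept_ids:
        out.add(mid)
        if mid in dictionary:
            out |= expand_relative_nodes(mid, dictionary, _seen=seen)
    return frozenset(out)


def _expansion(
    concept_id: str,
    dictionary: ChemicalDictionary,
    cache: dict[str, frozenset[str]],
) -> frozenset[str]:
    if concept_id not in cache:
        if concept_id in dictionary:
            cache[concept_id] = expand_relative_nodes(concept_id, dictionary)
        else:
            # a concept outside the dictionary expands to itself only
            cache[concept_id] = frozenset({concept_id})
    return cache[concept_id]


def compare(
    predicted: Mapping[str, Iterable[str]],
    gold: Mapping[str, Iterable[str]],
    matched_in_text: Mapping[str, Iterable[str]],
    dictionary: ChemicalDictionary,
) -> ConfusionCounts:
    """Count TP/FP/FN over per-document concept sets with relative-node credit.

    ``predicted``, ``gold`` and ``matched_in_text`` map doc_id -> concept
    ids (``matched_in_text`` holds the *pre-filter* free-text matches, used
    only to split the false negatives).  Per document: a predicted concept
    is TP when its expansion intersects the gold set, else FP — with the
    proviso that a prediction whose expansion only reaches already-credited
    gold concepts is deduplicated, not double-counted; TP is counted per
    covered gold concept, FN per uncovered one.
    """
    cache: dict[str, frozenset[str]] = {}
    tp = fp = fn_in = fn_out = 0
    for doc_id in sorted(set(predicted) | set(gold)):
        pred = set(predicted.get(doc_id, ()))
        gold_set = set(gold.get(doc_id, ()))
        matched = set(matched_in_text.get(doc_id, ()))
        covered: set[str] = set()
        for p in pred:
            exp = _expansion(p, dictionary, cache)
            hits = exp & gold_set
            if hits:
                covered |= hits
            else:
                fp += 1
        tp += len(covered)
        for g in gold_set - covered:
            reachable = any(
                g in _expansion(m, dictionary, cache) for m in matched
            )
            if reachable:
                fn_in += 1
            else:
                fn_out += 1
    return ConfusionCounts(tp=tp, fp=fp, fn_in_text=fn_in, fn_not_in_text=fn_out)


@dataclass(frozen=True)
class MetricsReport:
    """Precision/recall/F for one scope + filter configuration."""

    scope: Scope
    filter_config: FilterConfig
    counts: ConfusionCounts
    label: str = ""

    @property
    def precision(self) -> float:
        return precision(self.counts)

    @property
    def recall(self) -> float:
        return recall(self.counts)

    @property
    def f_measure(self) -> float:
        return f_measure(self.precision, self.recall)


def predict_concepts(
    corpus: Sequence[Document],
    dictionary: ChemicalDictionary,
    *,
    scope: Scope | str = Scope.FULL,
    config: FilterConfig = FilterConfig(),
    tokens: TokenDictionary | None = None,
    negative_names: Iterable[str] = (),
    ratios=None,
) -> dict[str, set[str]]:
    """Run matching plus the cascade; doc_id -> kept concept ids."""
    scope = Scope.parse(scope)
    working = (
        apply_structure_filter(dictionary)
        if config.enable_structure_filter
        else dictionary
    )
    negative = list(negative_names)
    out: dict[str, set[str]] = {}
    for doc in corpus:
        mentions = match_terms(doc, working, scope)
        result = apply_cascade(
            mentions,
            tokens=tokens,
            negative_names=negative,
            ratios=ratios,
            config=config,
        )
        out[doc.doc_id] = set().union(
            *(m.concept_ids for m in result.kept)
        ) if result.kept else set()
    return out


def evaluate_corpus(
    corpus: Sequence[Document],
    dictionary: ChemicalDictionary,
    configs: Sequence[tuple[FilterConfig, Scope | str]],
    *,
    tokens: TokenDictionary | None = None,
    negative_names: Iterable[str] = (),
    ratios=None,
    labels: Sequence[str] | None = None,
) -> list[MetricsReport]:
    """One MetricsReport per (filter configuration, scope).

    The FN split uses pre-filter, full-scope matches against the unfiltered
    input dictionary: "in text" means the term's string is present in the
    title or abstract at all, regardless of the configuration under test.
    Deterministic given corpus and configs.
    """
    corpus = [doc.validate() for doc in corpus]
    gold: dict[str, set[str]] = {}
    matched: dict[str, set[str]] = {}
    for doc in corpus:
        if doc.gold_concepts is None:
            raise ValueError(f"document {doc.doc_id!r} has no gold annotations")
        gold[doc.doc_id] = set(doc.gold_concepts)
        matched[doc.doc_id] = set().union(
            *(m.concept_ids for m in match_terms(doc, dictionary, Scope.FULL)),
            set(),
        )
    negative = list(negative_names)
    reports = []
    for i, (config, scope) in enumerate(configs):
        scope = Scope.parse(scope)
        predicted = predict_concepts(
            corpus,
            dictionary,
            scope=scope,
            config=config,
            tokens=tokens,
            negative_names=negative,
            ratios=ratios,
        )
        counts = compare(predicted, gold, matched, dictionary)
        label = labels[i] if labels else f"config{i}"
        reports.append(
            MetricsReport(scope=scope, filter_config=config, counts=counts, label=label)
        )
    return reports


def write_metrics_tsv(reports: Sequence[MetricsReport], path: str | Path) -> None:
    header = (
        "label\tscope\tstructure_filter\ttoken_rules\tnegative_vocab\t"
        "tp_threshold\ttp\tfp\tfn_in_text\tfn_not_in_text\t"
        "precision\trecall\tf_measure"
    )
    lines = [header]
    for r in reports:
        c, fc = r.counts, r.filter_config
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    r.label,
                    r.scope.value,
                    int(fc.enable_structure_filter),
                    int(fc.enable_token_rules),
                    int(fc.enable_negative_vocab),
                    f"{fc.tp_threshold:g}",
                    c.tp,
                    c.fp,
                    c.fn_in_text,
                    c.fn_not_in_text,
                    f"{r.precision:.3f}",
                    f"{r.recall:.3f}",
                    f"{r.f_measure:.3f}",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
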