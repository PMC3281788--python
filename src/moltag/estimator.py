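"""scikit-learn-style estimator wrapping the full annotation pipeline.

``ChemicalTagger`` is the package's high-level interface: construct it with
a chemical dictionary and filter settings, ``fit`` it on a gold-annotated
corpus (which trains the per-concept TP-ratio table), then ``predict`` the
kept concept ids for new documents or ``annotate`` them for full mention
audit trails.  It follows the scikit-learn estimator contract
(``get_params``/``set_params``, fitted attributes with a trailing
underscore, validation at fit time), so it composes with ``clone`` and
grid-search over ``tp_threshold`` or ``scope``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .annotator import Document, Mention, Scope, match_terms
from .evaluation import (
    compare,
    f_measure,
    precision,
    recall,
)
from .filters import FilterConfig, RuleConfig, apply_cascade
from .training import RatioTable, estimate_ratios
from .vocabulary import (
    ChemicalDictionary,
    TokenDictionary,
    apply_structure_filter,
    build_token_dictionary,
)

__all__ = ["ChemicalTagger"]


class ChemicalTagger(BaseEstimator):
    """Dictionary-based chemical annotator with a trainable TP-ratio filter.

    Parameters
    ----------
    dictionary:
        The chemical vocabulary to match against.
    token_dictionary:
        Chemical tokens for the name-decision rules; built from the
        dictionary's own names (with ``stoplist``) when omitted.
    negative_vocabulary:
        Protein/gene names whose occurrences suppress embedded matches.
    scope:
        ``"title"``, ``"title-fl"`` or ``"full"`` — which document regions
        are scanned.
    structure_filter, token_rules, negative_vocab:
        Enable the corresponding cascade stages.
    tp_threshold:
        Drop matches whose trained TP ratio is below this value; must lie
        in [0, 0.5).  0 disables the stage.
    rule_config:
        Name-decision rule settings (context window, affix rules).
    stoplist:
        Common words excluded from the token dictionary when it is built
        internally.

    Attributes
    ----------
    ratio_table_ : RatioTable
        Per-concept TP ratios estimated by ``fit``.
    working_dictionary_ : ChemicalDictionary
        The dictionary actually matched against (structure-filtered when
        enabled).
    token_dictionary_ : TokenDictionary
        The token dictionary in effect.
    """

    def __init__(
        self,
        dictionary: ChemicalDictionary | None = None,
        *,
        token_dictionary: TokenDictionary | None = None,
        negative_vocabulary: Sequence[str] = (),
        scope: str | Scope = "full",
        structure_filter: bool = True,
        token_rules: bool = True,
        negative_vocab: bool = True,
        tp_threshold: float = 0.0,
        rule_config: RuleConfig | None = None,
        stoplist: Sequence[str] = (),
    ):
        self.dictionary = dictionary
        self.token_dictionary = token_dictionary
        self.negative_vocabulary = negative_vocabulary
        self.scope = scope
        self.structure_filter = structure_filter
        self.token_rules = token_rules
        self.negative_vocab = negative_vocab
        self.tp_threshold = tp_threshold
        self.rule_config = rule_config
        self.stoplist = stoplist

    # -- sklearn plumbing ----------------------------------------------------

    def _filter_config(self) -> FilterConfig:
        return FilterConfig(
            enable_structure_filter=self.structure_filter,
            enable_token_rules=self.token_rules,
            enable_negative_vocab=self.negative_vocab,
            enable_tp_ratio=self.tp_threshold > 0,
            tp_threshold=self.tp_threshold,
            rule_config=self.rule_config or RuleConfig(),
        )

    def _check_is_fitted(self) -> None:
        if not hasattr(self, "ratio_table_"):
            raise RuntimeError(
                "this ChemicalTagger instance is not fitted yet; "
                "call fit before predict/annotate"
            )

    @staticmethod
    def _as_documents(
        X: Iterable[Document], y: Sequence[Iterable[str]] | None
    ) -> list[Document]:
        docs = list(X)
        if y is not None:
            if len(y) != len(docs):
                raise ValueError("X and y have inconsistent lengths")
            docs = [
                Document(
                    doc_id=d.doc_id,
                    title=d.title,
                    abstract=d.abstract,
                    gold_concepts=frozenset(labels),
                )
                for d, labels in zip(docs, y)
            ]
        return docs

    # -- estimator API -------------------------------------------------------

    def fit(self, X: Iterable[Document], y: Sequence[Iterable[str]] | None = None):
        """Prepare the working dictionary and estimate the TP-ratio table.

        ``X`` is a sequence of :class:`Document`; gold concept sets come
        from ``y`` or from ``Document.gold_concepts``.  A corpus without
        gold annotations is accepted only when the TP-ratio stage is off
        (threshold 0), in which case the fitted table is empty.
        """
        if self.dictionary is None or len(self.dictionary) == 0:
            raise ValueError("a non-empty dictionary is required")
        config = self._filter_config()  # validates tp_threshold
        docs = [d.validate() for d in self._as_documents(X, y)]
        self.working_dictionary_ = (
            apply_structure_filter(self.dictionary)
            if self.structure_filter
            else self.dictionary
        )
        self.token_dictionary_ = self.token_dictionary or build_token_dictionary(
            self.dictionary.all_names(), self.stoplist
        )
        have_gold = all(d.gold_concepts is not None for d in docs) and docs
        if have_gold:
            self.ratio_table_ = estimate_ratios(
                docs, self.working_dictionary_, scope=Scope.FULL
            )
        elif config.enable_tp_ratio:
            raise ValueError(
                "tp_threshold > 0 requires gold annotations at fit time"
            )
        else:
            self.ratio_table_ = RatioTable()
        self.n_training_documents_ = len(docs)
        return self

    def annotate(self, X: Iterable[Document]) -> list[list[Mention]]:
        """All mentions per document, kept and filtered, with audit flags."""
        self._check_is_fitted()
        config = self._filter_config()
        out = []
        for doc in X:
            mentions = match_terms(doc, self.working_dictionary_, self.scope)
            apply_cascade(
                mentions,
                tokens=self.token_dictionary_,
                negative_names=self.negative_vocabulary,
                ratios=self.ratio_table_,
                config=config,
            )
            out.append(mentions)
        return out

    def predict(self, X: Iterable[Document]) -> list[set[str]]:
        """Kept concept-id set per document."""
        return [
            set().union(*(m.concept_ids for m in doc_mentions if not m.rejected))
            if any(not m.rejected for m in doc_mentions)
            else set()
            for doc_mentions in self.annotate(X)
        ]

    def score(self, X: Iterable[Document], y: Sequence[Iterable[str]] | None = None) -> float:
        """F-measure against gold annotations with relative-node credit."""
        self._check_is_fitted()
        docs = self._as_documents(X, y)
        if any(d.gold_concepts is None for d in docs):
            raise ValueError("scoring requires gold annotations")
        predicted = {
            d.doc_id: p for d, p in zip(docs, self.predict(docs))
        }
        gold = {d.doc_id: set(d.gold_concepts or ()) for d in docs}
        matched = {
            d.doc_id: set().union(
                *(m.concept_ids for m in match_terms(d, self.dictionary, Scope.FULL)),
                set(),
            )
            for d in docs
        }
        counts = compare(predicted, gold, matched, self.dictionary)
        return f_measure(precision(counts), recall(counts))
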