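"""False-positive filter cascade for candidate mentions.

Free-text matching of a chemical vocabulary is precise about *strings* but
not about *topics*: most raw matches are fragments of longer entity names
(protein names embed chemical names) or chemically non-specific common
words.  The cascade removes such matches in three mention-level stages,
applied cumulatively:

1. **tokens and rules** — a match flanked by chemical tokens is a substring
   of a longer chemical name (context rules 1–3); a match preceded by
   "poly" or followed by a word ending in "ase" (except "release"/"base")
   is a polymer or an enzyme name, not the chemical itself;
2. **protein/gene negative vocabulary** — a match lying inside an
   occurrence of a known protein or gene name is suppressed;
3. **TP-ratio threshold** — terms whose trained true-positive ratio falls
   below a tunable threshold are dropped (see :mod:`moltag.training`).

A fourth, dictionary-level stage — restriction to structure-mapped
concepts — acts before matching (:func:`moltag.vocabulary.apply_structure_filter`).

Every rejection is recorded on the mention (stage + rule id), so the audit
identity ``|input| = |kept| + per-stage rejections`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotator import Mention, context_tokens, find_name_occurrences
from .vocabulary import TokenDictionary

__all__ = [
    "RuleConfig",
    "FilterConfig",
    "token_context_rule",
    "affix_rule",
    "negative_vocab_filter",
    "tp_ratio_filter",
    "apply_cascade",
    "CascadeResult",
]

STAGE_TOKEN_RULES = "token_rules"
STAGE_NEGATIVE = "protein_gene"
STAGE_TP_RATIO = "tp_ratio"


@dataclass(frozen=True)
class RuleConfig:
    """Configuration of the name-decision rules.

    Defaults reproduce the standard configuration: a two-token context
    window, all three context rules plus both affix rules enabled, the
    'ase' rule reading the token *following* the match (so "benzoyl-CoA
    reductase" rejects "benzoyl-CoA") with "release" and "base" excepted.
    Set ``ase_on_following_token=False`` for the literal alternative reading
    (the matched term itself ends in "ase").
    """

    context_window: int = 2
    rule1: bool = True  # two words in front both chemical tokens
    rule2: bool = True  # one word in front a chemical token
    rule3: bool = True  # one word behind a chemical token
    poly_rule: bool = True
    ase_rule: bool = True
    ase_exceptions: frozenset[str] = frozenset({"release", "base"})
    poly_prefix: str = "poly"
    ase_on_following_token: bool = True

    def __post_init__(self) -> None:
        if self.context_window < 1:
            raise ValueError("context_window must be >= 1")


@dataclass(frozen=True)
class FilterConfig:
    """Which cascade stages run, and the TP-ratio threshold.

    Thresholds of 0.5 and above are rejected: past that point the filter
    removes more true than false positives by construction.
    """

    enable_structure_filter: bool = True
    enable_token_rules: bool = True
    enable_negative_vocab: bool = True
    enable_tp_ratio: bool = True
    tp_threshold: float = 0.0
    rule_config: RuleConfig = field(default_factory=RuleConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.tp_threshold < 0.5):
            raise ValueError(
                f"tp_threshold must be in [0, 0.5), got {self.tp_threshold}"
            )


# -- stage 1: tokens and rules ----------------------------------------------


def token_context_rule(
    mention: Mention,
    tokens: TokenDictionary,
    config: RuleConfig = RuleConfig(),
) -> tuple[bool, str | None]:
    """Context rules 1–3: is the match embedded among chemical tokens?

    Rule 1 fires when the two words in front are both chemical tokens,
    rule 2 when the word immediately in front is one, rule 3 when the word
    immediately behind is one.  Context is drawn from the mention's own
    sentence; the first triggering rule's id is returned.
    """
    before, after = context_tokens(mention, config.context_window)
    b1 = tokens.__contains__(before[-1]) if before else False
    b2 = tokens.__contains__(before[-2]) if len(before) >= 2 else False
    a1 = tokens.__contains__(after[0]) if after else False
    if config.rule1 and b1 and b2:
        return True, "rule1"
    if config.rule2 and b1:
        return True, "rule2"
    if config.rule3 and a1:
        return True, "rule3"
    return False, None


def affix_rule(
    mention: Mention,
    config: RuleConfig = RuleConfig(),
) -> tuple[bool, str | None]:
    """Poly-prefix and ase-suffix rules.

    "poly" immediately before a match (standalone, or joined by hyphen or
    parenthesis, as in "poly(ethylene glycol)") marks a polymer; a following
    word ending in "ase" marks an enzyme name that merely contains the
    chemical ("benzoyl-CoA reductase"), except the listed common words.
    """
    before, after = context_tokens(mention, 1)
    if config.poly_rule and before:
        rel_start = mention.start - mention.sentence_start
        gap_ok = _poly_adjacent(mention.sentence_text, rel_start, config.poly_prefix)
        if before[-1].lower() == config.poly_prefix.lower() and gap_ok:
            return True, "poly_prefix"
    if config.ase_rule:
        if config.ase_on_following_token:
            if after:
                word = after[0].lower()
                if word.endswith("ase") and word not in config.ase_exceptions:
                    return True, "ase_suffix"
        else:
            surface = mention.surface.lower()
            if surface.endswith("ase") and surface not in config.ase_exceptions:
                return True, "ase_suffix"
    return False, None


def _poly_adjacent(sentence: str, rel_start: int, prefix: str) -> bool:
    """Does ``prefix`` sit immediately before position ``rel_start``, joined
    only by whitespace, hyphens or an opening parenthesis/bracket?"""
    i = rel_start
    while i > 0 and sentence[i - 1] in " \t-([":
        i -= 1
    return sentence[:i].lower().endswith(prefix.lower()) and (
        i - len(prefix) == 0 or not sentence[i - len(prefix) - 1].isalnum()
    )


def _apply_token_rules(
    mentions: Sequence[Mention],
    tokens: TokenDictionary,
    config: RuleConfig,
) -> list[Mention]:
    kept = []
    for m in mentions:
        fired, rule = token_context_rule(m, tokens, config)
        if not fired:
            fired, rule = affix_rule(m, config)
        if fired:
            m.reject(STAGE_TOKEN_RULES, rule or "")
        else:
            kept.append(m)
    return kept


# -- stage 2: protein/gene negative vocabulary -------------------------------


def negative_vocab_filter(
    mentions: Sequence[Mention],
    negative_names: Iterable[str],
) -> list[Mention]:
    """Reject mentions contained in an occurrence of a negative-vocabulary
    name (protein/gene names that embed chemical names).

    Containment is judged within the mention's sentence; a mention exactly
    coextensive with a negative name is also rejected.  Occurrence finding
    reuses the dictionary matcher's boundary and longest-match semantics.
    """
    names = [n for n in negative_names]
    if not names:
        return list(mentions)
    kept = []
    occ_cache: dict[str, list[tuple[int, int]]] = {}
    for m in mentions:
        occs = occ_cache.get(m.sentence_text)
        if occs is None:
            occs = find_name_occurrences(m.sentence_text, names)
            occ_cache[m.sentence_text] = occs
        rs = m.start - m.sentence_start
        re_ = m.end - m.sentence_start
        if any(s <= rs and re_ <= e for s, e in occs):
            m.reject(STAGE_NEGATIVE, "negative_name")
        else:
            kept.append(m)
    return kept


# -- stage 3: TP-ratio threshold ---------------------------------------------


def tp_ratio_filter(
    mentions: Sequence[Mention],
    ratios,  # RatioTable; untyped to avoid a circular import
    threshold: float,
) -> list[Mention]:
    """Drop mentions whose every candidate concept has a trained ratio
    strictly below ``threshold``.

    Concepts without training evidence pass (no evidence is not negative
    evidence), and an ambiguous mention survives if any reading survives.
    A threshold of 0 is the identity.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError(f"threshold must be in [0, 0.5), got {threshold}")
    kept = []
    for m in mentions:
        ratio_of = [
            ratios.get(cid).ratio if ratios.get(cid) is not None else None
            for cid in m.concept_ids
        ]
        if all(r is not None and r < threshold for r in ratio_of):
            m.reject(STAGE_TP_RATIO, f"ratio<{threshold:g}")
        else:
            kept.append(m)
    return kept


# -- the cascade -------------------------------------------------------------


@dataclass
class CascadeResult:
    kept: list[Mention]
    rejected: list[Mention]

    @property
    def all_mentions(self) -> list[Mention]:
        return sorted(self.kept + self.rejected, key=lambda m: m.key())

    def rejections_by_stage(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.rejected:
            stage = m.status.split(":", 1)[1]
            out[stage] = out.get(stage, 0) + 1
        return out


def apply_cascade(
    mentions: Sequence[Mention],
    *,
    tokens: TokenDictionary | None = None,
    negative_names: Iterable[str] = (),
    ratios=None,
    config: FilterConfig = FilterConfig(),
) -> CascadeResult:
    """Run the mention-level cascade in order: tokens-and-rules, negative
    vocabulary, TP-ratio.  (The structure filter acts earlier, on the
    dictionary.)  Mentions are annotated in place with their rejection stage
    and rule; the kept set is always a subset of the input."""
    from .training import RatioTable

    current = list(mentions)
    if config.enable_token_rules:
        current = _apply_token_rules(
            current, tokens or TokenDictionary(), config.rule_config
        )
    if config.enable_negative_vocab:
        current = negative_vocab_filter(current, negative_names)
    if config.enable_tp_ratio and config.tp_threshold > 0:
        current = tp_ratio_filter(
            current, ratios if ratios is not None else RatioTable(), config.tp_threshold
        )
    rejected = [m for m in mentions if m.rejected]
    return CascadeResult(kept=current, rejected=rejected)
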