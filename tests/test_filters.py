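"""Name-decision rules, negative vocabulary, TP-ratio threshold, cascade."""

from __future__ import annotations

import itertools

import pytest

from moltag.annotator import Document, Mention, Scope, match_terms
from moltag.filters import (
    FilterConfig,
    RuleConfig,
    affix_rule,
    apply_cascade,
    negative_vocab_filter,
    token_context_rule,
    tp_ratio_filter,
)
from moltag.training import RatioEntry, RatioTable
from moltag.vocabulary import (
    ChemicalDictionary,
    ConceptEntry,
    TokenDictionary,
    build_token_dictionary,
)


def mention_in(sentence: str, surface: str, concept_ids=("c",)) -> Mention:
    start = sentence.index(surface)
    return Mention(
        doc_id="d",
        start=start,
        end=start + len(surface),
        surface=surface,
        concept_ids=frozenset(concept_ids),
        region="body",
        sentence_start=0,
        sentence_end=len(sentence),
        sentence_text=sentence,
    )


class TestTokenContextRules:
    def test_flanking_chemical_tokens_reject_inner_term(self):
        tokens = build_token_dictionary(["flavin adenine dinucleotide"])
        m = mention_in("shown by the flavin adenine dinucleotide (FAD)-", "adenine")
        fired, rule = token_context_rule(m, tokens)
        assert fired and rule in {"rule1", "rule2", "rule3"}

    def test_sentence_start_with_plain_following_word_is_retained(self):
        tokens = build_token_dictionary(["flavin"])
        m = mention_in("adenine was measured.", "adenine")
        fired, _ = token_context_rule(m, tokens)
        assert not fired

    @pytest.mark.parametrize(
        "b2, b1, a1, a2", list(itertools.product([False, True], repeat=4))
    )
    def test_truth_table_matches_or_of_rules(self, b2, b1, a1, a2):
        """Exhaustive check over chemical-token status of the 4 context slots."""
        chem = {"chemx"}
        words = [
            "chemx" if flag else "plain" for flag in (b2, b1, a1, a2)
        ]
        sentence = f"{words[0]} {words[1]} TERM {words[2]} {words[3]}."
        tokens = TokenDictionary(tokens=frozenset(chem))
        m = mention_in(sentence, "TERM")
        fired, rule = token_context_rule(m, tokens)
        expected = (b1 and b2) or b1 or a1
        assert fired == expected
        if fired:
            expected_rule = "rule1" if (b1 and b2) else ("rule2" if b1 else "rule3")
            assert rule == expected_rule

    def test_rules_individually_switchable(self):
        tokens = TokenDictionary(tokens=frozenset({"chemx"}))
        m = mention_in("plain chemx TERM plain plain.", "TERM")
        assert token_context_rule(m, tokens, RuleConfig())[0]
        off = RuleConfig(rule1=False, rule2=False, rule3=False)
        assert not token_context_rule(m, tokens, off)[0]

    def test_context_stays_within_sentence(self):
        tokens = TokenDictionary(tokens=frozenset({"chemx"}))
        # the chemical token sits in the previous sentence
        m = Mention(
            doc_id="d", start=13, end=17, surface="TERM",
            concept_ids=frozenset({"c"}), region="body",
            sentence_start=13, sentence_end=30,
            sentence_text="TERM was measured",
        )
        assert not token_context_rule(m, tokens)[0]

    def test_punctuation_only_tokens_skipped(self):
        tokens = TokenDictionary(tokens=frozenset({"chemx"}))
        m = mention_in("chemx ... TERM here.", "TERM")
        fired, rule = token_context_rule(m, tokens)
        assert fired and rule == "rule2"


class TestAffixRules:
    def test_following_ase_word_rejects(self):
        m = mention_in("the ATP-dependent benzoyl-CoA reductase and", "benzoyl-CoA")
        fired, rule = affix_rule(m)
        assert fired and rule == "ase_suffix"

    @pytest.mark.parametrize("word", ["release", "base"])
    def test_ase_exceptions_are_retained(self, word):
        m = mention_in(f"the histamine {word} was measured.", "histamine")
        assert not affix_rule(m)[0]

    def test_poly_with_parenthesis(self):
        m = mention_in("dissolved in poly(ethylene glycol) solution", "ethylene glycol")
        fired, rule = affix_rule(m)
        assert fired and rule == "poly_prefix"

    def test_poly_standalone_and_hyphen(self):
        for text in ("a poly ethylene glycol melt", "a poly-ethylene glycol melt"):
            m = mention_in(text, "ethylene glycol")
            assert affix_rule(m)[0], text

    def test_polymer_word_not_split_is_not_poly_prefix(self):
        # "polyploid" before the term is not the standalone token "poly"
        m = mention_in("the polyploid ethylene glycol mixture", "ethylene glycol")
        assert not affix_rule(m)[0]

    def test_literal_ase_reading_configurable(self):
        config = RuleConfig(ase_on_following_token=False)
        m = mention_in("purified benzoylase quickly", "benzoylase")
        assert affix_rule(m, config) == (True, "ase_suffix")
        m2 = mention_in("the benzoyl-CoA reductase and", "benzoyl-CoA")
        assert not affix_rule(m2, config)[0]


class TestNegativeVocabFilter:
    def test_mention_inside_negative_name_rejected(self):
        sentence = "the 4-hydroxybutyryl-CoA dehydratase was purified."
        m = mention_in(sentence, "4-hydroxybutyryl-CoA")
        kept = negative_vocab_filter([m], ["4-hydroxybutyryl-CoA dehydratase"])
        assert kept == [] and m.status == "filtered:protein_gene"

    def test_empty_vocabulary_is_identity(self):
        m = mention_in("some glucose here.", "glucose")
        assert negative_vocab_filter([m], []) == [m]
        assert not m.rejected

    def test_adjacent_but_not_inside_is_retained(self):
        sentence = "glucose near glucose oxidase site."
        first = mention_in(sentence, "glucose")  # the standalone one at 0
        kept = negative_vocab_filter([first], ["glucose oxidase"])
        assert kept == [first]

    def test_coextensive_mention_rejected(self):
        sentence = "the glucose oxidase assay."
        m = mention_in(sentence, "glucose oxidase")
        assert negative_vocab_filter([m], ["glucose oxidase"]) == []


class TestTpRatioFilter:
    def table(self, **ratios):
        t = RatioTable()
        for cid, (a, c) in ratios.items():
            t.entries[cid] = RatioEntry(cid, a, c)
        return t

    def test_threshold_brackets_trained_ratio(self):
        table = self.table(lead=(1000, 110))  # ratio 0.110
        m1 = mention_in("too much lead here.", "lead", ("lead",))
        assert tp_ratio_filter([m1], table, 0.15) == []
        m2 = mention_in("too much lead here.", "lead", ("lead",))
        assert tp_ratio_filter([m2], table, 0.025) == [m2]

    def test_zero_threshold_is_identity(self):
        table = self.table(x=(10, 0))
        m = mention_in("an x.", "x", ("x",))
        assert tp_ratio_filter([m], table, 0.0) == [m]

    def test_unknown_concept_passes(self):
        m = mention_in("mystery compound.", "mystery", ("unseen",))
        assert tp_ratio_filter([m], RatioTable(), 0.4) == [m]

    def test_ambiguous_mention_survives_if_any_reading_survives(self):
        table = self.table(bad=(100, 1), good=(100, 90))
        m = mention_in("the drug.", "drug", ("bad", "good"))
        assert tp_ratio_filter([m], table, 0.3) == [m]
        m2 = mention_in("the drug.", "drug", ("bad",))
        assert tp_ratio_filter([m2], table, 0.3) == []

    @pytest.mark.parametrize("t1, t2", [(0.0, 0.1), (0.05, 0.2), (0.2, 0.45)])
    def test_antitone_in_threshold(self, t1, t2):
        import random

        rng = random.Random(7)
        table = RatioTable()
        for i in range(30):
            a = rng.randint(1, 50)
            table.entries[f"c{i}"] = RatioEntry(f"c{i}", a, rng.randint(0, a))

        def run(threshold):
            ms = [
                mention_in(f"word{i} c{i}.", f"c{i}", (f"c{i}",))
                for i in range(30)
            ]
            return {m.concept_ids for m in tp_ratio_filter(ms, table, threshold)}

        assert run(t2) <= run(t1)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            tp_ratio_filter([], RatioTable(), 0.5)


class TestCascade:
    def test_all_filters_disabled_is_identity(self, excerpt_document, excerpt_dictionary):
        mentions = match_terms(excerpt_document, excerpt_dictionary, Scope.FULL)
        config = FilterConfig(
            enable_structure_filter=False,
            enable_token_rules=False,
            enable_negative_vocab=False,
            enable_tp_ratio=False,
        )
        result = apply_cascade(mentions, config=config)
        assert result.kept == mentions and result.rejected == []

    def test_worked_excerpt_full_cascade(
        self, excerpt_document, excerpt_dictionary, excerpt_tokens
    ):
        mentions = match_terms(excerpt_document, excerpt_dictionary, Scope.FULL)
        config = FilterConfig(enable_structure_filter=False)
        apply_cascade(mentions, tokens=excerpt_tokens, config=config)
        by_surface = {m.surface: m for m in mentions}
        assert by_surface["adenine"].status == "filtered:token_rules"
        assert by_surface["adenine"].filter_flags[0][1] in {"rule1", "rule2", "rule3"}
        for coa in ("benzoyl-CoA", "4-hydroxybenzoyl-CoA", "4-hydroxybutyryl-CoA"):
            assert by_surface[coa].filter_flags == [("token_rules", "ase_suffix")]

    def test_audit_accounting(self, excerpt_document, excerpt_dictionary, excerpt_tokens):
        mentions = match_terms(excerpt_document, excerpt_dictionary, Scope.FULL)
        result = apply_cascade(
            mentions,
            tokens=excerpt_tokens,
            negative_names=["benzoyl-CoA reductase"],
            config=FilterConfig(enable_structure_filter=False),
        )
        stage_counts = result.rejections_by_stage()
        assert len(mentions) == len(result.kept) + sum(stage_counts.values())

    def test_stages_combined_keep_at_most_min_of_single_stages(self):
        d = ChemicalDictionary(
            [
                ConceptEntry("a", "adenine", tree_numbers=("D01",)),
                ConceptEntry("g", "glucose", tree_numbers=("D02",)),
            ]
        )
        doc = Document(
            "d",
            "Title without terms",
            "flavin adenine dinucleotide acts. glucose oxidase binds glucose.",
        )
        tokens = build_token_dictionary(["flavin adenine dinucleotide"])
        negative = ["glucose oxidase"]
        table = RatioTable()
        table.entries["g"] = RatioEntry("g", 100, 1)

        def kept_count(**flags):
            mentions = match_terms(doc, d, Scope.FULL)
            config = FilterConfig(
                enable_structure_filter=False,
                enable_token_rules=flags.get("token_rules", False),
                enable_negative_vocab=flags.get("negative", False),
                enable_tp_ratio=flags.get("tp", False),
                tp_threshold=0.3 if flags.get("tp") else 0.0,
            )
            return len(
                apply_cascade(
                    mentions, tokens=tokens, negative_names=negative,
                    ratios=table, config=config,
                ).kept
            )

        singles = [
            kept_count(token_rules=True),
            kept_count(negative=True),
            kept_count(tp=True),
        ]
        combined = kept_count(token_rules=True, negative=True, tp=True)
        assert combined <= min(singles)

    def test_cascade_idempotent_on_kept_set(
        self, excerpt_document, excerpt_dictionary, excerpt_tokens
    ):
        mentions = match_terms(excerpt_document, excerpt_dictionary, Scope.FULL)
        config = FilterConfig(enable_structure_filter=False)
        first = apply_cascade(mentions, tokens=excerpt_tokens, config=config)
        second = apply_cascade(first.kept, tokens=excerpt_tokens, config=config)
        assert second.kept == first.kept


def test_filter_config_threshold_validation():
    with pytest.raises(ValueError):
        FilterConfig(tp_threshold=0.5)
    with pytest.raises(ValueError):
        FilterConfig(tp_threshold=-0.1)
    assert FilterConfig(tp_threshold=0.499).tp_threshold == 0.499


def test_rule_config_window_validation():
    with pytest.raises(ValueError):
        RuleConfig(context_window=0)
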