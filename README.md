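# moltag

Dictionary-based annotation of small-molecule names in scientific titles
and abstracts, with a cascade of false-positive filters, a trainable
per-term true-positive-ratio filter for tunable precision/recall, and
hierarchy-aware evaluation against manually indexed gold annotations.

## The problem

Free-text matching of a chemical vocabulary (a hierarchical thesaurus of
headings plus supplementary substance records) against abstracts finds the
right *strings* but mostly the wrong *annotations*: a matched term is often
a fragment of a longer entity name ("adenine" inside "flavin adenine
dinucleotide", "benzoyl-CoA" inside "benzoyl-CoA reductase") or a
chemically non-specific homonym of a common word ("lead", "link").
`moltag` reproduces what a human indexer would annotate by filtering raw
matches through four cumulative stages:

1. **structure filter** — restrict the vocabulary to concepts mapped to an
   actual small-molecule structure record, plus inorganic formulas
   ("NaCl", "KOH") added as case-sensitive synonyms;
2. **tokens and rules** — a *chemical token* dictionary (fragments of
   chemical names dissected at separators, minus common English words) and
   name-decision rules mark a match flanked by chemical tokens, preceded
   by "poly", or followed by a word ending in "ase" (except "release" and
   "base") as a substring of a larger name;
3. **protein/gene negative vocabulary** — matches inside occurrences of
   known protein/gene names are suppressed;
4. **TP-ratio filter** — for each concept, training on a gold-annotated
   corpus estimates

   `ratio = C / A`

   where `A` counts training abstracts containing a free-text match of the
   concept (binary per abstract) and `C` counts those the indexers
   actually annotated with it (directly or at an ancestor level). Matches
   whose every candidate concept has `ratio < t` are dropped; the
   threshold `t ∈ [0, 0.5)` tunes precision against recall.

Matching can be scoped to the title only, to the title plus the first and
last sentences of the abstract (where objectives and conclusions tend to
sit), or to the full abstract — a second precision/recall dial.

Evaluation credits a prediction when its *relative-node expansion* (the
concept, its tree-number ancestors, and mapped headings for substances)
intersects the gold set — indexers often choose "Penicillins" where the
text says "Penicillin G" — and splits false negatives into "in text, not
found" versus "not in text", with

`P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F = 2PR/(P+R)`.

## Worked example

Everything runs on synthetic fixtures generated from a seed (no downloads):

```python
from moltag import ChemicalTagger, FixtureSpec, generate_bundle

bundle = generate_bundle(FixtureSpec(seed=7, n_concepts=30, n_documents=200))
train, test = bundle.corpus[:150], bundle.corpus[150:]

tagger = ChemicalTagger(
    dictionary=bundle.dictionary,
    token_dictionary=bundle.tokens,
    negative_vocabulary=tuple(bundle.negative_names),
    scope="full",
    tp_threshold=0.15,
).fit(train)

print(len(tagger.ratio_table_), "concepts have TP ratios")
print(f"F on held-out documents: {tagger.score(test):.3f}")
```

Sweeping the TP-ratio threshold on the held-out half prints:

```
tp_threshold=0.0   TP= 38 FP= 48 FN(in text)=12 FN(not in text)= 6 P=0.442 R=0.679 F=0.535
tp_threshold=0.15  TP= 25 FP= 37 FN(in text)=25 FN(not in text)= 6 P=0.403 R=0.446 F=0.424
tp_threshold=0.25  TP= 13 FP= 20 FN(in text)=37 FN(not in text)= 6 P=0.394 R=0.232 F=0.292
```

Raising the threshold always shrinks the kept annotation set (recall
falls); whether precision rises depends on the spread of per-term ratios —
in this synthetic corpus every term shares the same annotation propensity
(0.3), so the filter cannot separate good terms from bad ones and only the
recall cost is visible. The six "not in text" false negatives are gold
concepts the generator deliberately never placed in the abstract: no
title/abstract annotator can find them, which is why they are reported
separately.

The same workflow is available from the shell:

```sh
moltag simulate --seed 7 --n-concepts 30 --n-documents 200 --out fx/
moltag build-dict --dict fx/dictionary.tsv --stoplist fx/stoplist.txt --out dict/
moltag train    --dict fx/dictionary.tsv --corpus fx/corpus.jsonl --out ratios.tsv
moltag annotate --dict fx/dictionary.tsv --corpus fx/corpus.jsonl \
                --negative fx/negative_vocabulary.txt --ratios ratios.tsv \
                --tp-threshold 0.15 --out mentions.tsv
moltag evaluate --dict fx/dictionary.tsv --corpus fx/corpus.jsonl \
                --negative fx/negative_vocabulary.txt --ratios ratios.tsv \
                --tp-threshold 0.0 --tp-threshold 0.15 --out metrics.tsv
```

`annotate` writes a PubTator-style TSV in which every mention carries an
audit status — `kept`, or `filtered:<stage>` naming the cascade stage (and
rule) that removed it.

## Layout

- `moltag.vocabulary` — dictionary loading (TSV/JSONL dialects), structure
  filter, formula augmentation, chemical-token dictionary, stoplists
- `moltag.annotator` — documents, sentence scoping, the free-text matcher
- `moltag.filters` — the name-decision rules and the filter cascade
- `moltag.training` — TP-ratio estimation and the ratio-table TSV
- `moltag.evaluation` — relative-node expansion, confusion counting, P/R/F
- `moltag.simulate` — seeded synthetic fixtures (dictionary, corpus, gold)
- `moltag.estimator` — `ChemicalTagger`, the sklearn-style front end
- `moltag.cli` — the `moltag` command
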