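# Methods

This note documents the model implemented by `moltag`, the numerical and
design choices that were genuinely open, what the synthetic fixtures do
and do not emulate, and known limitations.

## Annotation model

A document is a title plus an abstract. The annotator scans one of three
scopes — title only; title + first and last abstract sentences; title +
full abstract — and proposes every word-boundary-anchored occurrence of a
vocabulary name as a candidate mention. Candidates then pass a cumulative
filter cascade; what survives is the document's predicted concept set.
The pipeline is exposed both as library functions and as the
`ChemicalTagger` estimator (`fit` trains the TP-ratio table from a
gold-annotated corpus; `predict` returns per-document concept sets), so
threshold and scope sweeps compose with scikit-learn model selection.

### Matching

* **Normalization and case.** Names are indexed with internal whitespace
  collapsed and lower-cased, *except* names of ≤ 3 characters and names
  flagged as inorganic formulas, which are indexed case-sensitively:
  short strings and formulas are the dominant homonym risk ("KOH" must
  match, "koh" must not). A run of whitespace in text matches the single
  space of a normalized name.
* **Word boundaries.** A match must be flanked by text edges or
  non-alphanumeric characters. A hyphen therefore acts as a boundary, so
  "flavin-adenine-dinucleotide" exposes "adenine" to matching; the
  token-context rules then reject it because its hyphen-joined neighbours
  are chemical tokens. Finding-then-filtering, rather than silently not
  matching, keeps the audit trail complete and the pre-filter match
  statistics (used for the FN split and TP ratios) well defined.
* **Overlap resolution.** Longest match wins, then left-most, with
  equal-length ties broken by the lexicographically smallest concept-id
  set — the last rule exists purely to make output deterministic.
  Ambiguous surfaces keep *all* candidate concepts; ambiguity is never
  resolved at match time.
* **Sentence segmentation.** A sentence ends at terminal punctuation
  ([.?!]) followed by whitespace and an uppercase letter or digit, with a
  small configurable abbreviation list; setting
  `abbreviation_aware=False` splits at every terminal-punctuation +
  whitespace position. Matching always runs per sentence (the title is
  one region), which guarantees that no mention crosses a region
  boundary and that the three scopes yield nested mention sets.

### Chemical tokens

Tokens are produced by dissecting vocabulary names at whitespace, comma,
semicolon, parentheses, square brackets and slash; hyphens are kept
inside tokens *and* each hyphen-delimited fragment of length ≥ 2 is also
emitted (so "benzoyl-CoA" contributes "benzoyl-coa", "benzoyl" and
"coa"). Removed afterwards: stoplist words (any public-domain English
prose serves as a stoplist source via `build_stoplist`), single
characters, fragments without an alphabetic character (pure numbers,
digit-punctuation locants such as "2,4", special characters), and
numeric identifiers — a single letter with trailing digits of total
length ≤ 3 (e.g. "h2"). The separator set and the numeric-identifier
pattern are package choices; both live in one place
(`vocabulary.dissect_name`, `vocabulary._is_token_noise`) and are the
defaults the tests pin down.

### Filter cascade

Stages run in a fixed order: structure filter (on the dictionary, before
matching) → tokens-and-rules → protein/gene negative vocabulary →
TP-ratio threshold. Within tokens-and-rules the evaluation order is
rule 1 (two chemical tokens in front), rule 2 (one in front), rule 3 (one
behind), poly-prefix, ase-suffix; the rules are OR-ed, so the order only
fixes which rule id the audit trail records. Context is drawn from the
mention's own sentence, skipping punctuation-only fragments; the window
is two tokens per side (wider windows gain nothing and cost recall).

The ase rule inspects the token *following* the match: "benzoyl-CoA
reductase" rejects "benzoyl-CoA". The alternative literal reading — the
matched term itself ends in "ase" — is available via
`RuleConfig(ase_on_following_token=False)`, but the default is the
following-token reading because only it makes the "release"/"base"
exceptions sensible (those are common words *after* chemical names, not
chemical names themselves). The poly rule requires the standalone token
"poly" immediately before the match, joined by whitespace, hyphen or an
opening parenthesis/bracket ("poly(ethylene glycol)"); "polyploid" does
not trigger it.

The negative-vocabulary stage finds occurrences of protein/gene names
with the same matcher semantics (boundaries, longest match) and rejects
any mention whose span lies inside — or exactly coincides with — such an
occurrence, within the same sentence.

The TP-ratio stage drops a mention only when *every* candidate concept
has a trained ratio strictly below the threshold; concepts without
training evidence pass (absence of evidence is not negative evidence),
and an ambiguous surface survives if any reading survives. Thresholds
are restricted to [0, 0.5): beyond 0.5 the filter removes more true than
false positives by construction.

Every stage is contractive and idempotent; each rejection is recorded as
`(stage, rule)` on the mention and as `filtered:<stage>` in the TSV
output, so `|input| = |kept| + Σ rejections` is checkable per document.

### TP-ratio training

`A(c)` counts training documents with at least one pre-filter match of
concept `c` (binary per document — repeated mentions count once);
`C(c)` counts the subset whose gold set credits `c` under the same
relative-node expansion used in evaluation, so the ratio measures "was
this textual match endorsed by the indexer at any ancestor level".
`C ≤ A` by construction, ratios are exact rationals stored at full
precision (display rounding is two significant figures), and concepts
with `A = 0` have no entry. Estimation is invariant to document order
and independent of the filter configuration. No smoothing or shrinkage
is applied — a concept seen once keeps its extreme 0 or 1 ratio; with
thresholds below 0.5 this only ever *removes* rare terms whose single
training occurrence was unannotated.

### Evaluation

A prediction is credited (TP) when its relative-node expansion — itself,
every ancestor along each tree number (ancestors are dot-separated
prefixes), and for substance records each mapped heading plus that
heading's ancestors — intersects the document's gold set. Credit runs
only toward more general gold labels; a gold concept more specific than
the prediction earns nothing. TP is counted per covered gold concept and
FP per prediction whose expansion misses gold entirely, so a second
prediction crediting an already-covered gold concept is deduplicated
rather than double-counted, `TP + FN` always equals the number of gold
pairs, and `TP + FP` equals the number of predicted pairs whenever the
credit relation is one-to-one. Missed gold concepts split into
"in text, not found" (some pre-filter, full-scope match against the
*unfiltered* dictionary reaches them, directly or via a descendant) and
"not in text" — the latter is an upper bound on true absence, since a
term can also be missed for spelling or synonymy reasons. Precision,
recall and F are defined as 0 when their denominators vanish. No claim
is made (or asserted in tests) that precision is monotone in the
threshold; only the kept-set subset property is guaranteed.

## Synthetic fixtures

The generator (`moltag.simulate`) draws everything from one seeded
`random.Random` stream consumed in a fixed order (dictionary, then
corpus), so equal specs give byte-identical files; a manifest records the
planted truth. Defaults describe a desk-scale study condition: 30
concepts, 60 documents, 10 % ambiguous names, 5 % common-word homonyms,
10 % of occurrences embedded in protein-style names, per-(document,
concept) annotation probability 0.3 (the propensity of common chemicals
in real indexing), 20 % generalization of a gold label to the parent
concept, 60 % structure-id coverage, and a 15 % chance per document of a
gold concept never placed in the text. Names come from a small grammar
of chemical-looking morphemes so the token dictionary is non-trivial;
negative names are built as "<chemical name> <word ending in -ase>", so
the ase rule and the negative vocabulary genuinely overlap, as they do
in real corpora. The annotation decision is drawn once per (document,
concept), not per occurrence: ratio estimation is per-document binary,
and the per-occurrence variant would recover 1−(1−p)^k rather than p
for concepts occurring k times.

What the fixtures do **not** emulate: real English prose and its
punctuation diversity, IUPAC systematic names, acronym usage, spelling
variants, MEDLINE field structure beyond title/abstract, and realistic
per-term variation in annotation propensity (every concept shares one
`annotation_prob`, so threshold sweeps on fixtures show the recall cost
of the TP filter but not its precision benefit). Passing tests therefore
demonstrate correctness of the mechanics — matching, rules, counting,
credit, tunability — not corpus-level performance on real literature.

## Problem sizes in the test suite

Property suites use 200 random matcher fixtures (dictionaries ≤ 20
names, texts ≤ 300 characters) against a quadratic brute-force oracle,
100 seeded cascade fixtures, and, for ratio recovery, 100 simulated
corpora of 520 documents for each planted probability in {0.1, 0.3,
0.9}, checking the estimate against the central 99 % binomial interval
at the realised A (coverage required: ≥ 99 % of estimates). These sizes
keep the full suite under a minute while leaving each property with
enough trials to fail loudly when a semantics change breaks it.

## Known limitations

* Dictionary scanning is per-name regex search — linear in
  |names| × |text|. Fine for desk-scale vocabularies; a multi-pattern
  automaton would be the next step for 10⁵-name dictionaries.
* The negative vocabulary and the rules act within sentences; an entity
  name broken across a sentence boundary by the splitter escapes them.
* No acronym expansion, fuzzy matching or spelling correction: a name
  absent from the dictionary (or misspelled) is invisible, which is the
  known blind spot of dictionary-based recognition.
* `compare` treats concept ids absent from the dictionary as expanding
  to themselves, so gold sets referencing out-of-vocabulary concepts
  degrade gracefully instead of erroring.
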