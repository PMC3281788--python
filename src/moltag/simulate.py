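"""Deterministic synthetic fixtures: dictionary, corpus, gold annotations.

Real chemical thesauri and manually indexed corpora are large and
licensed; every stage of the pipeline is therefore testable against
synthetic data that reproduces the *statistical shape* of the problem:

* a 2–3-level concept tree with tree numbers, substance records mapped to
  headings, partial structure-id coverage, ambiguous names shared by two
  concepts, and homonyms of common words;
* protein-style negative names built as "<chemical name> <word ending in
  ase>", so both the ase-affix rule and the negative vocabulary fire;
* documents whose title and multi-sentence abstract embed concept names in
  controlled contexts — standalone, inside a negative name, or flanked by
  chemical tokens — with per-(document, concept) gold annotation
  probability ``annotation_prob``, optional generalization of a gold label
  to the concept's parent, and occasional gold concepts never placed in
  the text (populating the "not in text" false-negative class).

Everything is drawn from a single seeded pseudo-random stream consumed in
a documented order, so identical specs give byte-identical outputs; a
manifest records the planted truth for exact expected-value tests.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

from .annotator import Document
from .vocabulary import (
    ChemicalDictionary,
    ConceptEntry,
    TokenDictionary,
    build_token_dictionary,
    save_dictionary,
    write_wordlist,
)

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "generate_dictionary",
    "generate_corpus",
    "generate_bundle",
    "write_bundle",
]

# chemical-looking morphemes; names synthesized from these make the token
# dictionary non-trivial and exercise the real tokenizer paths
_PREFIXES = (
    "meth", "eth", "prop", "but", "pent", "hex", "benz", "oxy", "chlor",
    "fluor", "brom", "amin", "hydrox", "sulf", "nitr", "phen", "acet",
    "glyc", "carb", "thi",
)
_SUFFIXES = (
    "ane", "ene", "ol", "al", "ine", "ate", "ide", "one", "amide", "oxide",
    "yl", "an",
)
_ENZYME_SUFFIXES = (
    "dehydrogenase", "reductase", "synthase", "kinase", "dehydratase",
    "transferase", "hydrolase",
)

# the connective vocabulary of the generated prose; doubles as the stoplist
_STOPWORDS = (
    "the", "a", "of", "and", "in", "with", "was", "were", "is", "are",
    "we", "this", "study", "effect", "effects", "treated", "measured",
    "observed", "results", "conclude", "that", "levels", "increased",
    "decreased", "patients", "samples", "to", "on", "for", "by", "show",
    "showed", "analysis", "role", "during", "after", "compared", "control",
    "group", "enzyme", "purified", "activity", "response", "induced",
    "lead", "monitor", "advantage", "counter", "link",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study condition.

    Rates are fractions in [0, 1].  ``ambiguity_rate`` controls names
    shared by two concepts; ``homonym_rate`` names equal to stoplist words;
    ``substring_rate`` the fraction of in-text occurrences embedded in a
    longer protein-style name; ``annotation_prob`` the per-(document,
    concept) probability that a textual occurrence is gold-annotated;
    ``generalization_prob`` the probability a gold label is replaced by the
    concept's parent; ``structure_coverage`` the fraction of concepts
    carrying a structure id.
    """

    seed: int = 0
    n_concepts: int = 30
    n_documents: int = 60
    ambiguity_rate: float = 0.1
    homonym_rate: float = 0.05
    substring_rate: float = 0.1
    annotation_prob: float = 0.3
    generalization_prob: float = 0.2
    structure_coverage: float = 0.6
    unplaced_gold_prob: float = 0.15
    chemical_context_prob: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "ambiguity_rate", "homonym_rate", "substring_rate",
            "annotation_prob", "generalization_prob", "structure_coverage",
            "unplaced_gold_prob", "chemical_context_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_concepts < 2 or self.n_documents < 1:
            raise ValueError("need n_concepts >= 2 and n_documents >= 1")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    dictionary: ChemicalDictionary
    tokens: TokenDictionary
    negative_names: list[str]
    stoplist: list[str]
    corpus: list[Document]
    manifest: dict


def _make_name(rng: random.Random, taken: set[str]) -> str:
    for _ in range(1000):
        n_parts = rng.choice((1, 1, 2))
        parts = [
            rng.choice(_PREFIXES) + rng.choice(_PREFIXES) + rng.choice(_SUFFIXES)
            for _ in range(n_parts)
        ]
        name = " ".join(parts)
        if name not in taken and len(name) > 3:
            taken.add(name)
            return name
    raise RuntimeError("name grammar exhausted")  # pragma: no cover


def generate_dictionary(
    spec: FixtureSpec, rng: random.Random | None = None
) -> tuple[ChemicalDictionary, TokenDictionary, list[str], list[str]]:
    """Synthesize (dictionary, token dictionary, negative names, stoplist).

    The concept tree has 2–3 levels; the last ~15% of concepts are
    substance records (no tree numbers) mapped to a heading.  Exactly
    ``round(ambiguity_rate * n)`` names are shared by two concepts, and
    ``round(homonym_rate * n)`` concepts gain a stoplist-word synonym.
    """
    rng = rng if rng is not None else random.Random(spec.seed)
    n = spec.n_concepts
    taken: set[str] = set(_STOPWORDS)
    n_substances = max(1, n * 15 // 100) if n >= 7 else 0
    n_tree = n - n_substances
    n_roots = max(2, n_tree // 6)

    entries: list[ConceptEntry] = []
    tree_numbers: list[str] = []
    for i in range(n_tree):
        cid = f"C{i:04d}"
        name = _make_name(rng, taken)
        if i < n_roots:
            tn = f"D{i + 1:02d}"
        else:
            parent = rng.choice(tree_numbers)
            tn = f"{parent}.{100 + i}"
        tree_numbers.append(tn)
        entries.append(
            ConceptEntry(concept_id=cid, preferred_name=name, tree_numbers=(tn,))
        )
    for j in range(n_substances):
        cid = f"S{j:04d}"
        name = _make_name(rng, taken)
        mapped = rng.choice(entries[:n_tree]).concept_id
        entries.append(
            ConceptEntry(
                concept_id=cid, preferred_name=name, mapped_concept_ids=(mapped,)
            )
        )

    # structure-id coverage: exactly round(coverage * n) concepts flagged
    n_structured = round(spec.structure_coverage * n)
    structured = sorted(rng.sample(range(n), n_structured))
    entries = [
        ConceptEntry(
            concept_id=e.concept_id,
            preferred_name=e.preferred_name,
            synonyms=e.synonyms,
            tree_numbers=e.tree_numbers,
            structure_ids=(f"CID{1000 + i}",) if i in structured else (),
            mapped_concept_ids=e.mapped_concept_ids,
        )
        for i, e in enumerate(entries)
    ]

    # shared (ambiguous) names: concept i's preferred name becomes a synonym
    # of another concept
    n_shared = round(spec.ambiguity_rate * n)
    shared_names: list[str] = []
    for k in range(n_shared):
        donor = entries[k]
        recipient_idx = (k + n // 2) % n
        if recipient_idx == k:
            recipient_idx = (k + 1) % n
        r = entries[recipient_idx]
        entries[recipient_idx] = ConceptEntry(
            concept_id=r.concept_id,
            preferred_name=r.preferred_name,
            synonyms=(*r.synonyms, donor.preferred_name),
            tree_numbers=r.tree_numbers,
            structure_ids=r.structure_ids,
            mapped_concept_ids=r.mapped_concept_ids,
        )
        shared_names.append(donor.preferred_name)

    # homonyms of common words
    n_homonyms = round(spec.homonym_rate * n)
    homonym_words = ("lead", "monitor", "advantage", "counter", "link")
    homonyms: list[str] = []
    for k in range(n_homonyms):
        word = homonym_words[k % len(homonym_words)]
        idx = n - 1 - k
        e = entries[idx]
        if e.is_substance and not e.mapped_concept_ids:  # pragma: no cover
            continue
        entries[idx] = ConceptEntry(
            concept_id=e.concept_id,
            preferred_name=e.preferred_name,
            synonyms=(*e.synonyms, word),
            tree_numbers=e.tree_numbers,
            structure_ids=e.structure_ids,
            mapped_concept_ids=e.mapped_concept_ids,
        )
        homonyms.append(word)

    dictionary = ChemicalDictionary(entries)
    stoplist = sorted(_STOPWORDS)
    tokens = build_token_dictionary(dictionary.all_names(), stoplist)

    # protein-style negative names embed a chemical name before an -ase word
    negative_names = [
        f"{e.preferred_name} {rng.choice(_ENZYME_SUFFIXES)}"
        for e in entries[::3][: max(1, n // 3)]
    ]
    return dictionary, tokens, negative_names, stoplist


_SENTENCE_TEMPLATES = (
    "We measured {name} in treated samples.",
    "The levels of {name} increased during the study.",
    "Analysis showed that {name} induced a response in patients.",
    "This study observed the role of {name} after treatment.",
)
_FILLER_SENTENCES = (
    "The control group showed no response.",
    "Results were compared during the analysis.",
    "We observed increased activity after treatment.",
    "Samples were measured in the study.",
)


def _parent_of(concept_id: str, dictionary: ChemicalDictionary) -> str | None:
    entry = dictionary.concept(concept_id)
    if entry.is_substance:
        return entry.mapped_concept_ids[0] if entry.mapped_concept_ids else None
    for tn in entry.tree_numbers:
        parts = tn.split(".")
        if len(parts) > 1:
            parent = dictionary.concept_for_tree_number(".".join(parts[:-1]))
            if parent is not None:
                return parent
    return None


def generate_corpus(
    spec: FixtureSpec,
    dictionary: ChemicalDictionary,
    *,
    negative_names: list[str] | None = None,
    tokens: TokenDictionary | None = None,
    rng: random.Random | None = None,
) -> tuple[list[Document], dict]:
    """Synthesize gold-annotated documents; returns (corpus, manifest).

    Each document embeds 2–4 sampled concepts.  Per planted occurrence the
    context is standalone, inside a negative name (``substring_rate``), or
    flanked by chemical tokens (``chemical_context_prob``); the gold
    decision is drawn once per (document, concept).
    """
    rng = rng if rng is not None else random.Random(spec.seed + 1)
    negative_names = negative_names or []
    concept_ids = list(dictionary.concept_ids)
    chem_tokens = sorted(tokens.tokens) if tokens else []
    docs: list[Document] = []
    doc_manifests: list[dict] = []
    for d in range(spec.n_documents):
        doc_id = f"DOC{d:05d}"
        k = rng.randint(2, min(4, len(concept_ids)))
        chosen = rng.sample(concept_ids, k)
        title_cid = chosen[0]
        title_name = dictionary.concept(title_cid).preferred_name
        title = f"Effects of {title_name} in a controlled study"
        placed: list[dict] = []
        sentences: list[str] = [rng.choice(_FILLER_SENTENCES)]
        placed.append({"concept_id": title_cid, "mode": "title", "sentence": -1})
        for cid in chosen:
            name = dictionary.concept(cid).preferred_name
            roll = rng.random()
            candidates = [nn for nn in negative_names if nn.startswith(name + " ")]
            if roll < spec.substring_rate and candidates:
                neg = rng.choice(candidates)
                sentence = f"The enzyme {neg} was purified for analysis."
                mode = "negative_substring"
            elif roll < spec.substring_rate + spec.chemical_context_prob and chem_tokens:
                tok = rng.choice(chem_tokens)
                sentence = f"We observed {tok} {name} activity in samples."
                mode = "chemical_context"
            else:
                sentence = rng.choice(_SENTENCE_TEMPLATES).format(name=name)
                mode = "standalone"
            sentences.append(sentence)
            placed.append({"concept_id": cid, "mode": mode, "sentence": len(sentences) - 1})
        sentences.append(rng.choice(_FILLER_SENTENCES))
        abstract = " ".join(sentences)

        # gold: one draw per (document, concept); optional generalization
        gold: set[str] = set()
        placed_concepts = sorted({p["concept_id"] for p in placed})
        annotated: list[str] = []
        for cid in placed_concepts:
            if rng.random() < spec.annotation_prob:
                label = cid
                if rng.random() < spec.generalization_prob:
                    parent = _parent_of(cid, dictionary)
                    if parent is not None:
                        label = parent
                gold.add(label)
                annotated.append(cid)
        unplaced: list[str] = []
        if rng.random() < spec.unplaced_gold_prob:
            pool = [c for c in concept_ids if c not in placed_concepts]
            if pool:
                extra = rng.choice(pool)
                gold.add(extra)
                unplaced.append(extra)
        docs.append(
            Document(
                doc_id=doc_id,
                title=title,
                abstract=abstract,
                gold_concepts=frozenset(gold),
            )
        )
        doc_manifests.append(
            {
                "doc_id": doc_id,
                "placed": placed,
                "annotated_concepts": annotated,
                "gold": sorted(gold),
                "gold_not_in_text": unplaced,
            }
        )
    manifest = {"spec": asdict(spec), "documents": doc_manifests}
    return docs, manifest


def generate_bundle(spec: FixtureSpec) -> FixtureBundle:
    """All fixtures from one seeded stream, consumed in documented order:
    dictionary first, then corpus."""
    rng = random.Random(spec.seed)
    dictionary, tokens, negative_names, stoplist = generate_dictionary(spec, rng)
    corpus, manifest = generate_corpus(
        spec, dictionary, negative_names=negative_names, tokens=tokens, rng=rng
    )
    manifest["negative_names"] = negative_names
    return FixtureBundle(
        spec=spec,
        dictionary=dictionary,
        tokens=tokens,
        negative_names=negative_names,
        stoplist=stoplist,
        corpus=corpus,
        manifest=manifest,
    )


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write dictionary TSV, corpus JSONL, stoplist, negative vocabulary and
    the manifest JSON; byte-identical across runs of the same spec."""
    from .io import write_corpus_jsonl

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dictionary": outdir / "dictionary.tsv",
        "corpus": outdir / "corpus.jsonl",
        "stoplist": outdir / "stoplist.txt",
        "negative": outdir / "negative_vocabulary.txt",
        "manifest": outdir / "manifest.json",
    }
    save_dictionary(bundle.dictionary, paths["dictionary"])
    write_corpus_jsonl(bundle.corpus, paths["corpus"])
    write_wordlist(bundle.stoplist, paths["stoplist"])
    Path(paths["negative"]).write_text(
        "\n".join(bundle.negative_names) + "\n", encoding="utf-8"
    )
    paths["manifest"].write_text(
        json.dumps(bundle.manifest, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return paths
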