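"""Shared fixtures: small hand-built vocabularies, the printed-abstract
worked example, random matcher fixtures, and an independent brute-force
matching oracle."""

from __future__ import annotations

import random

import pytest

from moltag.annotator import Document, split_sentences
from moltag.vocabulary import (
    ChemicalDictionary,
    ConceptEntry,
    build_token_dictionary,
)

# The published abstract excerpt (PMID 16704345) used as the worked example
# for the tokens-and-rules filter.
EXCERPT = (
    "Related enzymes are the ATP-dependent benzoyl-CoA reductase and the "
    "ATP-independent 4-hydroxybenzoyl-CoA reductase. Ketyl radical anions "
    "may also be generated by one-electron oxidation as shown by the flavin "
    "adenine dinucleotide (FAD)- and [4Fe-4S]-containing 4-hydroxybutyryl-CoA "
    "dehydratase."
)


@pytest.fixture
def excerpt_document() -> Document:
    return Document(
        doc_id="16704345",
        title="Radical enzymes in anaerobic aromatic metabolism",
        abstract=EXCERPT,
    )


@pytest.fixture
def excerpt_dictionary() -> ChemicalDictionary:
    return ChemicalDictionary(
        [
            ConceptEntry("M:adenine", "adenine", tree_numbers=("D03.100",)),
            ConceptEntry("M:bcoa", "benzoyl-CoA", tree_numbers=("D02.200",)),
            ConceptEntry("M:hbcoa", "4-hydroxybenzoyl-CoA", tree_numbers=("D02.201",)),
            ConceptEntry("M:hbutcoa", "4-hydroxybutyryl-CoA", tree_numbers=("D02.202",)),
        ]
    )


@pytest.fixture
def excerpt_tokens():
    return build_token_dictionary(
        [
            "flavin adenine dinucleotide",
            "benzoyl-CoA",
            "4-hydroxybenzoyl-CoA",
            "4-hydroxybutyryl-CoA",
        ]
    )


@pytest.fixture
def penicillin_dictionary() -> ChemicalDictionary:
    """A 2-level antibiotic tree plus a substance mapped into it."""
    return ChemicalDictionary(
        [
            ConceptEntry("D:anti", "antibiotic agents", tree_numbers=("D01",)),
            ConceptEntry("D:pen", "penicillins", tree_numbers=("D01.100",)),
            ConceptEntry("D:peng", "penicillin G", tree_numbers=("D01.100.200",)),
            ConceptEntry("D:penv", "penicillin V", tree_numbers=("D01.100.201",)),
            ConceptEntry("S:benzx", "benzylpenicillin X", mapped_concept_ids=("D:pen",)),
        ]
    )


# -- independent brute-force matching oracle ---------------------------------


def oracle_match_region(text: str, dictionary: ChemicalDictionary):
    """Test every substring against the name index; boundary-anchor; resolve
    longest-first then left-most (smallest id set breaks ties).

    Deliberately quadratic and index-lookup based, sharing no scanning code
    with the production matcher.
    """
    n = len(text)
    candidates = []
    for s in range(n):
        for e in range(s + 1, n + 1):
            sub = text[s:e]
            if sub != sub.strip():
                continue  # only trimmed spans are matchable surfaces
            ids = dictionary.lookup(sub)
            if not ids:
                continue
            before_ok = s == 0 or not text[s - 1].isalnum()
            after_ok = e == n or not text[e].isalnum()
            if before_ok and after_ok:
                candidates.append((s, e, frozenset(ids)))
    chosen = []
    for cand in sorted(
        candidates, key=lambda c: (-(c[1] - c[0]), c[0], tuple(sorted(c[2])))
    ):
        if all(cand[1] <= t[0] or cand[0] >= t[1] for t in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda c: c[0])


def oracle_match_document(doc: Document, dictionary: ChemicalDictionary):
    """Full-scope oracle: title plus each abstract sentence independently."""
    out = []
    out.extend(
        ("title", s, e, ids)
        for s, e, ids in oracle_match_region(doc.title, dictionary)
    )
    for ss, se in split_sentences(doc.abstract):
        segment = doc.abstract[ss:se]
        out.extend(
            ("abstract", ss + s, ss + e, ids)
            for s, e, ids in oracle_match_region(segment, dictionary)
        )
    return out


# -- random fixtures for the matcher oracle ----------------------------------

_NOISE_WORDS = (
    "the", "of", "and", "was", "in", "with", "seen", "during", "assay",
    "after", "control", "samples",
)
_NAME_PARTS = (
    "benz", "meth", "oxy", "chlor", "amin", "sulf", "prop", "acet",
    "CoA", "glyc", "hydro", "Fe",
)


def random_match_fixture(seed: int):
    """A random dictionary (<= 20 names) and text (<= 300 chars)."""
    rng = random.Random(seed)
    n_names = rng.randint(1, 20)
    names = set()
    while len(names) < n_names:
        parts = [rng.choice(_NAME_PARTS) for _ in range(rng.randint(1, 3))]
        joiner = rng.choice(("", "-", " "))
        name = joiner.join(parts)
        if name.strip():
            names.add(name)
    entries = [
        ConceptEntry(f"R{i:03d}", name, tree_numbers=(f"D{i:02d}",))
        for i, name in enumerate(sorted(names))
    ]
    # deliberately share one name between two concepts now and then
    if len(entries) >= 2 and rng.random() < 0.3:
        first = entries[0]
        entries[1] = ConceptEntry(
            entries[1].concept_id,
            entries[1].preferred_name,
            synonyms=(first.preferred_name,),
            tree_numbers=entries[1].tree_numbers,
        )
    dictionary = ChemicalDictionary(entries)

    words = []
    while sum(len(w) + 1 for w in words) < rng.randint(40, 280):
        roll = rng.random()
        if roll < 0.4:
            w = rng.choice(sorted(names))
            if rng.random() < 0.3:
                w = w.upper() if rng.random() < 0.5 else w.capitalize()
        elif roll < 0.5:
            w = rng.choice(_NAME_PARTS) + "-" + rng.choice(sorted(names))
        else:
            w = rng.choice(_NOISE_WORDS)
        words.append(w)
        if rng.random() < 0.15:
            words.append(rng.choice((",", ".", ";", "(FAD)")))
    text = " ".join(words)[:300]
    doc = Document(doc_id=f"rand{seed}", title="Fixture title", abstract=text or "x.")
    return dictionary, doc
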