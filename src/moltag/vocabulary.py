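"""Chemical concept vocabulary: loading, filtering, and token-dictionary construction.

The vocabulary is a flat dictionary of *concepts* (headings from a
hierarchical thesaurus plus supplementary "substance" records mapped onto
headings).  Every concept carries one preferred name and any number of
synonyms; a *name index* maps normalized surface strings back to the set of
concepts bearing them, preserving ambiguity.  Two dictionary-level
refinements are supported: restriction to concepts with an associated
chemical structure record, and augmentation with inorganic formulas
(e.g. "NaCl", "KOH") as extra synonyms.

Name normalization is lower-cased with internal whitespace collapsed,
except that names of three characters or fewer and formula names are
indexed case-sensitively: short strings and formulas are the dominant
homonym risk ("KOH" must match, "koh" must not).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ConceptEntry",
    "ChemicalDictionary",
    "TokenDictionary",
    "DictionaryFormatError",
    "normalize_name",
    "index_key",
    "load_dictionary",
    "apply_structure_filter",
    "add_formulas",
    "build_token_dictionary",
    "build_stoplist",
    "dissect_name",
]

#: maximum length at which a (non-formula) name is still indexed case-sensitively
CASE_SENSITIVE_MAX_LEN = 3

VALID_NAME_TYPES = ("heading", "synonym", "formula")

TSV_COLUMNS = (
    "concept_id",
    "name",
    "name_type",
    "tree_numbers",
    "structure_ids",
    "mapped_concept_ids",
)


class DictionaryFormatError(ValueError):
    """A malformed dictionary row; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def normalize_name(name: str) -> str:
    """Trim and collapse internal whitespace (case is left alone)."""
    return " ".join(name.split())


def index_key(name: str, *, is_formula: bool = False) -> str:
    """Index key for a surface name under the case policy."""
    norm = normalize_name(name)
    if is_formula or len(norm) <= CASE_SENSITIVE_MAX_LEN:
        return norm
    return norm.lower()


@dataclass(frozen=True)
class ConceptEntry:
    """One vocabulary concept.

    A concept with no tree numbers is a supplementary "substance" record and
    must be mapped onto at least one heading concept.  ``formula_names``
    marks which of its names were added as inorganic formulas.
    """

    concept_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    tree_numbers: tuple[str, ...] = ()
    structure_ids: tuple[str, ...] = ()
    mapped_concept_ids: tuple[str, ...] = ()
    formula_names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")
        for name in self.names:
            if not normalize_name(name):
                raise ValueError(
                    f"concept {self.concept_id!r}: empty name after trimming"
                )
        if self.is_substance and not self.mapped_concept_ids:
            raise ValueError(
                f"substance concept {self.concept_id!r} (no tree numbers) "
                "has no mapped concept ids"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return (self.preferred_name, *self.synonyms)

    @property
    def is_substance(self) -> bool:
        return not self.tree_numbers

    def is_formula_name(self, name: str) -> bool:
        return normalize_name(name) in self.formula_names

    @property
    def has_structure(self) -> bool:
        return bool(self.structure_ids)


class ChemicalDictionary:
    """A collection of :class:`ConceptEntry` with a normalized name index.

    One surface name may map to more than one concept; the ambiguity is
    preserved here and only resolved downstream (or never).
    """

    def __init__(self, entries: Iterable[ConceptEntry] = ()):
        self._entries: dict[str, ConceptEntry] = {}
        for entry in entries:
            if entry.concept_id in self._entries:
                raise ValueError(f"duplicate concept_id {entry.concept_id!r}")
            self._entries[entry.concept_id] = entry
        self._build_indexes()

    def _build_indexes(self) -> None:
        # case-insensitive and case-sensitive halves of the name index
        ci: dict[str, set[str]] = {}
        cs: dict[str, set[str]] = {}
        tree: dict[str, str] = {}
        for entry in self._entries.values():
            for name in entry.names:
                formula = entry.is_formula_name(name)
                key = index_key(name, is_formula=formula)
                target = cs if (formula or len(key) <= CASE_SENSITIVE_MAX_LEN) else ci
                target.setdefault(key, set()).add(entry.concept_id)
            for tn in entry.tree_numbers:
                tree[tn] = entry.concept_id
        self._ci_index = {k: frozenset(v) for k, v in ci.items()}
        self._cs_index = {k: frozenset(v) for k, v in cs.items()}
        self._tree_index = tree

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ConceptEntry]:
        return iter(self._entries.values())

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._entries

    def concept(self, concept_id: str) -> ConceptEntry:
        try:
            return self._entries[concept_id]
        except KeyError:
            raise KeyError(f"unknown concept_id {concept_id!r}") from None

    @property
    def concept_ids(self) -> tuple[str, ...]:
        return tuple(self._entries)

    @property
    def name_index(self) -> Mapping[str, frozenset[str]]:
        """Normalized surface name -> concept ids bearing it."""
        merged = dict(self._ci_index)
        merged.update(self._cs_index)
        return merged

    @property
    def case_insensitive_index(self) -> Mapping[str, frozenset[str]]:
        return self._ci_index

    @property
    def case_sensitive_index(self) -> Mapping[str, frozenset[str]]:
        return self._cs_index

    def concept_for_tree_number(self, tree_number: str) -> str | None:
        return self._tree_index.get(tree_number)

    def all_names(self) -> list[str]:
        return [name for entry in self for name in entry.names]

    def lookup(self, surface: str) -> frozenset[str]:
        """Concept ids whose name matches ``surface`` under the case policy."""
        norm = normalize_name(surface)
        ids: frozenset[str] = self._cs_index.get(norm, frozenset())
        ids |= self._ci_index.get(norm.lower(), frozenset())
        return ids


# -- loading ----------------------------------------------------------------


def _split_multi(value: str) -> tuple[str, ...]:
    return tuple(part for part in value.split(";") if part)


def _rows_from_tsv(path: Path) -> Iterator[tuple[int, dict[str, str]]]:
    with open(path, encoding="utf-8") as handle:
        header_line = handle.readline()
        if not header_line:
            return
        header = tuple(header_line.rstrip("\n").split("\t"))
        if header != TSV_COLUMNS:
            raise DictionaryFormatError(
                f"expected header {list(TSV_COLUMNS)}, got {list(header)}", line=1
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise DictionaryFormatError(
                    f"expected {len(TSV_COLUMNS)} tab-separated fields, "
                    f"got {len(fields)}",
                    line=lineno,
                )
            yield lineno, dict(zip(TSV_COLUMNS, fields))


def _rows_from_jsonl(path: Path) -> Iterator[tuple[int, dict[str, str]]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip():
                continue
            try:
                record = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise DictionaryFormatError(f"invalid JSON: {exc}", line=lineno)
            row = {
                "concept_id": str(record.get("concept_id", "")),
                "name": str(record.get("name", "")),
                "name_type": str(record.get("name_type", "heading")),
                "tree_numbers": ";".join(record.get("tree_numbers", []) or []),
                "structure_ids": ";".join(record.get("structure_ids", []) or []),
                "mapped_concept_ids": ";".join(
                    record.get("mapped_concept_ids", []) or []
                ),
            }
            yield lineno, row


def load_dictionary(path: str | Path, dialect: str = "tsv") -> ChemicalDictionary:
    """Load a dictionary from the TSV or JSONL dialect (one row per name).

    Malformed rows raise :class:`DictionaryFormatError` naming the line;
    nothing is skipped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        rows = _rows_from_tsv(path)
    elif dialect == "jsonl":
        rows = _rows_from_jsonl(path)
    else:
        raise ValueError(f"unknown dictionary dialect {dialect!r}")

    # accumulate per concept; exactly one heading row is required per concept
    order: list[str] = []
    heading: dict[str, str] = {}
    first_line: dict[str, int] = {}
    synonyms: dict[str, list[str]] = {}
    formulas: dict[str, set[str]] = {}
    tree_numbers: dict[str, list[str]] = {}
    structure_ids: dict[str, list[str]] = {}
    mapped_ids: dict[str, list[str]] = {}

    for lineno, row in rows:
        cid = row["concept_id"].strip()
        name = normalize_name(row["name"])
        ntype = row["name_type"].strip()
        if not cid:
            raise DictionaryFormatError("empty concept_id", line=lineno)
        if not name:
            raise DictionaryFormatError(
                f"empty name for concept {cid!r}", line=lineno
            )
        if ntype not in VALID_NAME_TYPES:
            raise DictionaryFormatError(
                f"invalid name_type {ntype!r} (expected one of {VALID_NAME_TYPES})",
                line=lineno,
            )
        if cid not in order:
            order.append(cid)
            first_line[cid] = lineno
            synonyms[cid] = []
            formulas[cid] = set()
            tree_numbers[cid] = []
            structure_ids[cid] = []
            mapped_ids[cid] = []
        if ntype == "heading":
            if cid in heading:
                raise DictionaryFormatError(
                    f"duplicate heading row for concept {cid!r}", line=lineno
                )
            heading[cid] = name
        else:
            synonyms[cid].append(name)
            if ntype == "formula":
                formulas[cid].add(name)
        for tn in _split_multi(row["tree_numbers"]):
            if tn not in tree_numbers[cid]:
                tree_numbers[cid].append(tn)
        for sid in _split_multi(row["structure_ids"]):
            if sid not in structure_ids[cid]:
                structure_ids[cid].append(sid)
        for mid in _split_multi(row["mapped_concept_ids"]):
            if mid not in mapped_ids[cid]:
                mapped_ids[cid].append(mid)

    entries = []
    for cid in order:
        if cid not in heading:
            raise DictionaryFormatError(
                f"concept {cid!r} has no heading row", line=first_line[cid]
            )
        try:
            entries.append(
                ConceptEntry(
                    concept_id=cid,
                    preferred_name=heading[cid],
                    synonyms=tuple(
                        s for s in synonyms[cid] if s != heading[cid]
                    ),
                    tree_numbers=tuple(tree_numbers[cid]),
                    structure_ids=tuple(structure_ids[cid]),
                    mapped_concept_ids=tuple(mapped_ids[cid]),
                    formula_names=frozenset(formulas[cid]),
                )
            )
        except ValueError as exc:
            raise DictionaryFormatError(str(exc), line=first_line[cid]) from exc
    return ChemicalDictionary(entries)


def save_dictionary(dictionary: ChemicalDictionary, path: str | Path) -> None:
    """Write the TSV dialect (one row per name, concept metadata on each row)."""
    lines = ["\t".join(TSV_COLUMNS)]
    for entry in dictionary:
        meta = (
            ";".join(entry.tree_numbers),
            ";".join(entry.structure_ids),
            ";".join(entry.mapped_concept_ids),
        )
        for i, name in enumerate(entry.names):
            if i == 0:
                ntype = "heading"
            elif entry.is_formula_name(name):
                ntype = "formula"
            else:
                ntype = "synonym"
            lines.append("\t".join((entry.concept_id, name, ntype, *meta)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- dictionary-level refinements -------------------------------------------


def apply_structure_filter(dictionary: ChemicalDictionary) -> ChemicalDictionary:
    """Keep only concepts with an associated structure record.

    Restricting the vocabulary to names that denote an actual small-molecule
    structure removes protein names, category headings and other
    non-specific terms; on a full thesaurus this discards roughly two thirds
    of the concepts.  Idempotent; the result's entries are a subset of the
    input's.
    """
    return ChemicalDictionary(e for e in dictionary if e.has_structure)


def add_formulas(
    dictionary: ChemicalDictionary,
    formulas: Iterable[tuple[str, str]],
) -> ChemicalDictionary:
    """Add inorganic formulas as case-sensitive synonyms of existing concepts.

    ``formulas`` is an iterable of ``(formula_text, concept_id)``.  Adding a
    formula already present on the concept is a no-op (idempotent).
    """
    updates: dict[str, ConceptEntry] = {}
    for formula, cid in formulas:
        norm = normalize_name(formula)
        if not norm:
            raise ValueError(f"empty formula for concept {cid!r}")
        if cid not in dictionary:
            raise KeyError(
                f"formula {formula!r} names unknown concept {cid!r}"
            )
        entry = updates.get(cid, dictionary.concept(cid))
        if norm in {normalize_name(n) for n in entry.names}:
            continue  # already a name of this concept: no-op (idempotent)
        updates[cid] = replace(
            entry,
            synonyms=(*entry.synonyms, norm),
            formula_names=entry.formula_names | {norm},
        )
    return ChemicalDictionary(
        updates.get(e.concept_id, e) for e in dictionary
    )


# -- token dictionary --------------------------------------------------------

#: separators at which chemical names are dissected into tokens
_SEPARATOR_RE = re.compile(r"[\s,;()\[\]/]+")
#: numeric identifier: a single letter with trailing digits, total length <= 3
_NUMERIC_ID_RE = re.compile(r"^[^\W\d_]\d{1,2}$")
_ALPHA_RE = re.compile(r"[^\W\d_]")


@dataclass(frozen=True)
class TokenDictionary:
    """Normalized fragments of chemical names ("chemical tokens").

    Used to judge whether a matched term is embedded in a longer chemical
    name.  Contains no stoplist words, no single characters, and no purely
    numeric or special-character strings.
    """

    tokens: frozenset[str] = frozenset()
    stoplist_size: int = 0

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.tokens

    def __len__(self) -> int:
        return len(self.tokens)


def _is_token_noise(token: str) -> bool:
    if len(token) < 2:
        return True
    if not _ALPHA_RE.search(token):
        # pure numbers, digit-punctuation mixes, special characters
        return True
    if len(token) <= 3 and _NUMERIC_ID_RE.match(token):
        # numeric identifier such as "h2" used as a locant/label
        return True
    return False


def dissect_name(name: str) -> list[str]:
    """Dissect one name into lower-cased candidate tokens.

    Splits at whitespace, comma, semicolon, parentheses, square brackets and
    slash.  Hyphens are kept inside tokens, and each hyphen-delimited
    fragment of length >= 2 is additionally emitted.
    """
    out: list[str] = []
    for fragment in _SEPARATOR_RE.split(name.lower()):
        if not fragment:
            continue
        out.append(fragment)
        if "-" in fragment:
            out.extend(p for p in fragment.split("-") if len(p) >= 2)
    return out


def build_token_dictionary(
    names: Iterable[str], stoplist: Iterable[str] = ()
) -> TokenDictionary:
    """Build the chemical-token dictionary from a list of names.

    Common English words (the stoplist), pure numbers, numeric identifiers,
    single characters and special-character-only fragments are removed.
    """
    stop = {w.lower() for w in stoplist}
    candidates: set[str] = set()
    for name in names:
        candidates.update(dissect_name(name))
    removed_common = candidates & stop
    tokens = frozenset(
        t for t in candidates - stop if not _is_token_noise(t)
    )
    return TokenDictionary(tokens=tokens, stoplist_size=len(removed_common))


_WORD_RE = re.compile(r"[^\W\d_]+")


def build_stoplist(corpus_text: str) -> set[str]:
    """Lower-cased alphabetic word types of a plain text.

    Any public-domain English prose works; the resulting set is used to keep
    common words out of the chemical-token dictionary.
    """
    return {m.group(0).lower() for m in _WORD_RE.finditer(corpus_text)}


def read_wordlist(path: str | Path) -> list[str]:
    """Read a plain-text word list (one entry per line, '#' comments)."""
    out: list[str] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line)
    return out


def write_wordlist(words: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(sorted(set(words))) + "\n", encoding="utf-8"
    )
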