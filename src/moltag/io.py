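"""Corpus and annotation I/O: JSONL, MEDLINE-style text, PubTator-style TSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from .annotator import Document, Mention

__all__ = [
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_corpus_medline",
    "read_corpus",
    "write_mentions_tsv",
    "read_mentions_tsv",
]


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    """One JSON record per line: doc_id, title, abstract, optional gold_concepts."""
    docs = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip():
            continue
        try:
            rec = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: line {lineno}: invalid JSON: {exc}")
        gold = rec.get("gold_concepts")
        docs.append(
            Document(
                doc_id=str(rec["doc_id"]),
                title=rec.get("title", ""),
                abstract=rec.get("abstract", ""),
                gold_concepts=frozenset(gold) if gold is not None else None,
            )
        )
    return docs


def write_corpus_jsonl(corpus: Iterable[Document], path: str | Path) -> None:
    lines = []
    for doc in corpus:
        rec: dict = {
            "doc_id": doc.doc_id,
            "title": doc.title,
            "abstract": doc.abstract,
        }
        if doc.gold_concepts is not None:
            rec["gold_concepts"] = sorted(doc.gold_concepts)
        lines.append(json.dumps(rec, sort_keys=True))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_corpus_medline(path: str | Path) -> list[Document]:
    """MEDLINE-style field-tagged text: records separated by blank lines,
    ``PMID-``/``TI  -``/``AB  -`` tags, continuation lines indented."""
    docs = []
    record: dict[str, list[str]] = {}
    current: str | None = None

    def flush() -> None:
        nonlocal record, current
        if record:
            docs.append(
                Document(
                    doc_id=" ".join(record.get("PMID", [""])).strip(),
                    title=" ".join(record.get("TI", [])).strip(),
                    abstract=" ".join(record.get("AB", [])).strip(),
                )
            )
        record, current = {}, None

    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip():
            flush()
            continue
        if raw[:1].isspace():  # continuation line
            if current is not None:
                record.setdefault(current, []).append(raw.strip())
            continue
        if "-" not in raw:
            raise ValueError(f"malformed MEDLINE line: {raw!r}")
        tag, _, value = raw.partition("-")
        current = tag.strip()
        record.setdefault(current, []).append(value.strip())
    flush()
    return docs


def read_corpus(path: str | Path, fmt: str = "jsonl") -> list[Document]:
    if fmt == "jsonl":
        return read_corpus_jsonl(path)
    if fmt == "medline":
        return read_corpus_medline(path)
    raise ValueError(f"unknown corpus format {fmt!r}")


MENTION_COLUMNS = (
    "doc_id",
    "start",
    "end",
    "surface",
    "type",
    "concept_ids",
    "region",
    "status",
)


def write_mentions_tsv(mentions: Sequence[Mention], path: str | Path) -> None:
    """PubTator-style TSV with an audit status column
    (``kept`` or ``filtered:<stage>``)."""
    lines = ["\t".join(MENTION_COLUMNS)]
    for m in sorted(mentions, key=lambda m: m.key()):
        lines.append(
            "\t".join(
                (
                    m.doc_id,
                    str(m.start),
                    str(m.end),
                    m.surface,
                    "Chemical",
                    ";".join(sorted(m.concept_ids)),
                    m.region,
                    m.status,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_mentions_tsv(path: str | Path) -> list[dict]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != MENTION_COLUMNS:
        raise ValueError(f"{path}: not a mention TSV (bad header)")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = dict(zip(MENTION_COLUMNS, line.split("\t")))
        fields["start"] = int(fields["start"])
        fields["end"] = int(fields["end"])
        fields["concept_ids"] = set(
            c for c in fields["concept_ids"].split(";") if c
        )
        out.append(fields)
    return out
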