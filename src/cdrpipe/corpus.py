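"""PubTator-format corpus I/O and the shared document data model.

A corpus is a sequence of records; each record is a title line ``id|t|...``,
an abstract line ``id|a|...``, zero or more tab-separated mention lines
(``id<TAB>start<TAB>end<TAB>text<TAB>type<TAB>conceptID``), zero or more
relation lines (``id<TAB>CID<TAB>chemID<TAB>disID``) and a blank separator
line.  Mention offsets are 0-based half-open character offsets over
``title + " " + abstract`` (the separator occupies one offset position).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable

from ._text import canonicalize

__all__ = [
    "EntityType",
    "Mention",
    "Relation",
    "Document",
    "DictionaryEntry",
    "NameCandidateList",
    "PubtatorError",
    "parse_pubtator",
    "write_pubtator",
    "load_dictionary",
    "load_candidate_lists",
    "load_knowledge",
]

UNMAPPED = "-1"


class EntityType(str, Enum):
    CHEMICAL = "Chemical"
    DISEASE = "Disease"


class CandidateSource(str, Enum):
    MESH_SEARCH = "MESH_SEARCH"
    WIKIPEDIA = "WIKIPEDIA"


class PubtatorError(ValueError):
    """Malformed PubTator input (carries the offending line number or doc id)."""


@dataclass
class Mention:
    doc_id: str
    start: int
    end: int
    text: str
    etype: EntityType
    concept_id: str = UNMAPPED

    def __post_init__(self) -> None:
        self.etype = EntityType(self.etype)
        if self.start >= self.end:
            raise ValueError(f"empty mention span ({self.start}, {self.end})")

    def overlaps(self, other: "Mention") -> bool:
        return self.start < other.end and other.start < self.end

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Relation:
    doc_id: str
    chemical_id: str
    disease_id: str

    def __post_init__(self) -> None:
        if not self.chemical_id or not self.disease_id:
            raise ValueError("relation IDs must be non-empty")
        if UNMAPPED in (self.chemical_id, self.disease_id):
            raise ValueError("relation IDs may not be the unmapped sentinel")


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Title and abstract joined by the single separator character."""
        return self.title + " " + self.abstract

    def validate(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        text = self.text
        for m in self.mentions:
            if not (0 <= m.start < m.end <= len(text)):
                raise PubtatorError(
                    f"doc {self.doc_id}: mention span {m.span} outside document"
                )
            if text[m.start : m.end] != m.text:
                raise PubtatorError(
                    f"doc {self.doc_id}: mention text {m.text!r} does not match "
                    f"document slice {text[m.start:m.end]!r} at {m.span}"
                )


@dataclass
class DictionaryEntry:
    surface_name: str
    concept_id: str
    etype: EntityType
    normalized_key: str = ""

    def __post_init__(self) -> None:
        self.etype = EntityType(self.etype)
        if not self.concept_id:
            raise ValueError("dictionary concept_id must be non-empty")
        if not self.normalized_key:
            self.normalized_key = canonicalize(self.surface_name)


@dataclass
class NameCandidateList:
    mention_text: str
    source: CandidateSource
    candidates: list[str] = field(default_factory=list)


def _as_lines(stream: IO[str] | str) -> Iterable[tuple[int, str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for i, line in enumerate(stream, start=1):
        yield i, line.rstrip("\n")


def parse_pubtator(stream: IO[str] | str) -> list[Document]:
    """Parse a PubTator stream into :class:`Document` objects.

    Raises :class:`PubtatorError` naming the line number for malformed lines
    and the doc id for mention/offset integrity failures.  Mentions are sorted
    by start offset.
    """
    docs: list[Document] = []
    cur: Document | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None:
            cur.mentions.sort(key=lambda m: (m.start, m.end))
            cur.validate()
            docs.append(cur)
            cur = None

    for lineno, line in _as_lines(stream):
        if not line.strip():
            flush()
            continue
        if "|t|" in line or "|a|" in line:
            doc_id, kind, text = line.split("|", 2)
            if kind == "t":
                flush()
                cur = Document(doc_id=doc_id, title=text, abstract="")
            elif kind == "a":
                if cur is None or cur.doc_id != doc_id:
                    raise PubtatorError(f"line {lineno}: abstract without title")
                cur.abstract = text
            else:  # pragma: no cover - unreachable given the `in` guard
                raise PubtatorError(f"line {lineno}: unknown section {kind!r}")
            continue
        fields = line.split("\t")
        if cur is None:
            raise PubtatorError(f"line {lineno}: annotation before any document")
        if len(fields) == 4 and fields[1] == "CID":
            doc_id, _, chem, dis = fields
            try:
                cur.relations.append(Relation(doc_id, chem, dis))
            except ValueError as exc:
                raise PubtatorError(f"line {lineno}: {exc}") from exc
        elif len(fields) in (5, 6):
            doc_id, start, end, text, etype = fields[:5]
            concept = fields[5] if len(fields) == 6 else UNMAPPED
            try:
                cur.mentions.append(
                    Mention(doc_id, int(start), int(end), text, etype, concept)
                )
            except ValueError as exc:
                raise PubtatorError(f"line {lineno}: {exc}") from exc
        else:
            raise PubtatorError(f"line {lineno}: malformed annotation line {line!r}")
    flush()
    return docs


def write_pubtator(docs: Iterable[Document], stream: IO[str]) -> None:
    """Serialize documents; refuses documents violating invariants."""
    for doc in docs:
        doc.validate()
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in sorted(doc.mentions, key=lambda m: (m.start, m.end)):
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t"
                f"{m.etype.value}\t{m.concept_id}\n"
            )
        for r in doc.relations:
            stream.write(f"{doc.doc_id}\tCID\t{r.chemical_id}\t{r.disease_id}\n")
        stream.write("\n")


def dumps_pubtator(docs: Iterable[Document]) -> str:
    buf = io.StringIO()
    write_pubtator(docs, buf)
    return buf.getvalue()


def load_dictionary(stream: IO[str] | str) -> list[DictionaryEntry]:
    """Load a ``surface<TAB>concept_id<TAB>type`` dictionary TSV."""
    entries: list[DictionaryEntry] = []
    for lineno, line in _as_lines(stream):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise PubtatorError(
                f"line {lineno}: dictionary rows need 3 columns, got {len(fields)}"
            )
        surface, concept_id, etype = fields
        entries.append(DictionaryEntry(surface, concept_id, etype))
    return entries


def load_candidate_lists(
    stream: IO[str] | str,
) -> dict[tuple[str, CandidateSource], NameCandidateList]:
    """Load candidate-list TSV ``mention<TAB>source<TAB>rank<TAB>candidate``.

    Lists stand in for the MeSH WebSearch / Wikipedia look-ups; keys are the
    canonicalized mention text plus source, candidates ordered by rank.
    """
    rows: dict[tuple[str, CandidateSource], list[tuple[int, str]]] = {}
    for lineno, line in _as_lines(stream):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise PubtatorError(
                f"line {lineno}: candidate rows need 4 columns, got {len(fields)}"
            )
        text, source, rank, name = fields
        key = (canonicalize(text), CandidateSource(source))
        rows.setdefault(key, []).append((int(rank), name))
    out: dict[tuple[str, CandidateSource], NameCandidateList] = {}
    for (text, source), ranked in rows.items():
        ranked.sort()
        out[(text, source)] = NameCandidateList(
            mention_text=text, source=source, candidates=[n for _, n in ranked]
        )
    return out


def load_knowledge(stream: IO[str] | str) -> set[tuple[str, str]]:
    """Load known (chemical_id, disease_id) pairs from a two-column TSV."""
    pairs: set[tuple[str, str]] = set()
    for lineno, line in _as_lines(stream):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise PubtatorError(
                f"line {lineno}: knowledge rows need 2 columns, got {len(fields)}"
            )
        pairs.add((fields[0], fields[1]))
    return pairs
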