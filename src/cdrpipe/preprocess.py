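"""Sentence boundary detection, tokenization and POS tagging.

Turns a :class:`~cdrpipe.corpus.Document` into :class:`TaggedSentence` units,
the input of the sequence labelers.  The tokenizer is rule-based: whitespace
split, leading/trailing punctuation split off, slashes and commas always
split, internal hyphens and digits kept together (so multi-part chemical
names like ``5-fluorouracil`` stay one token while ``(CAD)`` exposes the
abbreviation).  The POS tagger is a deterministic lexicon + suffix-rule
tagger; the backend is pluggable via config so a heavier model can be
substituted without touching feature extraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .corpus import Document

__all__ = [
    "Token",
    "Section",
    "TaggedSentence",
    "split_sentences",
    "tokenize",
    "pos_tag",
    "preprocess_document",
]


class Section(str, Enum):
    TITLE = "TITLE"
    ABSTRACT = "ABSTRACT"


@dataclass
class Token:
    text: str
    start: int
    end: int
    pos: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty token span")


@dataclass
class TaggedSentence:
    doc_id: str
    sent_index: int
    section: Section
    tokens: list[Token]
    char_span: tuple[int, int]


# Word token: alnum runs glued by internal hyphen/apostrophe/period
# (keeps 5-fluorouracil, O'Brien, i.v); anything else is a 1-char token,
# so slashes, commas and brackets always split.
_TOKEN_RE = re.compile(r"[A-Za-z0-9±α-ω]+(?:[-'.][A-Za-z0-9α-ω]+)*|\S")

# Sentence terminator followed by whitespace and an upper-case/digit/paren
# opener.  Splitting is suppressed inside parentheses and after stop-list
# abbreviations.
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[\"'(\[]?[A-Z0-9])")

_ABBREV_STOPLIST = frozenset(
    {
        "e.g", "i.e", "i.v", "i.m", "i.p", "p.o", "et al", "vs", "fig", "figs",
        "dr", "mr", "mrs", "ms", "st", "no", "approx", "ca", "cf", "resp",
    }
)


def _split_text(text: str, base: int) -> list[tuple[int, int]]:
    """Offsets of sentences inside ``text``; ``base`` shifts to doc coords."""
    spans: list[tuple[int, int]] = []
    start = 0
    depth = 0
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
        elif depth == 0:
            m = _BOUNDARY_RE.match(text, pos)
            if m is not None:
                prev = re.search(r"[\w.]+$", text[start:pos])
                word = prev.group(0).casefold().rstrip(".") if prev else ""
                if word not in _ABBREV_STOPLIST:
                    spans.append((start, m.end()))
                    start = m.end()
                    pos = m.end()
                    while pos < len(text) and text[pos].isspace():
                        pos += 1
                    start = pos
                    continue
        pos += 1
    tail = text[start:].strip()
    if tail:
        first = start + (len(text[start:]) - len(text[start:].lstrip()))
        spans.append((first, first + len(text[start:].strip()) + 0))
        spans[-1] = (first, first + len(tail))
    # trim trailing whitespace from non-final spans
    out = []
    for s, e in spans:
        seg = text[s:e]
        s += len(seg) - len(seg.lstrip())
        e -= len(seg) - len(seg.rstrip())
        if e > s:
            out.append((s + base, e + base))
    return out


def split_sentences(doc: Document) -> list[tuple[tuple[int, int], Section]]:
    """Sentence character spans over the document coordinate system.

    The title is always segmented separately, so no sentence ever crosses the
    title/abstract boundary.
    """
    spans: list[tuple[tuple[int, int], Section]] = []
    for span in _split_text(doc.title, 0):
        spans.append((span, Section.TITLE))
    for span in _split_text(doc.abstract, len(doc.title) + 1):
        spans.append((span, Section.ABSTRACT))
    return spans


def tokenize(sentence_text: str, offset_base: int = 0) -> list[Token]:
    """Tokenize one sentence; offsets are absolute (document coordinates)."""
    return [
        Token(m.group(0), offset_base + m.start(), offset_base + m.end())
        for m in _TOKEN_RE.finditer(sentence_text)
    ]


_LEXICON = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "that": "DT", "those": "DT", "each": "DT", "no": "DT", "some": "DT",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "with": "IN",
    "for": "IN", "to": "TO", "from": "IN", "after": "IN", "before": "IN",
    "during": "IN", "between": "IN", "without": "IN", "under": "IN",
    "into": "IN", "through": "IN", "following": "IN", "within": "IN",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "can": "MD", "may": "MD", "should": "MD", "could": "MD", "will": "MD",
    "not": "RB", "also": "RB", "however": "RB", "subsequently": "RB",
    "we": "PRP", "it": "PRP", "he": "PRP", "she": "PRP", "they": "PRP",
    "patient": "NN", "patients": "NNS", "case": "NN", "cases": "NNS",
    "who": "WP", "which": "WDT", "whom": "WP",
}

_SUFFIX_RULES: list[tuple[str, str]] = [
    ("ly", "RB"),
    ("ing", "VBG"),
    ("ed", "VBD"),
    ("ous", "JJ"),
    ("ive", "JJ"),
    ("al", "JJ"),
    ("ic", "JJ"),
    ("able", "JJ"),
    ("est", "JJS"),
    ("er", "JJR"),
    ("s", "NNS"),
]

_DIGIT_RE = re.compile(r"^[\d.,:%-]*\d[\d.,:%-]*$")


def _tag_one(text: str) -> str:
    lower = text.casefold()
    if lower in _LEXICON:
        return _LEXICON[lower]
    if _DIGIT_RE.match(text):
        return "CD"
    if not any(c.isalnum() for c in text):
        return "PUNCT"
    if len(text) > 3:
        for suffix, tag in _SUFFIX_RULES:
            if lower.endswith(suffix) and len(lower) > len(suffix) + 1:
                if suffix == "s" and lower.endswith(("ss", "us", "is")):
                    continue
                return tag
    return "NN"


def pos_tag(tokens: list[Token]) -> list[Token]:
    """Fill ``pos`` in place (and return the list) with deterministic tags."""
    for tok in tokens:
        tok.pos = _tag_one(tok.text)
    return tokens


def preprocess_document(doc: Document, backend: str = "lexicon") -> list[TaggedSentence]:
    """Full preprocessing: sentences, tokens, POS tags.

    ``backend`` selects the POS tagger; only the deterministic ``lexicon``
    backend ships with the package.
    """
    if backend != "lexicon":
        raise ValueError(f"unknown POS backend {backend!r}")
    text = doc.text
    sentences: list[TaggedSentence] = []
    for i, (span, section) in enumerate(split_sentences(doc)):
        toks = tokenize(text[span[0] : span[1]], offset_base=span[0])
        pos_tag(toks)
        sentences.append(
            TaggedSentence(
                doc_id=doc.doc_id,
                sent_index=i,
                section=section,
                tokens=toks,
                char_span=span,
            )
        )
    return sentences
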