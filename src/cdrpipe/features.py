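"""Token-in-context feature extraction shared by both sequence labelers.

One extractor instance feeds both the CRF and the margin-based tagger, so
the two models see byte-identical feature keys by construction.  Families
(key namespaces):

``bow:``   token uni/bi/trigrams in a +/-2 window
``pos:``   POS uni/bi/trigrams
``wp:``    the fixed list of token x POS index combinations
``sent:``  sentence length bucket, unmatched-bracket flag
``pre*/suf*:`` affixes of length 1..5
``orth:``  closed orthographic predicate set
``shape:`` positional and run-collapsed word shapes
``sec:``   title/abstract section
``dict:``  gazetteer longest-match begin/inside flags
``freq:``  corpus frequency/IDF threshold flag
``cg:``    character n-grams (n = 1..4)
``rep:``   optional word-representation cluster ids
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._text import canonicalize
from .corpus import DictionaryEntry, Document, EntityType
from .preprocess import Section, TaggedSentence

__all__ = [
    "PAD",
    "word_shape",
    "affixes",
    "char_ngrams",
    "Gazetteer",
    "FrequencyModel",
    "WordRepModel",
    "FeatureExtractor",
]

PAD = "__PAD__"

FeatureDict = dict[str, float]


def word_shape(token_text: str) -> tuple[str, str]:
    """Positional and run-collapsed character-class shapes.

    Upper-case letters map to ``A``, lower-case to ``a``, digits to ``#`` and
    anything else to ``-``; the collapsed variant merges consecutive runs of
    the same class.
    """
    full = []
    for ch in token_text:
        if ch.isalpha():
            full.append("A" if ch.isupper() else "a")
        elif ch.isdigit():
            full.append("#")
        else:
            full.append("-")
    collapsed = [full[0]] if full else []
    for c in full[1:]:
        if c != collapsed[-1]:
            collapsed.append(c)
    return "".join(full), "".join(collapsed)


def affixes(token_text: str) -> FeatureDict:
    """Prefixes and suffixes of length 1..5 (capped by token length)."""
    out: FeatureDict = {}
    for n in range(1, min(len(token_text), 5) + 1):
        out[f"pre{n}:{token_text[:n]}"] = 1.0
        out[f"suf{n}:{token_text[-n:]}"] = 1.0
    return out


def char_ngrams(token_text: str, max_n: int = 4) -> FeatureDict:
    out: FeatureDict = {}
    for n in range(1, max_n + 1):
        for i in range(len(token_text) - n + 1):
            out[f"cg{n}:{token_text[i : i + n]}"] = 1.0
    return out


_GREEK = frozenset(
    "alpha beta gamma delta epsilon kappa lambda omega sigma theta".split()
)


def _orthographic(token_text: str) -> FeatureDict:
    t = token_text
    preds = {
        "allcaps": t.isupper() and any(c.isalpha() for c in t),
        "initcap": t[:1].isupper(),
        "innercap": any(c.isupper() for c in t[1:]),
        "hasdigit": any(c.isdigit() for c in t),
        "alldigit": t.isdigit(),
        "hyphen": "-" in t,
        "slash": "/" in t,
        "punct": not any(c.isalnum() for c in t),
        "greek": t.casefold() in _GREEK or "α" <= t[:1] <= "ω",
    }
    return {f"orth:{name}": 1.0 for name, on in preds.items() if on}


class Gazetteer:
    """Entity-name dictionary supporting longest token-sequence matching."""

    def __init__(self, etype: EntityType, names: Iterable[str]):
        self.etype = EntityType(etype)
        self.entries: set[tuple[str, ...]] = set()
        self.max_len = 0
        for name in names:
            toks = tuple(canonicalize(name).split())
            if toks:
                self.entries.add(toks)
                self.max_len = max(self.max_len, len(toks))

    @classmethod
    def from_entries(
        cls, entries: Iterable[DictionaryEntry], etype: EntityType
    ) -> "Gazetteer":
        etype = EntityType(etype)
        return cls(etype, (e.surface_name for e in entries if e.etype == etype))

    def match_flags(self, token_texts: Sequence[str]) -> list[str | None]:
        """Per-token ``"B"``/``"I"``/None flags from greedy longest matches."""
        keys = [canonicalize(t) for t in token_texts]
        flags: list[str | None] = [None] * len(keys)
        i = 0
        while i < len(keys):
            best = 0
            for n in range(min(self.max_len, len(keys) - i), 0, -1):
                if tuple(keys[i : i + n]) in self.entries:
                    best = n
                    break
            if best:
                flags[i] = "B"
                for j in range(i + 1, i + best):
                    flags[j] = "I"
                i += best
            else:
                i += 1
        return flags


@dataclass
class FrequencyModel:
    """Corpus term-frequency / normalized-IDF model behind the frequency flag.

    The flag fires when a token's case-folded corpus frequency exceeds
    ``freq_threshold`` (default 4) while its normalized inverse document
    frequency, ``log(N/df)/log(N)``, falls below ``idf_threshold``
    (default 0.1) — i.e. the token is a frequent, widely spread corpus word.
    """

    freq_threshold: int = 4
    idf_threshold: float = 0.1
    term_freq: dict[str, int] = field(default_factory=dict)
    idf: dict[str, float] = field(default_factory=dict)

    def fit(self, docs_tokens: Sequence[Sequence[str]]) -> "FrequencyModel":
        """Fit from one token-text sequence per training document."""
        self.term_freq = {}
        doc_freq: dict[str, int] = {}
        n_docs = max(len(docs_tokens), 1)
        for toks in docs_tokens:
            folded = [t.casefold() for t in toks]
            for t in folded:
                self.term_freq[t] = self.term_freq.get(t, 0) + 1
            for t in set(folded):
                doc_freq[t] = doc_freq.get(t, 0) + 1
        denom = math.log(n_docs) if n_docs > 1 else 1.0
        self.idf = {
            t: (math.log(n_docs / df) / denom) if n_docs > 1 else 0.0
            for t, df in doc_freq.items()
        }
        return self

    def flag(self, token_text: str) -> bool:
        t = token_text.casefold()
        return (
            self.term_freq.get(t, 0) > self.freq_threshold
            and self.idf.get(t, 1.0) < self.idf_threshold
        )


@dataclass
class WordRepModel:
    """Optional word-representation features (cluster ids per token).

    ``brown_paths`` maps a token to its Brown-style bit-string path (features
    use prefixes of length 4, 6 and 10); ``embedding_clusters`` maps a token
    to a flat cluster id.  Both are trained on the corpus being processed when
    enabled; the family is off when the model is absent.
    """

    brown_paths: dict[str, str] = field(default_factory=dict)
    embedding_clusters: dict[str, int] = field(default_factory=dict)
    prefix_lengths: tuple[int, ...] = (4, 6, 10)

    def features(self, token_text: str) -> FeatureDict:
        out: FeatureDict = {}
        t = token_text.casefold()
        path = self.brown_paths.get(t)
        if path is not None:
            for n in self.prefix_lengths:
                out[f"rep:brown{n}:{path[:n]}"] = 1.0
        cluster = self.embedding_clusters.get(t)
        if cluster is not None:
            out[f"rep:emb:{cluster}"] = 1.0
        return out


def _sent_len_bucket(n: int) -> str:
    if n <= 10:
        return "<=10"
    if n <= 25:
        return "11-25"
    if n <= 40:
        return "26-40"
    return ">40"


def _unmatched_bracket(token_texts: Sequence[str]) -> bool:
    depth = 0
    unmatched = False
    for t in token_texts:
        for ch in t:
            if ch in "([{":
                depth += 1
            elif ch in ")]}":
                if depth == 0:
                    unmatched = True
                else:
                    depth -= 1
    return unmatched or depth > 0


# token x POS index combinations, implemented verbatim from the system's
# published feature table (the unusual pairs are intentional).
_WP_PAIRS = [(-1, -2), (1, -1), (-1, 0), (2, -1), (0, 0), (0, 1), (1, 0), (1, 1), (1, 2)]
_W_UNI = [0, -1, 1, -2]  # w0 listed twice in the source table; no +2 unigram
_W_BI = [(-2, -1), (-1, 0), (0, 1), (1, 2)]
_W_TRI = [(-2, -1, 0), (-1, 0, 1), (0, 1, 2)]
_P_UNI = [0, -1, 1, -2, 2]
_P_BI = [(-2, -1), (-1, 0), (0, 1), (1, 2)]
_P_TRI = [(-2, -1, 0), (-1, 0, 1), (0, 1, 2)]


class FeatureExtractor:
    """Bundles the trained resources and maps (sentence, index) -> features."""

    def __init__(
        self,
        chem_gazetteer: Gazetteer | None = None,
        disease_gazetteer: Gazetteer | None = None,
        frequency_model: FrequencyModel | None = None,
        word_rep_model: WordRepModel | None = None,
    ):
        self.chem_gazetteer = chem_gazetteer
        self.disease_gazetteer = disease_gazetteer
        self.frequency_model = frequency_model
        self.word_rep_model = word_rep_model

    def sentence_features(self, sentence: TaggedSentence) -> list[FeatureDict]:
        """Feature dicts for every token of a sentence (shared work hoisted)."""
        texts = [t.text for t in sentence.tokens]
        n = len(texts)
        sent_feats: FeatureDict = {
            f"sent:len:{_sent_len_bucket(n)}": 1.0,
            f"sec:{sentence.section.value}": 1.0,
        }
        if _unmatched_bracket(texts):
            sent_feats["sent:unmatched_bracket"] = 1.0
        gaz_flags: dict[str, list[str | None]] = {}
        if self.chem_gazetteer is not None:
            gaz_flags["chem"] = self.chem_gazetteer.match_flags(texts)
        if self.disease_gazetteer is not None:
            gaz_flags["dis"] = self.disease_gazetteer.match_flags(texts)

        def w(i: int) -> str:
            return texts[i] if 0 <= i < n else PAD

        def p(i: int) -> str:
            return sentence.tokens[i].pos if 0 <= i < n else PAD

        out: list[FeatureDict] = []
        for i in range(n):
            f: FeatureDict = dict(sent_feats)
            for d in _W_UNI:
                f[f"bow:w{d}:{w(i + d)}"] = 1.0
            for d1, d2 in _W_BI:
                f[f"bow:w{d1}w{d2}:{w(i + d1)}|{w(i + d2)}"] = 1.0
            for d1, d2, d3 in _W_TRI:
                f[f"bow:w{d1}w{d2}w{d3}:{w(i + d1)}|{w(i + d2)}|{w(i + d3)}"] = 1.0
            for d in _P_UNI:
                f[f"pos:p{d}:{p(i + d)}"] = 1.0
            for d1, d2 in _P_BI:
                f[f"pos:p{d1}p{d2}:{p(i + d1)}|{p(i + d2)}"] = 1.0
            for d1, d2, d3 in _P_TRI:
                f[f"pos:p{d1}p{d2}p{d3}:{p(i + d1)}|{p(i + d2)}|{p(i + d3)}"] = 1.0
            for dw, dp in _WP_PAIRS:
                f[f"wp:w{dw}p{dp}:{w(i + dw)}|{p(i + dp)}"] = 1.0
            text = texts[i]
            f.update(affixes(text))
            f.update(_orthographic(text))
            full, collapsed = word_shape(text)
            f[f"shape:full:{full}"] = 1.0
            f[f"shape:collapsed:{collapsed}"] = 1.0
            f.update(char_ngrams(text))
            for name, flags in gaz_flags.items():
                if flags[i] is not None:
                    f[f"dict:{name}:{flags[i]}"] = 1.0
            if self.frequency_model is not None and self.frequency_model.flag(text):
                f["freq:high_freq_low_idf"] = 1.0
            if self.word_rep_model is not None:
                f.update(self.word_rep_model.features(text))
            out.append(f)
        return out

    def extract(self, sentence: TaggedSentence, index: int) -> FeatureDict:
        """Features for one token (convenience over ``sentence_features``)."""
        return self.sentence_features(sentence)[index]
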