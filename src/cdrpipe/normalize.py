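"""Concept normalization: mention text -> MeSH-style concept ID.

The workflow mirrors a dictionary-lookup normalizer with optional name
normalization: abbreviations are completed first (a Schwartz–Hearst-style
character-alignment detector pairs a parenthesized short form with its
preceding long form), then one of four strategies assigns the ID:

``MAP_DIRECT``  exact canonical lookup of the (expanded) mention text —
                the default and strongest strategy;
``MESH_LIST`` / ``WIKI_LIST``
                take the rank-1 name from an offline candidate list standing
                in for the MeSH WebSearch / Wikipedia APIs; if that first
                name exactly matches a dictionary item its ID is assigned,
                otherwise the mention is discarded (ID ``-1``);
``RERANK``      pool both lists, score candidates with a pairwise-trained
                linear ranker and pass the best-scoring name through the
                dictionary.

A mention that cannot be mapped keeps the sentinel ID ``-1``; such mentions
stay in the mention output but are invisible to relation extraction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import LinearSVC

from ._text import canonicalize, token_dice
from .corpus import (
    CandidateSource,
    DictionaryEntry,
    Document,
    Mention,
    NameCandidateList,
    UNMAPPED,
)

__all__ = [
    "AbbreviationPair",
    "NormalizationStrategy",
    "DictionaryIndex",
    "canonicalize",
    "detect_abbreviations",
    "expand_mention",
    "map_direct",
    "normalize_via_list",
    "CandidateReranker",
    "NormalizationResources",
    "normalize_document",
]


class NormalizationStrategy(str, Enum):
    MAP_DIRECT = "MAP_DIRECT"
    MESH_LIST = "MESH_LIST"
    WIKI_LIST = "WIKI_LIST"
    RERANK = "RERANK"


@dataclass(frozen=True)
class AbbreviationPair:
    short_form: str
    long_form: str
    doc_id: str
    # character offset of the short form, used for nearest-definition lookup
    position: int = 0


class DictionaryIndex:
    """First-wins exact-match lookup over canonicalized surface names."""

    def __init__(self, entries: Sequence[DictionaryEntry]):
        self._by_key: dict[str, str] = {}
        for e in entries:
            self._by_key.setdefault(e.normalized_key, e.concept_id)

    def lookup(self, name: str) -> str:
        return self._by_key.get(canonicalize(name), UNMAPPED)

    def __contains__(self, name: str) -> bool:
        return canonicalize(name) in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)


# ---------------------------------------------------------------------------
# Abbreviation completion (Schwartz–Hearst character alignment)

_PAREN_RE = re.compile(r"\(([^()]{1,25})\)")
_WORD_RE = re.compile(r"\S+")


def _valid_short_form(sf: str) -> bool:
    sf = sf.strip()
    return (
        2 <= len(sf) <= 10
        and any(c.isalpha() for c in sf)
        and sf[0].isalnum()
        and len(sf.split()) <= 2
    )


def _align(short: str, window: str) -> str | None:
    """Shortest suffix of ``window`` whose characters align with ``short``.

    Right-to-left character alignment: every short-form character must appear
    in order in the long form (case-insensitive) and the first one must start
    a word of the long form.
    """
    s = short.casefold()
    w = window.casefold()
    si = len(s) - 1
    wi = len(w) - 1
    while si >= 0:
        ch = s[si]
        if not ch.isalnum():
            si -= 1
            continue
        while wi >= 0 and (
            w[wi] != ch or (si == 0 and wi > 0 and w[wi - 1].isalnum())
        ):
            wi -= 1
        if wi < 0:
            return None
        si -= 1
        wi -= 1
    start = window.rfind(" ", 0, wi + 1) + 1
    result = window[start:].strip()
    return result or None


def detect_abbreviations(doc: Document) -> list[AbbreviationPair]:
    """Find (short form, long form) definitions like ``long form (SF)``."""
    pairs: list[AbbreviationPair] = []
    text = doc.text
    for m in _PAREN_RE.finditer(text):
        sf = m.group(1).strip()
        if not _valid_short_form(sf):
            continue
        preceding = text[: m.start()]
        words = _WORD_RE.findall(preceding)
        if not words:
            continue
        sf_alnum = sum(c.isalnum() for c in sf)
        max_words = min(sf_alnum + 5, sf_alnum * 2)
        window_words = words[-max_words:]
        window = " ".join(window_words)
        long_form = _align(sf, window)
        if long_form and canonicalize(long_form) != canonicalize(sf):
            pairs.append(
                AbbreviationPair(
                    short_form=sf,
                    long_form=long_form,
                    doc_id=doc.doc_id,
                    position=m.start(1),
                )
            )
    return pairs


def expand_mention(m: Mention, pairs: Sequence[AbbreviationPair]) -> str:
    """Long form for an abbreviation mention, else the mention text unchanged.

    When a short form is defined more than once, the nearest preceding
    definition wins.
    """
    best: AbbreviationPair | None = None
    for p in pairs:
        if p.doc_id == m.doc_id and p.short_form == m.text and p.position <= m.start:
            if best is None or p.position > best.position:
                best = p
    if best is None:
        # a definition occurring after the mention still applies document-wide
        for p in pairs:
            if p.doc_id == m.doc_id and p.short_form == m.text:
                best = p
                break
    return best.long_form if best else m.text


# ---------------------------------------------------------------------------
# Strategies


def map_direct(m_text: str, dictionary: DictionaryIndex) -> str:
    """Exact canonical dictionary lookup; ``-1`` when absent."""
    return dictionary.lookup(m_text)


def normalize_via_list(
    m_text: str,
    candidate_list: NameCandidateList | None,
    dictionary: DictionaryIndex,
) -> str:
    """First-name rule over an offline candidate list.

    If the first name in the list exactly matches a dictionary item the
    mention gets that item's ID; otherwise (or when the list is empty or
    missing) the mention is discarded with ID ``-1``.
    """
    if candidate_list is None or not candidate_list.candidates:
        return UNMAPPED
    return dictionary.lookup(candidate_list.candidates[0])


@dataclass
class _RankedCandidate:
    name: str
    in_mesh: bool
    in_wiki: bool
    mesh_rank: int | None
    wiki_rank: int | None


def _pool(
    mesh: NameCandidateList | None, wiki: NameCandidateList | None
) -> list[_RankedCandidate]:
    pool: dict[str, _RankedCandidate] = {}
    for source_list, attr in ((mesh, "mesh"), (wiki, "wiki")):
        if source_list is None:
            continue
        for rank, name in enumerate(source_list.candidates, start=1):
            key = canonicalize(name)
            cand = pool.get(key)
            if cand is None:
                cand = _RankedCandidate(name, False, False, None, None)
                pool[key] = cand
            if attr == "mesh" and not cand.in_mesh:
                cand.in_mesh, cand.mesh_rank = True, rank
            elif attr == "wiki" and not cand.in_wiki:
                cand.in_wiki, cand.wiki_rank = True, rank
    return list(pool.values())


def _rank_features(
    cand: _RankedCandidate, m_text: str, context: Sequence[str]
) -> dict[str, float]:
    feats: dict[str, float] = {}
    for tok in canonicalize(m_text).split():
        feats[f"mbow:{tok}"] = 1.0
    feats["sim:mention"] = token_dice(cand.name, m_text)
    if context:
        sims = [token_dice(cand.name, c) for c in context]
        feats["sim:context_max"] = max(sims)
        feats["sim:context_mean"] = sum(sims) / len(sims)
    feats["src:mesh"] = float(cand.in_mesh)
    feats["src:wiki"] = float(cand.in_wiki)
    feats["src:both"] = float(cand.in_mesh and cand.in_wiki)
    if cand.mesh_rank is not None:
        feats["rank:mesh_inv"] = 1.0 / cand.mesh_rank
        feats[f"rank:mesh:{cand.mesh_rank}"] = 1.0
    if cand.wiki_rank is not None:
        feats["rank:wiki_inv"] = 1.0 / cand.wiki_rank
        feats[f"rank:wiki:{cand.wiki_rank}"] = 1.0
    return feats


@dataclass
class RankQuery:
    """One re-ranking training query: a mention with its candidate lists."""

    mention_text: str
    context_mentions: list[str]
    mesh_list: NameCandidateList | None
    wiki_list: NameCandidateList | None
    gold_concept_id: str = UNMAPPED


class CandidateReranker(BaseEstimator):
    """Pairwise-preference linear ranker over pooled name candidates.

    Trained SVM-rank style: for every query, the candidate resolving to the
    gold concept is preferred over every candidate that does not; each
    preference contributes the feature difference in both orientations to a
    linear SVM.
    """

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def fit(
        self, queries: Sequence[RankQuery], dictionary: DictionaryIndex
    ) -> "CandidateReranker":
        rows: list[dict[str, float]] = []
        ys: list[int] = []
        for q in queries:
            cands = _pool(q.mesh_list, q.wiki_list)
            feats = [_rank_features(c, q.mention_text, q.context_mentions) for c in cands]
            correct = [
                i
                for i, c in enumerate(cands)
                if dictionary.lookup(c.name) == q.gold_concept_id
                and q.gold_concept_id != UNMAPPED
            ]
            wrong = [i for i in range(len(cands)) if i not in correct]
            for i in correct:
                for j in wrong:
                    diff = dict(feats[i])
                    for k, v in feats[j].items():
                        diff[k] = diff.get(k, 0.0) - v
                    rows.append(diff)
                    ys.append(1)
                    rows.append({k: -v for k, v in diff.items()})
                    ys.append(0)
        if not rows:
            raise ValueError("no preference pairs; cannot train the re-ranker")
        self.feature_names_ = sorted({k for r in rows for k in r})
        index = {k: i for i, k in enumerate(self.feature_names_)}
        X = np.zeros((len(rows), len(index)))
        for i, r in enumerate(rows):
            for k, v in r.items():
                X[i, index[k]] = v
        svc = LinearSVC(C=self.C, random_state=self.seed, max_iter=20000)
        svc.fit(X, np.asarray(ys))
        self.coef_ = svc.coef_.ravel().copy()
        return self

    def _score(self, feats: dict[str, float]) -> float:
        index = {k: i for i, k in enumerate(self.feature_names_)}
        return sum(
            self.coef_[index[k]] * v for k, v in feats.items() if k in index
        )

    def rerank(
        self,
        m_text: str,
        context_mentions: Sequence[str],
        mesh_list: NameCandidateList | None,
        wiki_list: NameCandidateList | None,
        dictionary: DictionaryIndex,
    ) -> str:
        """Concept ID of the best-scoring pooled candidate (``-1`` if none
        present in the dictionary)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("re-ranker is not fitted")
        cands = _pool(mesh_list, wiki_list)
        if not cands:
            return UNMAPPED
        scored = sorted(
            (
                (-self._score(_rank_features(c, m_text, context_mentions)), idx)
                for idx, c in enumerate(cands)
            ),
        )
        best = cands[scored[0][1]]
        return dictionary.lookup(best.name)


# ---------------------------------------------------------------------------
# Document-level pipeline


@dataclass
class NormalizationResources:
    chem_dictionary: DictionaryIndex
    disease_dictionary: DictionaryIndex
    candidate_lists: dict[tuple[str, CandidateSource], NameCandidateList] = field(
        default_factory=dict
    )
    reranker: CandidateReranker | None = None

    def dictionary_for(self, mention: Mention) -> DictionaryIndex:
        from .corpus import EntityType

        if mention.etype == EntityType.CHEMICAL:
            return self.chem_dictionary
        return self.disease_dictionary

    def lists_for(
        self, text: str
    ) -> tuple[NameCandidateList | None, NameCandidateList | None]:
        key = canonicalize(text)
        return (
            self.candidate_lists.get((key, CandidateSource.MESH_SEARCH)),
            self.candidate_lists.get((key, CandidateSource.WIKIPEDIA)),
        )


def normalize_document(
    doc: Document,
    strategy: NormalizationStrategy | str,
    resources: NormalizationResources,
) -> Document:
    """Fill ``concept_id`` on every mention of ``doc`` in place.

    Pipeline: abbreviation detection -> mention expansion -> strategy.
    """
    strategy = NormalizationStrategy(strategy)
    pairs = detect_abbreviations(doc)
    if strategy in (NormalizationStrategy.MESH_LIST, NormalizationStrategy.WIKI_LIST):
        if not resources.candidate_lists:
            warnings.warn(
                f"strategy {strategy.value} without candidate lists: every "
                "mention will be unmapped"
            )
    context = [m.text for m in doc.mentions]
    for m in doc.mentions:
        text = expand_mention(m, pairs)
        dictionary = resources.dictionary_for(m)
        if strategy == NormalizationStrategy.MAP_DIRECT:
            m.concept_id = map_direct(text, dictionary)
        else:
            mesh_list, wiki_list = resources.lists_for(text)
            if strategy == NormalizationStrategy.MESH_LIST:
                m.concept_id = normalize_via_list(text, mesh_list, dictionary)
            elif strategy == NormalizationStrategy.WIKI_LIST:
                m.concept_id = normalize_via_list(text, wiki_list, dictionary)
            else:
                if resources.reranker is None:
                    raise RuntimeError("RERANK strategy requires a trained re-ranker")
                other_context = [c for c in context if c != m.text]
                m.concept_id = resources.reranker.rerank(
                    text, other_context, mesh_list, wiki_list, dictionary
                )
    return doc
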