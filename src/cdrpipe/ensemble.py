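"""Stacked meta-classification of mention proposals.

Both sequence taggers propose mentions; a linear-SVM meta-classifier decides,
per proposed mention, whether to keep it.  Its features describe agreement
between the proposal and every other proposal at the same or an adjacent
position: eight pairwise span-agreement booleans aggregated as any-true
flags, plus how many and which taggers proposed the mention.

Training is standard stacking: the base taggers are re-trained inside a
document-level cross-validation so every meta-training instance comes from
taggers that never saw its document; a proposal is labeled positive iff it
exactly matches a gold mention (span and type).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import LinearSVC

from .corpus import Document, Mention
from .preprocess import TaggedSentence

__all__ = [
    "MentionPairFeatures",
    "CandidateMention",
    "pair_features",
    "collect_candidates",
    "build_meta_features",
    "MentionEnsemble",
]

FeatureDict = dict[str, float]


@dataclass(frozen=True)
class MentionPairFeatures:
    exact_span: bool
    partial_span: bool
    exact_span_type: bool
    partial_span_type: bool
    same_start: bool
    same_end: bool
    subsumes: bool
    subsumed_by: bool

    _NAMES = (
        "exact_span",
        "partial_span",
        "exact_span_type",
        "partial_span_type",
        "same_start",
        "same_end",
        "subsumes",
        "subsumed_by",
    )

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in self._NAMES}


@dataclass
class CandidateMention:
    mention: Mention
    sources: set[str]
    score: float = 0.0
    meta_features: FeatureDict = field(default_factory=dict)


def pair_features(a: Mention, b: Mention) -> MentionPairFeatures:
    """The eight span-agreement features for two mentions of one document.

    Partial match means any overlap; subsumption is inclusive, so equal spans
    subsume each other.
    """
    if a.doc_id != b.doc_id:
        raise ValueError("pair features require mentions of the same document")
    exact = a.span == b.span
    partial = a.overlaps(b)
    types = a.etype == b.etype
    return MentionPairFeatures(
        exact_span=exact,
        partial_span=partial,
        exact_span_type=exact and types,
        partial_span_type=partial and types,
        same_start=a.start == b.start,
        same_end=a.end == b.end,
        subsumes=a.start <= b.start and a.end >= b.end,
        subsumed_by=b.start <= a.start and b.end >= a.end,
    )


def collect_candidates(
    proposals: dict[str, Sequence[Mention]]
) -> list[CandidateMention]:
    """Merge per-tagger mention proposals into unique candidates.

    Proposals agreeing on (span, type) collapse into one candidate whose
    ``sources`` records every proposing tagger.
    """
    merged: dict[tuple, CandidateMention] = {}
    for source, mentions in proposals.items():
        for m in mentions:
            key = (m.doc_id, m.start, m.end, m.etype)
            if key in merged:
                merged[key].sources.add(source)
            else:
                merged[key] = CandidateMention(mention=m, sources={source})
    return sorted(
        merged.values(), key=lambda c: (c.mention.doc_id, c.mention.start, c.mention.end)
    )


def _adjacent(a: Mention, b: Mention, token_spans: Sequence[tuple[int, int]]) -> bool:
    """Same-or-adjacent position: span overlap or at most one token between."""
    if a.overlaps(b):
        return True
    lo, hi = min(a.end, b.end), max(a.start, b.start)
    if lo > hi:
        return True
    between = sum(1 for s, e in token_spans if s >= lo and e <= hi)
    return between <= 1


def build_meta_features(
    cand: CandidateMention,
    all_cands: Sequence[CandidateMention],
    n_taggers: int = 2,
    token_spans: Sequence[tuple[int, int]] = (),
) -> FeatureDict:
    """Meta-features: aggregated pairwise agreement plus provenance."""
    feats: FeatureDict = {f"nsrc:{len(cand.sources)}": 1.0}
    for source in sorted(cand.sources):
        feats[f"src:{source}"] = 1.0
    if len(cand.sources) == n_taggers:
        feats["src:all"] = 1.0
    for other in all_cands:
        if other is cand or other.mention.doc_id != cand.mention.doc_id:
            continue
        if not _adjacent(cand.mention, other.mention, token_spans):
            continue
        for name, on in pair_features(cand.mention, other.mention).as_dict().items():
            if on:
                feats[f"pair:{name}"] = 1.0
    cand.meta_features = feats
    return feats


def _doc_token_spans(sentences: Sequence[TaggedSentence]) -> list[tuple[int, int]]:
    return [(t.start, t.end) for s in sentences for t in s.tokens]


class MentionEnsemble(BaseEstimator):
    """Linear-SVM arbiter over merged tagger proposals.

    Parameters
    ----------
    C : float
        SVM regularization strength.
    threshold : float
        Decision threshold on the linear score (default 0).
    cv_folds : int
        Folds used by the stacking trainer when producing meta-training
        proposals (consumed by the pipeline, recorded here).
    seed : int
        Random state for the underlying solver.
    """

    def __init__(
        self, C: float = 1.0, threshold: float = 0.0, cv_folds: int = 5, seed: int = 0
    ):
        self.C = C
        self.threshold = threshold
        self.cv_folds = cv_folds
        self.seed = seed

    # --- featurization over documents ---

    @staticmethod
    def featurize(
        proposals: dict[str, Sequence[Mention]],
        sentences: Sequence[TaggedSentence],
    ) -> list[CandidateMention]:
        cands = collect_candidates(proposals)
        spans = _doc_token_spans(sentences)
        n_taggers = max(len(proposals), 1)
        for c in cands:
            build_meta_features(c, cands, n_taggers=n_taggers, token_spans=spans)
        return cands

    def fit(
        self,
        candidates: Sequence[CandidateMention],
        labels: Sequence[int],
    ) -> "MentionEnsemble":
        if not candidates:
            raise ValueError("no candidates to train the meta-classifier on")
        self.feature_names_ = sorted({k for c in candidates for k in c.meta_features})
        index = {k: i for i, k in enumerate(self.feature_names_)}
        X = np.zeros((len(candidates), len(index)))
        for i, c in enumerate(candidates):
            for k, v in c.meta_features.items():
                X[i, index[k]] = v
        y = np.asarray(labels)
        if len(set(y.tolist())) < 2:
            # degenerate stacking corpus (e.g. both taggers perfect): keep all
            self.coef_ = np.zeros(len(index))
            self.intercept_ = 1.0 if y.all() else -1.0
        else:
            svc = LinearSVC(C=self.C, random_state=self.seed, max_iter=20000)
            svc.fit(X, y)
            self.coef_ = svc.coef_.ravel().copy()
            self.intercept_ = float(svc.intercept_[0])
        return self

    def decision_scores(self, candidates: Sequence[CandidateMention]) -> np.ndarray:
        index = {k: i for i, k in enumerate(self.feature_names_)}
        X = np.zeros((len(candidates), len(index)))
        for i, c in enumerate(candidates):
            for k, v in c.meta_features.items():
                j = index.get(k)
                if j is not None:
                    X[i, j] = v
        return X @ self.coef_ + self.intercept_

    def apply(self, candidates: Sequence[CandidateMention]) -> list[Mention]:
        """Kept mentions after classification and overlap resolution.

        Overlaps among kept mentions are resolved toward the higher decision
        score; ties go to the longer span.  Output spans are always a subset
        of the union of tagger proposals.
        """
        if not candidates:
            return []
        scores = self.decision_scores(candidates)
        kept = [
            (c, s) for c, s in zip(candidates, scores) if s > self.threshold
        ]
        kept.sort(
            key=lambda cs: (-cs[1], -(cs[0].mention.end - cs[0].mention.start))
        )
        out: list[Mention] = []
        for c, s in kept:
            c.score = float(s)
            if not any(
                c.mention.doc_id == m.doc_id and c.mention.overlaps(m) for m in out
            ):
                out.append(c.mention)
        out.sort(key=lambda m: (m.doc_id, m.start, m.end))
        return out


def stacking_instances(
    docs: Sequence[Document],
    sentences_by_doc: dict[str, list[TaggedSentence]],
    proposals_by_doc: dict[str, dict[str, list[Mention]]],
) -> tuple[list[CandidateMention], list[int]]:
    """Meta-training instances from (cross-validated) tagger proposals.

    A candidate is positive iff its (span, type) exactly matches a gold
    mention of its document.
    """
    cands: list[CandidateMention] = []
    labels: list[int] = []
    for doc in docs:
        gold = {(m.start, m.end, m.etype) for m in doc.mentions}
        doc_cands = MentionEnsemble.featurize(
            proposals_by_doc.get(doc.doc_id, {}), sentences_by_doc[doc.doc_id]
        )
        for c in doc_cands:
            cands.append(c)
            labels.append(
                int((c.mention.start, c.mention.end, c.mention.etype) in gold)
            )
    return cands, labels
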