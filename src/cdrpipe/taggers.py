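"""BIO sequence labeling: a linear-chain CRF and a margin-based structured
tagger over the shared feature map, plus label projection and decoding.

Both models are scikit-learn style estimators: ``fit(sentences, tag_sequences)``
and ``predict(sentences)`` where a tag sequence is a list of labels from
``{B-Chemical, I-Chemical, B-Disease, I-Disease, O}`` aligned to the sentence
tokens.  Scoring is the classic chain model

    score(y | x) = sum_t  w_{y_t} . f(x, t)  +  sum_{t>0}  T[y_{t-1}, y_t]

with label-pair-only transition weights, so exhaustive enumeration over all
``5^L`` labelings is a valid decoding oracle on short sentences.

The CRF minimizes the L2-regularized negative log-likelihood with L-BFGS
(forward-backward gradients).  The margin model is a cost-augmented averaged
structured perceptron: decoding at training time adds a Hamming cost to every
wrong label, which pushes the gold sequence to win by a margin — a different
training objective from the CRF over the identical feature space.
"""

from __future__ import annotations

import json
import warnings
from typing import IO, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .corpus import Document, EntityType, Mention, UNMAPPED
from .features import FeatureExtractor
from .preprocess import TaggedSentence

__all__ = [
    "LABELS",
    "project_labels",
    "decode_mentions",
    "repair_bio",
    "viterbi",
    "ChainCRFTagger",
    "StructuredPerceptronTagger",
]

LABELS = ["O", "B-Chemical", "I-Chemical", "B-Disease", "I-Disease"]
_LABEL_INDEX = {label: i for i, label in enumerate(LABELS)}


# ---------------------------------------------------------------------------
# BIO projection / decoding


def project_labels(
    doc: Document, sentences: Sequence[TaggedSentence]
) -> list[list[str]]:
    """Project gold mention spans onto BIO token labels.

    Mentions not aligned to token boundaries are snapped outward to full
    tokens (with a warning); of two overlapping gold mentions the longer one
    wins (with a warning).
    """
    kept: list[Mention] = []
    for m in sorted(doc.mentions, key=lambda m: (m.end - m.start), reverse=True):
        if any(m.overlaps(k) for k in kept):
            warnings.warn(
                f"doc {doc.doc_id}: overlapping gold mention {m.text!r} dropped "
                "in label projection (longer mention kept)"
            )
            continue
        kept.append(m)
    out: list[list[str]] = []
    for sent in sentences:
        labels = ["O"] * len(sent.tokens)
        for m in kept:
            idxs = [
                i
                for i, t in enumerate(sent.tokens)
                if t.start < m.end and m.start < t.end
            ]
            if not idxs:
                continue
            lo, hi = min(idxs), max(idxs)
            if sent.tokens[lo].start != m.start or sent.tokens[hi].end != m.end:
                warnings.warn(
                    f"doc {doc.doc_id}: mention {m.text!r} snapped outward to "
                    "token boundaries"
                )
            labels[lo] = f"B-{m.etype.value}"
            for i in range(lo + 1, hi + 1):
                labels[i] = f"I-{m.etype.value}"
        out.append(labels)
    return out


def repair_bio(labels: list[str]) -> list[str]:
    """Repair illegal transitions: I-X after O or a different type becomes B-X."""
    out = list(labels)
    for i, lab in enumerate(out):
        if lab.startswith("I-"):
            prev = out[i - 1] if i else "O"
            if prev == "O" or prev[2:] != lab[2:]:
                out[i] = "B-" + lab[2:]
    return out


def decode_mentions(
    sentences: Sequence[TaggedSentence], tags: Sequence[list[str]]
) -> list[Mention]:
    """Turn maximal B..I label runs back into character-span mentions."""
    mentions: list[Mention] = []
    for sent, labels in zip(sentences, tags, strict=True):
        labels = repair_bio(labels)
        i = 0
        while i < len(labels):
            if labels[i].startswith("B-"):
                etype = labels[i][2:]
                j = i + 1
                while j < len(labels) and labels[j] == f"I-{etype}":
                    j += 1
                toks = sent.tokens[i:j]
                mentions.append(
                    Mention(
                        doc_id=sent.doc_id,
                        start=toks[0].start,
                        end=toks[-1].end,
                        text=" ".join(t.text for t in toks),
                        etype=EntityType(etype),
                        concept_id=UNMAPPED,
                    )
                )
                i = j
            else:
                i += 1
    return mentions


def mention_text_from_doc(doc: Document, mentions: list[Mention]) -> list[Mention]:
    """Replace decoded mention texts with the exact document slice."""
    text = doc.text
    for m in mentions:
        m.text = text[m.start : m.end]
    return mentions


# ---------------------------------------------------------------------------
# Decoding


def viterbi(emissions: np.ndarray, transitions: np.ndarray) -> list[int]:
    """Best label sequence for an ``(L, K)`` emission score matrix.

    Ties are broken toward the lowest label index (argmax convention), which
    matches the brute-force enumeration oracle iterating labels in order.
    """
    L, K = emissions.shape
    if L == 0:
        return []
    back = np.zeros((L, K), dtype=np.intp)
    score = emissions[0].copy()
    for t in range(1, L):
        cand = score[:, None] + transitions  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(K)] + emissions[t]
    path = [int(np.argmax(score))]
    for t in range(L - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


# ---------------------------------------------------------------------------
# Feature matrix plumbing shared by both taggers


class _Vocabulary:
    def __init__(self) -> None:
        self.index: dict[str, int] = {}

    def add(self, key: str) -> int:
        idx = self.index.get(key)
        if idx is None:
            idx = len(self.index)
            self.index[key] = idx
        return idx


def _build_matrix(
    feature_dicts: list[dict[str, float]],
    vocab: _Vocabulary,
    grow: bool,
) -> sp.csr_matrix:
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for feats in feature_dicts:
        for key, val in feats.items():
            if grow:
                indices.append(vocab.add(key))
                data.append(val)
            else:
                idx = vocab.index.get(key)
                if idx is not None:
                    indices.append(idx)
                    data.append(val)
        indptr.append(len(indices))
    n_features = max(len(vocab.index), 1)
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.intp), np.asarray(indptr, dtype=np.intp)),
        shape=(len(feature_dicts), n_features),
    )


class _TaggerBase(BaseEstimator):
    """Shared featurization, prediction and JSON serialization."""

    extractor: FeatureExtractor | None

    def _featurize(
        self, sentences: Sequence[TaggedSentence], grow: bool
    ) -> tuple[sp.csr_matrix, list[tuple[int, int]]]:
        extractor = self.extractor or FeatureExtractor()
        dicts: list[dict[str, float]] = []
        bounds: list[tuple[int, int]] = []
        for sent in sentences:
            start = len(dicts)
            dicts.extend(extractor.sentence_features(sent))
            bounds.append((start, len(dicts)))
        X = _build_matrix(dicts, self.vocab_, grow)
        return X, bounds

    def predict(self, sentences: Sequence[TaggedSentence]) -> list[list[str]]:
        self._check_fitted()
        if not sentences:
            return []
        X, bounds = self._featurize(sentences, grow=False)
        X = X[:, : self.weights_.shape[1]] if X.shape[1] > self.weights_.shape[1] else X
        E = X @ self.weights_.T
        out: list[list[str]] = []
        for lo, hi in bounds:
            path = viterbi(E[lo:hi], self.transitions_)
            out.append(repair_bio([LABELS[k] for k in path]))
        return out

    def predict_mentions(
        self, doc: Document, sentences: Sequence[TaggedSentence]
    ) -> list[Mention]:
        tags = self.predict(sentences)
        return mention_text_from_doc(doc, decode_mentions(sentences, tags))

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")

    # --- serialization (weights as JSON; float repr round-trips exactly) ---

    def to_json(self) -> dict:
        self._check_fitted()
        return {
            "kind": self.kind,
            "vocab": list(self.vocab_.index.keys()),
            "weights": self.weights_.tolist(),
            "transitions": self.transitions_.tolist(),
            "train_meta": getattr(self, "train_meta_", {}),
        }

    def load_weights(self, payload: dict) -> "_TaggerBase":
        self.vocab_ = _Vocabulary()
        for key in payload["vocab"]:
            self.vocab_.add(key)
        self.weights_ = np.asarray(payload["weights"], dtype=float)
        self.transitions_ = np.asarray(payload["transitions"], dtype=float)
        self.train_meta_ = payload.get("train_meta", {})
        return self

    def save(self, stream: IO[str]) -> None:
        json.dump(self.to_json(), stream)

    @classmethod
    def _encode_labels(cls, tag_sequences: Sequence[list[str]]) -> list[np.ndarray]:
        return [
            np.asarray([_LABEL_INDEX[lab] for lab in labels], dtype=np.intp)
            for labels in tag_sequences
        ]


class ChainCRFTagger(_TaggerBase):
    """Linear-chain CRF trained by L-BFGS on the L2-regularized NLL.

    Parameters
    ----------
    extractor : FeatureExtractor
        Shared feature map (gazetteers, frequency model, ...).
    l2 : float
        L2 regularization coefficient (default 0.1).
    max_iter : int
        L-BFGS iteration cap (default 100).
    seed : int
        Recorded in train metadata; training itself is deterministic.
    """

    kind = "CRF"

    def __init__(
        self,
        extractor: FeatureExtractor | None = None,
        l2: float = 0.1,
        max_iter: int = 100,
        seed: int = 0,
    ):
        self.extractor = extractor
        self.l2 = l2
        self.max_iter = max_iter
        self.seed = seed

    def fit(
        self,
        sentences: Sequence[TaggedSentence],
        tag_sequences: Sequence[list[str]],
    ) -> "ChainCRFTagger":
        if not sentences:
            raise ValueError("cannot train on an empty corpus")
        self.vocab_ = _Vocabulary()
        X, bounds = self._featurize(sentences, grow=True)
        Y = self._encode_labels(tag_sequences)
        K = len(LABELS)
        F = X.shape[1]
        n_tokens = X.shape[0]
        gold_flat = np.concatenate([y for y in Y if len(y)]) if n_tokens else np.empty(0)
        # empirical emission counts: sum_t f(x,t) at the gold label
        Y_onehot = sp.csr_matrix(
            (np.ones(n_tokens), (np.arange(n_tokens), gold_flat)), shape=(n_tokens, K)
        )
        emp_W = (Y_onehot.T @ X).toarray()
        emp_T = np.zeros((K, K))
        for y in Y:
            for a, b in zip(y[:-1], y[1:]):
                emp_T[a, b] += 1.0

        def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
            W = theta[: K * F].reshape(K, F)
            T = theta[K * F :].reshape(K, K)
            E = np.asarray(X @ W.T)  # (n_tokens, K)
            nll = 0.0
            exp_T = np.zeros((K, K))
            P = np.empty_like(E)
            for (lo, hi), y in zip(bounds, Y):
                e = E[lo:hi]
                L = hi - lo
                if L == 0:
                    continue
                alpha = np.empty((L, K))
                beta = np.empty((L, K))
                alpha[0] = e[0]
                for t in range(1, L):
                    m = alpha[t - 1][:, None] + T
                    mx = m.max(axis=0)
                    alpha[t] = e[t] + mx + np.log(np.exp(m - mx).sum(axis=0))
                beta[L - 1] = 0.0
                for t in range(L - 2, -1, -1):
                    m = T + (e[t + 1] + beta[t + 1])[None, :]
                    mx = m.max(axis=1)
                    beta[t] = mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))
                mx = alpha[L - 1].max()
                logZ = mx + np.log(np.exp(alpha[L - 1] - mx).sum())
                gold_score = e[np.arange(L), y].sum() + T[y[:-1], y[1:]].sum()
                nll += logZ - gold_score
                P[lo:hi] = np.exp(alpha + beta - logZ)
                for t in range(L - 1):
                    M = np.exp(
                        alpha[t][:, None] + T + (e[t + 1] + beta[t + 1])[None, :] - logZ
                    )
                    exp_T += M
            G = sp.csr_matrix(P)
            grad_W = np.asarray((G.T @ X).todense()) - emp_W
            grad_T = exp_T - emp_T
            nll += 0.5 * self.l2 * (theta @ theta)
            grad = np.concatenate([grad_W.ravel(), grad_T.ravel()]) + self.l2 * theta
            return nll, grad

        theta0 = np.zeros(K * F + K * K)
        res = scipy.optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "maxcor": 10},
        )
        self.weights_ = res.x[: K * F].reshape(K, F)
        self.transitions_ = res.x[K * F :].reshape(K, K)
        self.train_meta_ = {
            "iterations": int(res.nit),
            "regularization": self.l2,
            "seed": self.seed,
            "final_nll": float(res.fun),
        }
        return self


class StructuredPerceptronTagger(_TaggerBase):
    """Margin-based structured tagger (cost-augmented averaged perceptron).

    Training decodes with a per-token Hamming cost added to every non-gold
    label and applies averaged perceptron updates, i.e. a structured
    large-margin objective optimized by (sub)gradient steps.
    """

    kind = "MARGIN_STRUCT"

    def __init__(
        self,
        extractor: FeatureExtractor | None = None,
        epochs: int = 10,
        cost: float = 1.0,
        seed: int = 0,
    ):
        self.extractor = extractor
        self.epochs = epochs
        self.cost = cost
        self.seed = seed

    def fit(
        self,
        sentences: Sequence[TaggedSentence],
        tag_sequences: Sequence[list[str]],
    ) -> "StructuredPerceptronTagger":
        if not sentences:
            raise ValueError("cannot train on an empty corpus")
        self.vocab_ = _Vocabulary()
        X, bounds = self._featurize(sentences, grow=True)
        Y = self._encode_labels(tag_sequences)
        K = len(LABELS)
        F = X.shape[1]
        W = np.zeros((K, F))
        T = np.zeros((K, K))
        # lazy averaging accumulators (Daume trick): avg = W - U / step
        U_W = np.zeros((K, F))
        U_T = np.zeros((K, K))
        rng = np.random.default_rng(self.seed)
        order = np.arange(len(bounds))
        step = 1.0
        indices, indptr, data = X.indices, X.indptr, X.data
        for _ in range(self.epochs):
            rng.shuffle(order)
            for si in order:
                lo, hi = bounds[si]
                if hi == lo:
                    continue
                y = Y[si]
                Xs = X[lo:hi]
                e = np.asarray(Xs @ W.T)
                e += self.cost
                e[np.arange(hi - lo), y] -= self.cost
                pred = np.asarray(viterbi(e, T), dtype=np.intp)
                if not np.array_equal(pred, y):
                    for t in range(hi - lo):
                        if pred[t] == y[t]:
                            continue
                        row = indices[indptr[lo + t] : indptr[lo + t + 1]]
                        vals = data[indptr[lo + t] : indptr[lo + t + 1]]
                        W[y[t], row] += vals
                        W[pred[t], row] -= vals
                        U_W[y[t], row] += step * vals
                        U_W[pred[t], row] -= step * vals
                    for a, b, pa, pb in zip(y[:-1], y[1:], pred[:-1], pred[1:]):
                        if (a, b) != (pa, pb):
                            T[a, b] += 1.0
                            T[pa, pb] -= 1.0
                            U_T[a, b] += step
                            U_T[pa, pb] -= step
                step += 1.0
        self.weights_ = W - U_W / step
        self.transitions_ = T - U_T / step
        self.train_meta_ = {
            "iterations": self.epochs,
            "regularization": self.cost,
            "seed": self.seed,
        }
        return self


def load_tagger(payload: dict, extractor: FeatureExtractor | None = None) -> _TaggerBase:
    """Recreate a tagger from its JSON payload (predictions bit-identical)."""
    cls = {"CRF": ChainCRFTagger, "MARGIN_STRUCT": StructuredPerceptronTagger}[
        payload["kind"]
    ]
    tagger = cls(extractor=extractor)
    tagger.load_weights(payload)
    return tagger
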