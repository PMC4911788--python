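"""Sequence taggers: BIO projection/decoding, Viterbi oracle, training."""

import io
import itertools
import json

import numpy as np
import pytest

from cdrpipe.corpus import Document, EntityType, Mention
from cdrpipe.features import FeatureExtractor
from cdrpipe.preprocess import preprocess_document
from cdrpipe.taggers import (
    LABELS,
    ChainCRFTagger,
    StructuredPerceptronTagger,
    decode_mentions,
    load_tagger,
    project_labels,
    repair_bio,
    viterbi,
)


def _doc_with(text, spans):
    doc = Document("1", "T.", text)
    for s, e, etype in spans:
        doc.mentions.append(Mention("1", s + 3, e + 3, doc.text[s + 3 : e + 3], etype))
    return doc, preprocess_document(doc)


def test_project_two_token_chemical():
    doc, sents = _doc_with("mefenamic acid nephropathy.", [(0, 14, EntityType.CHEMICAL)])
    labels = project_labels(doc, sents)
    assert labels[1] == ["B-Chemical", "I-Chemical", "O", "O"]


def test_project_mention_free_sentence_all_outside():
    doc, sents = _doc_with("nothing to see here.", [])
    assert project_labels(doc, sents)[1] == ["O"] * len(sents[1].tokens)


def test_overlapping_gold_mentions_longer_wins():
    doc, sents = _doc_with(
        "inappropriate hypoaldosteronism seen.", [(0, 31, EntityType.DISEASE)]
    )
    doc.mentions.append(Mention("1", 17, 34, doc.text[17:34], EntityType.DISEASE))
    with pytest.warns(UserWarning, match="overlapping"):
        labels = project_labels(doc, sents)
    assert labels[1][:2] == ["B-Disease", "I-Disease"]


def test_decode_project_roundtrip_on_synthetic(corpus42, sents42):
    for doc in corpus42.documents[:30]:
        sents = sents42[doc.doc_id]
        mentions = decode_mentions(sents, project_labels(doc, sents))
        got = {(m.start, m.end, m.etype) for m in mentions}
        want = {(m.start, m.end, m.etype) for m in doc.mentions}
        assert got == want


def test_decode_repairs_illegal_transitions():
    assert repair_bio(["O", "I-Disease", "I-Disease"]) == [
        "O", "B-Disease", "I-Disease"
    ]
    assert repair_bio(["B-Chemical", "I-Disease"]) == ["B-Chemical", "B-Disease"]


def test_decode_all_outside_yields_no_mentions():
    doc, sents = _doc_with("plain words only.", [])
    assert decode_mentions(sents, [["O"] * len(s.tokens) for s in sents]) == []


def _brute_force(emissions, transitions):
    L, K = emissions.shape
    best, best_score = None, -np.inf
    for seq in itertools.product(range(K), repeat=L):
        score = sum(emissions[t, k] for t, k in enumerate(seq))
        score += sum(transitions[a, b] for a, b in zip(seq, seq[1:]))
        if score > best_score:
            best, best_score = list(seq), score
    return best


def test_viterbi_equals_exhaustive_search_small():
    rng = np.random.default_rng(3)
    for _ in range(40):
        L = int(rng.integers(1, 5))
        E = rng.normal(size=(L, 5))
        T = rng.normal(size=(5, 5))
        assert viterbi(E, T) == _brute_force(E, T)


def _tiny_corpus():
    doc, sents = _doc_with(
        "alphaxine caused severe betanosis.", [(0, 9, EntityType.CHEMICAL), (24, 33, EntityType.DISEASE)]
    )
    labels = project_labels(doc, sents)
    return sents, labels


@pytest.mark.parametrize("cls", [ChainCRFTagger, StructuredPerceptronTagger])
def test_memorization_of_repeated_sentence(cls):
    sents, labels = _tiny_corpus()
    tagger = cls(extractor=FeatureExtractor()).fit(sents * 5, labels * 5)
    assert tagger.predict(sents) == labels


@pytest.mark.parametrize("cls", [ChainCRFTagger, StructuredPerceptronTagger])
def test_training_deterministic_across_runs(cls):
    sents, labels = _tiny_corpus()
    a = cls(extractor=FeatureExtractor(), seed=5).fit(sents * 3, labels * 3)
    b = cls(extractor=FeatureExtractor(), seed=5).fit(sents * 3, labels * 3)
    assert np.array_equal(a.weights_, b.weights_)
    assert a.predict(sents) == b.predict(sents)


@pytest.mark.parametrize("cls", [ChainCRFTagger, StructuredPerceptronTagger])
def test_serialization_roundtrip_preserves_predictions(cls):
    sents, labels = _tiny_corpus()
    tagger = cls(extractor=FeatureExtractor()).fit(sents * 3, labels * 3)
    buf = io.StringIO()
    tagger.save(buf)
    clone = load_tagger(json.loads(buf.getvalue()), FeatureExtractor())
    assert np.array_equal(clone.weights_, tagger.weights_)
    assert clone.predict(sents) == tagger.predict(sents)


def test_empty_corpus_rejected():
    with pytest.raises(ValueError):
        ChainCRFTagger(extractor=FeatureExtractor()).fit([], [])


def test_predict_empty_sentence_list():
    sents, labels = _tiny_corpus()
    tagger = StructuredPerceptronTagger(extractor=FeatureExtractor()).fit(sents, labels)
    assert tagger.predict([]) == []


def test_unfitted_predict_raises():
    with pytest.raises(RuntimeError):
        ChainCRFTagger(extractor=FeatureExtractor()).predict([])


def test_label_set_is_two_type_bio():
    assert LABELS == ["O", "B-Chemical", "I-Chemical", "B-Disease", "I-Disease"]
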