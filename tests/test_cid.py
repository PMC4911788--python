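"""CID candidate filtering, gap-threshold fitting and relation classification."""

import numpy as np
import pytest

from cdrpipe import cid as cid_mod
from cdrpipe.cid import (
    CIDCandidate,
    CIDClassifier,
    FilterConfig,
    candidate_features,
    extract_relations,
    fit_gap_threshold,
    generate_candidates,
    generate_step2_candidates,
    label_candidates,
)
from cdrpipe.corpus import Document, EntityType, Mention, Relation
from cdrpipe.preprocess import preprocess_document


def _fixture_doc():
    """Chemical in sentence 0 (title); disease in sentences 1 and 4."""
    title = "Studies of alphaxine therapy outcomes."
    abstract = (
        "Severe cases of betanosis were recorded early. "
        "Follow up continued for months. "
        "No adverse findings were noted meanwhile. "
        "Late recurrence of betanosis was confirmed afterwards."
    )
    doc = Document("1", title, abstract)
    text = doc.text
    for surface, etype, cid in [
        ("alphaxine", EntityType.CHEMICAL, "C1"),
        ("betanosis", EntityType.DISEASE, "E1"),
    ]:
        start = -1
        while True:
            start = text.find(surface, start + 1)
            if start < 0:
                break
            doc.mentions.append(
                Mention("1", start, start + len(surface), surface, etype, cid)
            )
    doc.mentions.sort(key=lambda m: m.start)
    return doc, preprocess_document(doc)


def test_sentence_window_limits_step1():
    doc, sents = _fixture_doc()
    cands = generate_candidates(doc, sents, FilterConfig(3, gap_threshold=1000))
    # sentences 0-1 pairing survives; the sentence-4 disease is out of window
    assert len(cands) == 1
    assert cands[0].sent_distance == 1
    # hand count: tokens after the chemical in the title (therapy outcomes .)
    # plus tokens before the disease in sentence 1 (Severe cases of)
    assert cands[0].word_gap == 6
    assert cands[0].n_mentions_between == 0


def test_window_one_means_same_sentence():
    doc, sents = _fixture_doc()
    assert generate_candidates(doc, sents, FilterConfig(1, 1000)) == []


def test_step2_keeps_minimal_gap_pair():
    doc, sents = _fixture_doc()
    cands = generate_candidates(doc, sents, FilterConfig(4, 1000))
    # both disease mentions share the ID pair; only the closer one remains
    assert len(cands) == 1 and cands[0].word_gap == 6


def test_step3_gap_threshold_drops_distant_pairs():
    doc, sents = _fixture_doc()
    assert generate_candidates(doc, sents, FilterConfig(3, 5)) == []
    assert len(generate_candidates(doc, sents, FilterConfig(3, 6))) == 1


def test_gap_eighty_removed_under_threshold_78():
    filler = " ".join(["filler"] * 80)
    abstract = f"after dosing alphaxine {filler} betanosis was confirmed."
    doc = Document("1", "T.", abstract)
    text = doc.text
    for surface, etype, cid in [
        ("alphaxine", EntityType.CHEMICAL, "C1"),
        ("betanosis", EntityType.DISEASE, "E1"),
    ]:
        s = text.index(surface)
        doc.mentions.append(Mention("1", s, s + len(surface), surface, etype, cid))
    sents = preprocess_document(doc)
    assert generate_candidates(doc, sents, FilterConfig(3, 78)) == []
    assert len(generate_candidates(doc, sents, FilterConfig(3, 80))) == 1


def test_auto_threshold_at_inference_rejected():
    doc, sents = _fixture_doc()
    with pytest.raises(ValueError, match="AUTO"):
        generate_candidates(doc, sents, FilterConfig(3, cid_mod.AUTO))


def _candidate(word_gap=0, n_between=0, chem="C1", dis="E1", label="UNLABELED"):
    cm = Mention("1", 0, 4, "chem", EntityType.CHEMICAL, chem)
    dm = Mention("1", 10, 14, "dise", EntityType.DISEASE, dis)
    return CIDCandidate("1", chem, dis, cm, dm, 0, word_gap, n_between, label)


def test_fit_gap_threshold_mean_rounded_down():
    cands = [_candidate(word_gap=4, label="TRUE"), _candidate(word_gap=6, label="TRUE")]
    assert fit_gap_threshold(cands) == 5
    assert fit_gap_threshold([_candidate(word_gap=78, label="TRUE")]) == 78
    cands.append(_candidate(word_gap=2, label="TRUE"))
    assert fit_gap_threshold(cands) == 4  # mean 4.0 exactly


def test_fit_gap_threshold_requires_positives():
    with pytest.raises(ValueError):
        fit_gap_threshold([_candidate(label="FALSE")])


def test_fit_gap_threshold_ten_candidate_fixture():
    gaps_true = [1, 3, 5, 7, 9]
    gaps_false = [2, 4, 6, 8, 10]
    cands = [_candidate(word_gap=g, label="TRUE") for g in gaps_true]
    cands += [_candidate(word_gap=g, label="FALSE") for g in gaps_false]
    assert fit_gap_threshold(cands) == int(sum(gaps_true) / len(gaps_true))


def test_candidate_features_three_families():
    c = _candidate(n_between=0)
    feats = candidate_features(c, knowledge={("C1", "E1")})
    assert feats["kb:known_pair"] == 1.0
    assert feats["between:0"] == 1.0
    assert feats["cbow:chem"] == 1.0 and feats["dbow:dise"] == 1.0
    assert candidate_features(c, knowledge=set()).get("kb:known_pair") is None
    assert candidate_features(c, set()) == candidate_features(c, set())


def test_window_and_threshold_monotonicity(corpus42, sents42):
    for doc in corpus42.documents[:20]:
        sents = sents42[doc.doc_id]
        small = {
            (c.pair, c.word_gap)
            for c in generate_candidates(doc, sents, FilterConfig(2, 1000))
        }
        large = {
            (c.pair, c.word_gap)
            for c in generate_candidates(doc, sents, FilterConfig(4, 1000))
        }
        assert small <= large
        tight = {c.pair for c in generate_candidates(doc, sents, FilterConfig(3, 3))}
        loose = {c.pair for c in generate_candidates(doc, sents, FilterConfig(3, 10))}
        assert tight <= loose


def test_classifier_rejects_unlabeled_and_single_class():
    with pytest.raises(ValueError):
        CIDClassifier().fit([_candidate()], set())
    with pytest.raises(ValueError):
        CIDClassifier().fit(
            [_candidate(label="TRUE"), _candidate(label="TRUE")], set()
        )


def test_classifier_label_flip_negates_scores():
    rng = np.random.default_rng(0)
    cands = []
    for i in range(40):
        pos = bool(i % 2)
        cands.append(
            _candidate(
                n_between=0 if pos else 1 + int(rng.integers(3)),
                chem=f"C{i % 5}",
                dis=f"E{i % 7}",
                label="TRUE" if pos else "FALSE",
            )
        )
    a = CIDClassifier().fit(cands, set())
    flipped = [
        CIDCandidate(
            c.doc_id, c.chemical_id, c.disease_id, c.chemical_mention,
            c.disease_mention, c.sent_distance, c.word_gap, c.n_mentions_between,
            "FALSE" if c.label == "TRUE" else "TRUE",
        )
        for c in cands
    ]
    b = CIDClassifier().fit(flipped, set())
    sa = a.decision_scores(cands, set())
    sb = b.decision_scores(cands, set())
    assert np.allclose(sa, -sb, atol=1e-3)


def test_classifier_deterministic():
    cands = [
        _candidate(n_between=i % 3, chem=f"C{i}", label="TRUE" if i % 2 else "FALSE")
        for i in range(20)
    ]
    a = CIDClassifier(seed=1).fit(cands, set()).decision_scores(cands, set())
    b = CIDClassifier(seed=1).fit(cands, set()).decision_scores(cands, set())
    assert np.array_equal(a, b)


def test_extract_relations_without_chemicals_is_empty():
    doc = Document("1", "Only betanosis here today.", "Nothing else was found anywhere.")
    doc.mentions = [Mention("1", 5, 14, "betanosis", EntityType.DISEASE, "E1")]
    sents = preprocess_document(doc)
    model = CIDClassifier()
    model.feature_names_ = ["kb:known_pair"]
    model.coef_ = np.asarray([1.0])
    model.intercept_ = 0.0
    assert extract_relations(doc, sents, model, FilterConfig(3, 10), set()) == []


def test_extract_relations_with_perfect_stub_recovers_planted(corpus42, sents42):
    """An always-true classifier on threshold-filtered candidates returns
    exactly the planted relations (the filter alone isolates them is not
    guaranteed, so restrict to documents without same-sentence distractors)."""
    model = CIDClassifier()
    model.feature_names_ = []
    model.coef_ = np.asarray([])
    model.intercept_ = 1.0
    cfg = FilterConfig(3, 3)
    for doc in corpus42.documents[:40]:
        rels = set(
            extract_relations(doc, sents42[doc.doc_id], model, cfg, set())
        )
        assert {Relation(doc.doc_id, r.chemical_id, r.disease_id) for r in doc.relations} <= rels


def test_every_relation_id_exists_among_mentions(corpus42, sents42, world42):
    cfg = FilterConfig(3, 3)
    model = CIDClassifier()
    model.feature_names_ = ["kb:known_pair", "between:0"]
    model.coef_ = np.asarray([2.0, 2.0])
    model.intercept_ = -1.0
    for doc in corpus42.documents[:30]:
        rels = extract_relations(doc, sents42[doc.doc_id], model, cfg, world42.knowledge)
        ids = {m.concept_id for m in doc.mentions}
        for r in rels:
            assert r.chemical_id in ids and r.disease_id in ids
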