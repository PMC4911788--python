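"""Meta-classification of mention proposals: pairwise features and stacking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdrpipe.corpus import Document, EntityType, Mention
from cdrpipe.ensemble import (
    MentionEnsemble,
    build_meta_features,
    collect_candidates,
    pair_features,
)
from cdrpipe.preprocess import preprocess_document


def _m(start, end, etype=EntityType.DISEASE, doc_id="1"):
    return Mention(doc_id, start, end, "x" * (end - start), etype)


def test_identical_mentions_all_eight_true():
    f = pair_features(_m(3, 9), _m(3, 9))
    assert all(f.as_dict().values())


def test_prefix_overlap_case():
    f = pair_features(_m(10, 20), _m(10, 25))
    assert f.as_dict() == {
        "exact_span": False,
        "partial_span": True,
        "exact_span_type": False,
        "partial_span_type": True,
        "same_start": True,
        "same_end": False,
        "subsumes": False,
        "subsumed_by": True,
    }


def test_disjoint_spans_all_false():
    f = pair_features(_m(0, 5), _m(10, 15))
    assert not any(f.as_dict().values())


def test_cross_document_pair_rejected():
    with pytest.raises(ValueError):
        pair_features(_m(0, 5, doc_id="1"), _m(0, 5, doc_id="2"))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    a=st.tuples(st.integers(0, 40), st.integers(1, 10)),
    b=st.tuples(st.integers(0, 40), st.integers(1, 10)),
    ta=st.sampled_from(list(EntityType)),
    tb=st.sampled_from(list(EntityType)),
)
def test_pair_feature_implication_chain(a, b, ta, tb):
    ma = _m(a[0], a[0] + a[1], ta)
    mb = _m(b[0], b[0] + b[1], tb)
    f = pair_features(ma, mb)
    if f.exact_span:
        assert f.partial_span and f.same_start and f.same_end
        assert f.subsumes and f.subsumed_by
    if f.exact_span_type:
        assert f.exact_span
    if f.partial_span_type:
        assert f.partial_span
    if f.subsumes and f.subsumed_by:
        assert f.exact_span


def test_both_source_candidate_provenance_features():
    props = {"CRF": [_m(0, 5)], "MARGIN_STRUCT": [_m(0, 5)]}
    cands = collect_candidates(props)
    assert len(cands) == 1
    feats = build_meta_features(cands[0], cands, n_taggers=2)
    assert feats["nsrc:2"] == 1.0
    assert feats["src:CRF"] == 1.0 and feats["src:MARGIN_STRUCT"] == 1.0


def test_boundary_conflict_subsumption_flags():
    """One tagger proposes the correct short span, the other an overlong
    span extended by a preceding modifier (the classic boundary dispute)."""
    text = "We saw inappropriate hypoaldosteronism in one patient."
    doc = Document("1", "T.", text)
    full = doc.text
    short = Mention("1", full.index("hypoaldosteronism"), full.index("hypoaldosteronism") + 17, "hypoaldosteronism", EntityType.DISEASE)
    long = Mention("1", full.index("inappropriate"), full.index("hypoaldosteronism") + 17, "inappropriate hypoaldosteronism", EntityType.DISEASE)
    cands = collect_candidates({"CRF": [short], "MARGIN_STRUCT": [long]})
    spans = [(t.start, t.end) for s in preprocess_document(doc) for t in s.tokens]
    by_len = sorted(cands, key=lambda c: c.mention.end - c.mention.start)
    f_short = build_meta_features(by_len[0], cands, token_spans=spans)
    f_long = build_meta_features(by_len[1], cands, token_spans=spans)
    assert f_short.get("pair:subsumed_by") == 1.0
    assert f_long.get("pair:subsumes") == 1.0


def test_lone_candidate_has_no_pair_flags():
    cands = collect_candidates({"CRF": [_m(0, 5)]})
    feats = build_meta_features(cands[0], cands, n_taggers=2)
    assert feats["nsrc:1"] == 1.0
    assert not any(k.startswith("pair:") for k in feats)


def test_output_subset_of_proposals_and_perfect_taggers_keep_all():
    props = {"CRF": [_m(0, 5), _m(10, 14)], "MARGIN_STRUCT": [_m(0, 5), _m(10, 14)]}
    cands = MentionEnsemble.featurize(props, [])
    ens = MentionEnsemble().fit(cands, [1] * len(cands))  # degenerate: all good
    kept = ens.apply(cands)
    proposed = {(m.start, m.end) for ms in props.values() for m in ms}
    assert {(m.start, m.end) for m in kept} <= proposed
    assert len(kept) == 2


def test_meta_training_deterministic():
    props = {"CRF": [_m(0, 5), _m(10, 14)], "MARGIN_STRUCT": [_m(0, 6), _m(10, 14)]}
    cands = MentionEnsemble.featurize(props, [])
    labels = [1, 0, 1]
    a = MentionEnsemble(seed=3).fit(cands, labels).apply(cands)
    b = MentionEnsemble(seed=3).fit(cands, labels).apply(cands)
    assert [(m.start, m.end) for m in a] == [(m.start, m.end) for m in b]


def test_empty_candidate_list_yields_empty_output():
    ens = MentionEnsemble().fit(
        MentionEnsemble.featurize({"CRF": [_m(0, 5)]}, []), [1]
    )
    assert ens.apply([]) == []


def test_overlap_resolution_keeps_single_mention():
    props = {"CRF": [_m(0, 5)], "MARGIN_STRUCT": [_m(0, 8)]}
    cands = MentionEnsemble.featurize(props, [])
    ens = MentionEnsemble().fit(cands, [1, 1])
    kept = ens.apply(cands)
    assert len(kept) == 1
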