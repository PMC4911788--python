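"""Normalization: abbreviations, canonical lookup, list strategies, re-ranking."""

import pytest

from cdrpipe.corpus import (
    CandidateSource,
    DictionaryEntry,
    Document,
    EntityType,
    Mention,
    NameCandidateList,
    UNMAPPED,
    load_dictionary,
)
from cdrpipe.normalize import (
    AbbreviationPair,
    CandidateReranker,
    DictionaryIndex,
    NormalizationResources,
    NormalizationStrategy,
    canonicalize,
    detect_abbreviations,
    expand_mention,
    map_direct,
    normalize_document,
    normalize_via_list,
)


def _doc(abstract, doc_id="1"):
    return Document(doc_id, "Title.", abstract)


def test_detect_standard_definition():
    pairs = detect_abbreviations(_doc("Patients had coronary artery disease (CAD) at entry."))
    assert [(p.short_form, p.long_form) for p in pairs] == [
        ("CAD", "coronary artery disease")
    ]


def test_detect_rejects_unalignable_inner_text():
    assert detect_abbreviations(_doc("We say hello (world) to everyone.")) == []


def test_detect_rejects_letterless_short_form():
    assert detect_abbreviations(_doc("The compound (±) was racemic.")) == []


def test_expand_short_form_mention():
    doc = _doc("Severe coronary artery disease (CAD) was noted. CAD persisted.")
    pairs = detect_abbreviations(doc)
    m = Mention("1", doc.text.rindex("CAD"), doc.text.rindex("CAD") + 3, "CAD", EntityType.DISEASE)
    assert expand_mention(m, pairs) == "coronary artery disease"


def test_expand_identity_without_matching_pair():
    m = Mention("1", 0, 12, "hyperkalemia", EntityType.DISEASE)
    assert expand_mention(m, []) == "hyperkalemia"


def test_expand_nearest_preceding_definition_wins():
    doc = _doc(
        "First chronic arterial disease (CAD) was defined. "
        "Then coronary artery disease (CAD) was defined. Finally CAD recurred."
    )
    pairs = detect_abbreviations(doc)
    assert len(pairs) == 2
    pos = doc.text.rindex("CAD")
    m = Mention("1", pos, pos + 3, "CAD", EntityType.DISEASE)
    assert expand_mention(m, pairs) == "coronary artery disease"


@pytest.mark.parametrize(
    "raw, canon",
    [
        ("Giant Axonal Neuropathy", "giant axonal neuropathy"),
        ("heart-disease", "heart disease"),
        ("  IDs  ", "ids"),
    ],
)
def test_canonicalize(raw, canon):
    assert canonicalize(raw) == canon


@pytest.fixture()
def disease_index():
    return DictionaryIndex(
        load_dictionary(
            "Giant Axonal Neuropathy\tD056768\tDisease\n"
            "Spinocerebellar Ataxias\tD020754\tDisease\n"
        )
    )


def test_map_direct_exact_lookup(disease_index):
    assert map_direct("Giant Axonal Neuropathy", disease_index) == "D056768"
    assert map_direct("giant axonal neuropathy", disease_index) == "D056768"


def test_map_direct_unknown_is_unmapped(disease_index):
    assert map_direct("completely unknown disorder", disease_index) == UNMAPPED


def test_dictionary_first_entry_wins_on_duplicate_key():
    index = DictionaryIndex(
        load_dictionary("Same Name\tD000001\tDisease\nsame name\tD000002\tDisease\n")
    )
    assert index.lookup("same NAME") == "D000001"


def _ranked_lists():
    mesh = NameCandidateList(
        "axonal neuropathy",
        CandidateSource.MESH_SEARCH,
        [
            "Giant Axonal Neuropathy",
            "Spinocerebellar Ataxias",
            "Alcoholic Neuropathy",
            "Giant Axonal Neuropathy, Autosomal Dominant",
            "Severe infantile axonal neuropathy",
        ],
    )
    wiki = NameCandidateList(
        "axonal neuropathy",
        CandidateSource.WIKIPEDIA,
        [
            "Giant axonal neuropathy with curly hair",
            "Giant Axonal Neuropathy",
            "Acute motor axonal neuropathy",
            "Gigaxonin",
            "Gan",
        ],
    )
    return mesh, wiki


def test_first_name_rule_mesh_list_resolves(disease_index):
    mesh, _ = _ranked_lists()
    assert normalize_via_list("axonal neuropathy", mesh, disease_index) == "D056768"


def test_first_name_rule_wiki_list_discards(disease_index):
    _, wiki = _ranked_lists()
    assert normalize_via_list("axonal neuropathy", wiki, disease_index) == UNMAPPED


def test_first_name_rule_empty_or_missing_list(disease_index):
    empty = NameCandidateList("x", CandidateSource.MESH_SEARCH, [])
    assert normalize_via_list("x", empty, disease_index) == UNMAPPED
    assert normalize_via_list("x", None, disease_index) == UNMAPPED


def test_list_strategy_never_returns_id_outside_dictionary(disease_index, corpus42):
    for (text, _), clist in list(corpus42.candidate_lists.items())[:50]:
        got = normalize_via_list(text, clist, disease_index)
        if got != UNMAPPED:
            assert clist.candidates[0] in disease_index


def test_reranker_with_similarity_scorer_picks_dictionary_candidate(disease_index):
    mesh, wiki = _ranked_lists()
    ranker = CandidateReranker()
    ranker.feature_names_ = ["sim:mention"]
    import numpy as np

    ranker.coef_ = np.asarray([1.0])
    got = ranker.rerank("giant axonal neuropathy", [], mesh, wiki, disease_index)
    assert got == "D056768"


def test_reranker_unfitted_raises(disease_index):
    mesh, wiki = _ranked_lists()
    with pytest.raises(RuntimeError):
        CandidateReranker().rerank("x", [], mesh, wiki, disease_index)


def _map_direct_resources(world):
    entries = world.dictionary_entries()
    return NormalizationResources(
        chem_dictionary=DictionaryIndex(
            [e for e in entries if e.etype == EntityType.CHEMICAL]
        ),
        disease_dictionary=DictionaryIndex(
            [e for e in entries if e.etype == EntityType.DISEASE]
        ),
    )


def test_map_direct_recovers_planted_ids(world42, corpus42):
    resources = _map_direct_resources(world42)
    for doc in corpus42.test[:30]:
        gold = [(m.span, m.concept_id) for m in doc.mentions]
        pred = Document(doc.doc_id, doc.title, doc.abstract)
        pred.mentions = [
            Mention(m.doc_id, m.start, m.end, m.text, m.etype) for m in doc.mentions
        ]
        normalize_document(pred, NormalizationStrategy.MAP_DIRECT, resources)
        for (span, gold_id), m in zip(gold, pred.mentions):
            if gold_id != UNMAPPED and not m.text.isupper():
                assert m.concept_id == gold_id, (doc.doc_id, m.text)


def test_list_strategy_without_lists_warns_and_unmaps(world42):
    resources = _map_direct_resources(world42)
    doc = _doc("Plain betanosis text here.")
    doc.mentions = [Mention("1", 13, 22, "betanosis", EntityType.DISEASE)]
    with pytest.warns(UserWarning):
        normalize_document(doc, NormalizationStrategy.MESH_LIST, resources)
    assert doc.mentions[0].concept_id == UNMAPPED


def test_trained_reranker_beats_rank1_baseline(world42, corpus42):
    """With correct names planted at random ranks, the pairwise-trained
    ranker's top-1 accuracy exceeds the first-name-rule baseline."""
    from cdrpipe.normalize import RankQuery
    from cdrpipe.corpus import CandidateSource

    entries = world42.dictionary_entries()
    union = DictionaryIndex(entries)
    lists = corpus42.candidate_lists

    def queries(docs):
        out = []
        for d in docs:
            for m in d.mentions:
                if m.concept_id == UNMAPPED or m.text.isupper():
                    continue
                key = canonicalize(m.text)
                mesh = lists.get((key, CandidateSource.MESH_SEARCH))
                wiki = lists.get((key, CandidateSource.WIKIPEDIA))
                if mesh is None and wiki is None:
                    continue
                out.append(
                    RankQuery(m.text, [c.text for c in d.mentions if c is not m],
                              mesh, wiki, m.concept_id)
                )
        return out

    ranker = CandidateReranker(seed=0).fit(queries(corpus42.train[:60]), union)
    test_q = queries(corpus42.test[:40])
    rerank_hits = baseline_hits = 0
    for q in test_q:
        got = ranker.rerank(q.mention_text, q.context_mentions, q.mesh_list,
                            q.wiki_list, union)
        rerank_hits += got == q.gold_concept_id
        baseline_hits += (
            normalize_via_list(q.mention_text, q.mesh_list, union)
            == q.gold_concept_id
        )
    assert rerank_hits / len(test_q) > baseline_hits / len(test_q)
    assert rerank_hits / len(test_q) > 0.9


def test_abbreviation_definition_resolves_via_expansion(world42):
    resources = _map_direct_resources(world42)
    name = sorted(world42.diseases)[0]
    cid = world42.diseases[name]
    sf = "".join(w[0].upper() for w in name.split()) if " " in name else name[:3].upper()
    abstract = f"Cases of {name} ({sf}) were reviewed. Later {sf} recurred."
    doc = _doc(abstract)
    pos = doc.text.rindex(sf)
    doc.mentions = [Mention("1", pos, pos + len(sf), sf, EntityType.DISEASE)]
    normalize_document(doc, NormalizationStrategy.MAP_DIRECT, resources)
    assert doc.mentions[0].concept_id == cid
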