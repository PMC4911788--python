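"""Shared fixtures: synthetic corpora, trained taggers, hand-built records.

Heavy resources (the 300-document corpus and the taggers trained on its
200-document training split) are session-scoped and shared across test
modules.
"""

from __future__ import annotations

import pytest

from cdrpipe.corpus import Document, EntityType, Mention, Relation
from cdrpipe.pipeline import _preprocess_all, build_extractor, train_taggers
from cdrpipe.synthetic import GeneratorConfig, build_world, generate_corpus


@pytest.fixture(scope="session")
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=42, n_docs=300)


@pytest.fixture(scope="session")
def world42(gen_cfg):
    return build_world(gen_cfg)


@pytest.fixture(scope="session")
def corpus42(world42, gen_cfg):
    return generate_corpus(world42, gen_cfg)


@pytest.fixture(scope="session")
def sents42(corpus42):
    return _preprocess_all(corpus42.documents)


@pytest.fixture(scope="session")
def extractor42(world42, corpus42, sents42):
    entries = world42.dictionary_entries()
    chem = [e for e in entries if e.etype == EntityType.CHEMICAL]
    dis = [e for e in entries if e.etype == EntityType.DISEASE]
    return build_extractor(chem, dis, corpus42.train, sents42)


@pytest.fixture(scope="session")
def taggers42(corpus42, sents42, extractor42):
    """CRF and margin taggers trained on the 200-document training split."""
    return train_taggers(corpus42.train, sents42, extractor42, {}, seed=0)


def _annotated_record() -> Document:
    """Synthetic stand-in for a hand-annotated title+abstract record.

    Two-section document with underline-style chemical/disease mentions and
    one document-level relation, mimicking the layout of real annotated
    PubMed records; content is invented.
    """
    title = "Scleroderma renal crisis after carboplatin therapy."
    abstract = (
        "A patient with scleroderma developed renal crisis and severe "
        "hypertension after receiving carboplatin. The carboplatin infusion "
        "was discontinued and blood pressure normalized."
    )
    doc = Document(doc_id="7468724", title=title, abstract=abstract)
    text = doc.text

    def add(surface: str, etype: EntityType, cid: str, occurrence: int = 0) -> None:
        start = -1
        for _ in range(occurrence + 1):
            start = text.index(surface, start + 1)
        doc.mentions.append(
            Mention("7468724", start, start + len(surface), surface, etype, cid)
        )

    add("Scleroderma", EntityType.DISEASE, "D012595")
    add("renal crisis", EntityType.DISEASE, "D007674")
    add("carboplatin", EntityType.CHEMICAL, "D016190", 0)
    add("scleroderma", EntityType.DISEASE, "D012595", 0)
    add("renal crisis", EntityType.DISEASE, "D007674", 1)
    add("hypertension", EntityType.DISEASE, "D006973")
    add("carboplatin", EntityType.CHEMICAL, "D016190", 1)
    add("carboplatin", EntityType.CHEMICAL, "D016190", 2)
    doc.mentions.sort(key=lambda m: (m.start, m.end))
    doc.relations.append(Relation("7468724", "D016190", "D007674"))
    doc.validate()
    return doc


@pytest.fixture(scope="session")
def annotated_record() -> Document:
    return _annotated_record()
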