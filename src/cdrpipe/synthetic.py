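"""Synthetic PubTator corpora with planted mentions, IDs, abbreviations and
CID relations, so every pipeline stage can be trained and tested hermetically.

The generator emulates title+abstract records: morphologically plausible
chemical and disease names (prefix+stem+suffix pools, so affix and shape
features are informative), span-annotated mentions carrying MeSH-style IDs,
abbreviation definitions ``long form (SF)`` with later short-form references,
and document-level CID relations.

Relation semantics.  Each document contains 1-3 chemical-disease "events":

* trigger event — chemical and disease in one sentence joined by a
  three-token inductive connector ("... induced ..."); always relational;
* knowledge event — a pair from the known-pair list co-mentioned in one
  sentence with one unmappable mention between them; always relational;
* distractor events — trigger-free co-mentions, either in one sentence with
  an unmappable mention between (same surface shape as a knowledge event) or
  across adjacent sentences; never relational.

A relation is therefore planted iff the pair co-occurs within two sentences
and the connecting template carries a trigger or the pair is in the knowledge
set.  Trigger tokens sit between the paired mentions, never inside mention
text, so the relation classifier must rely on the knowledge-pair feature and
the mention-density statistic rather than mention bags-of-words.  Every
template keeps at least three tokens before its first mention and two after
its last, so pairs from different sentences are always separated by more
tokens than same-sentence event pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._text import canonicalize
from .corpus import (
    CandidateSource,
    DictionaryEntry,
    Document,
    EntityType,
    Mention,
    NameCandidateList,
    Relation,
    UNMAPPED,
)
from .preprocess import preprocess_document

__all__ = [
    "GeneratorConfig",
    "SyntheticWorld",
    "SyntheticCorpus",
    "build_world",
    "generate_corpus",
    "corrupt_predictions",
]


@dataclass
class GeneratorConfig:
    seed: int
    n_docs: int = 300
    n_chemicals: int = 40
    n_diseases: int = 40
    abbrev_rate: float = 0.25
    relation_trigger_rate: float = 0.5
    distractor_rate: float = 0.5
    tagger_noise: float = 0.1
    kb_rate: float = 0.2
    n_kb_pairs: int = 25
    n_orphans: int = 12

    def __post_init__(self) -> None:
        for name in (
            "abbrev_rate",
            "relation_trigger_rate",
            "distractor_rate",
            "tagger_noise",
            "kb_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class SyntheticWorld:
    chemicals: dict[str, str]  # name -> ID
    diseases: dict[str, str]
    orphans: list[str]  # names annotated but not mappable (ID -1)
    knowledge: set[tuple[str, str]]  # (chem ID, disease ID)

    def dictionary_entries(self) -> list[DictionaryEntry]:
        out = [
            DictionaryEntry(name, cid, EntityType.CHEMICAL)
            for name, cid in self.chemicals.items()
        ]
        out += [
            DictionaryEntry(name, cid, EntityType.DISEASE)
            for name, cid in self.diseases.items()
        ]
        return out


@dataclass
class SyntheticCorpus:
    train: list[Document]
    test: list[Document]
    world: SyntheticWorld
    candidate_lists: dict[tuple[str, CandidateSource], NameCandidateList] = field(
        default_factory=dict
    )
    # event bookkeeping: how many knowledge / trigger / distractor events
    # were generated (used by statistical self-checks)
    stats: dict[str, int] = field(default_factory=dict)

    @property
    def documents(self) -> list[Document]:
        return self.train + self.test


_CHEM_PRE = ["flu", "meth", "carb", "oxa", "pheno", "chlor", "sulf", "keto",
             "benz", "nitro", "dextro", "levo", "amo", "cipro", "halo"]
_CHEM_MID = ["an", "ox", "ard", "ep", "im", "ur", "al", "en", "iz", "ast"]
_CHEM_SUF = ["ine", "ol", "ate", "mide", "azole", "icin", "arin", "oxin"]

_DIS_PRE = ["cardi", "nephr", "neur", "hepat", "derm", "arthr", "encephal",
            "pulmon", "gastr", "oste", "myel", "vascul"]
_DIS_MID = ["o", "oa", "io"]
_DIS_SUF = ["itis", "emia", "pathy", "oma", "osis", "algia"]
_DIS_ADJ = ["acute", "chronic", "toxic", "renal", "hepatic", "refractory",
            "congenital", "transient"]


def _name_pool(pres: list[str], mids: list[str], sufs: list[str]) -> list[str]:
    return ["".join(parts) for parts in itertools.product(pres, mids, sufs)]


def build_world(cfg: GeneratorConfig) -> SyntheticWorld:
    """Deterministic lexicons, orphan names and knowledge pairs."""
    rng = np.random.default_rng(cfg.seed)
    chem_pool = _name_pool(_CHEM_PRE, _CHEM_MID, _CHEM_SUF)
    dis_pool = _name_pool(_DIS_PRE, _DIS_MID, _DIS_SUF)
    if cfg.n_chemicals > len(chem_pool):
        raise ValueError(f"n_chemicals exceeds the {len(chem_pool)}-name pool")
    if cfg.n_diseases + cfg.n_orphans > len(dis_pool) * (1 + len(_DIS_ADJ)):
        raise ValueError("n_diseases exceeds the disease name pool")
    chem_names = [chem_pool[i] for i in rng.choice(len(chem_pool), cfg.n_chemicals, replace=False)]
    base = [dis_pool[i] for i in rng.choice(len(dis_pool), cfg.n_diseases + cfg.n_orphans, replace=False)]
    dis_names = []
    for i, name in enumerate(base[: cfg.n_diseases]):
        if rng.random() < 0.5:
            name = f"{_DIS_ADJ[int(rng.integers(len(_DIS_ADJ)))]} {name}"
        dis_names.append(name)
    orphans = base[cfg.n_diseases :]
    seen = {canonicalize(n) for n in chem_names}
    for n in dis_names + orphans:
        key = canonicalize(n)
        if key in seen:
            raise ValueError(f"name collision after canonicalization: {n!r}")
        seen.add(key)
    chemicals = {n: f"D{1000 + i:06d}" for i, n in enumerate(chem_names)}
    diseases = {n: f"D{500000 + i:06d}" for i, n in enumerate(dis_names)}
    chem_ids = sorted(chemicals.values())
    dis_ids = sorted(diseases.values())
    pairs: set[tuple[str, str]] = set()
    while len(pairs) < min(cfg.n_kb_pairs, len(chem_ids) * len(dis_ids)):
        pairs.add(
            (
                chem_ids[int(rng.integers(len(chem_ids)))],
                dis_ids[int(rng.integers(len(dis_ids)))],
            )
        )
    return SyntheticWorld(
        chemicals=chemicals, diseases=diseases, orphans=orphans, knowledge=pairs
    )


# --- sentence templates -----------------------------------------------------
# Layout invariant: >= 3 tokens before the first mention slot and >= 2 tokens
# (plus the period) after the last, so cross-sentence mention pairs always
# have a larger token gap than same-sentence event pairs.

_LEADS = [
    "In this cohort",
    "In the present study",
    "During the trial",
    "Among treated subjects",
    "Across both groups",
]
_TAILS = ["during therapy", "in most cases", "within days", "after admission"]
_TRIGGERS = [
    "consistently induced severe",
    "repeatedly induced transient",
    "apparently induced progressive",
    "induced clinically significant",
]
_FILLERS = [
    "The cohort was followed for twelve months.",
    "Laboratory values remained stable throughout the study.",
    "Informed consent was obtained from all participants.",
    "Dosage adjustments were recorded at every visit.",
    "No protocol deviations were reported by the investigators.",
]


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.title = ""
        self.parts: list[str] = []
        self.mentions: list[Mention] = []
        self.relations: list[Relation] = []
        self._pending: list[tuple[int, int, str, EntityType, str]] = []

    def set_title(self, text: str, mentions: list[tuple[int, str, EntityType, str]]) -> None:
        self.title = text
        for offset, name, etype, cid in mentions:
            self._pending.append((offset, offset + len(name), name, etype, cid))

    def add_sentence(
        self, text: str, mentions: list[tuple[int, str, EntityType, str]] = ()
    ) -> None:
        base = len(self.title) + 1 + sum(len(p) + 1 for p in self.parts)
        self.parts.append(text)
        for offset, name, etype, cid in mentions:
            self._pending.append(
                (base + offset, base + offset + len(name), name, etype, cid)
            )

    def build(self) -> Document:
        doc = Document(
            doc_id=self.doc_id, title=self.title, abstract=" ".join(self.parts)
        )
        for start, end, name, etype, cid in self._pending:
            doc.mentions.append(Mention(self.doc_id, start, end, name, etype, cid))
        doc.mentions.sort(key=lambda m: (m.start, m.end))
        doc.relations = sorted(set(self.relations), key=lambda r: (r.chemical_id, r.disease_id))
        doc.validate()
        return doc


def _pick(rng: np.random.Generator, seq: Sequence[str]) -> str:
    return seq[int(rng.integers(len(seq)))]


def _short_form(name: str) -> str:
    words = name.split()
    if len(words) >= 2:
        return "".join(w[0].upper() for w in words)
    return name[:3].upper()


def _generate_document(
    doc_id: str,
    world: SyntheticWorld,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    stats: dict[str, int] | None = None,
) -> Document:
    if stats is None:
        stats = {}
    b = _DocBuilder(doc_id)
    chem_names = sorted(world.chemicals)
    dis_names = sorted(world.diseases)
    n_events = int(rng.integers(1, 4))
    # sample per-document concepts; reject cross pairs that sit in the
    # knowledge set so the planted-relation rule stays clean
    for _ in range(200):
        chems = [chem_names[i] for i in rng.choice(len(chem_names), n_events, replace=False)]
        diss = [dis_names[i] for i in rng.choice(len(dis_names), n_events, replace=False)]
        cross_kb = any(
            (world.chemicals[c], world.diseases[d]) in world.knowledge
            and i != j
            for i, c in enumerate(chems)
            for j, d in enumerate(diss)
        )
        if not cross_kb:
            break
    # title: singleton mention or plain
    if rng.random() < 0.5:
        name = _pick(rng, chem_names + dis_names)
        etype = (
            EntityType.CHEMICAL if name in world.chemicals else EntityType.DISEASE
        )
        cid = world.chemicals.get(name) or world.diseases[name]
        prefix = "Case reports describing "
        b.set_title(
            f"{prefix}{name} toxicity in adults.", [(len(prefix), name, etype, cid)]
        )
    else:
        b.set_title("Clinical observations from a prospective cohort study.", [])

    # abbreviation definitions for event concepts
    abbrevs: dict[str, str] = {}
    used_sf: set[str] = set()
    for name in chems + diss:
        if rng.random() >= cfg.abbrev_rate:
            continue
        sf = _short_form(name)
        if canonicalize(sf) in used_sf or sf in world.chemicals or sf in world.diseases:
            continue
        used_sf.add(canonicalize(sf))
        abbrevs[name] = sf
        etype = EntityType.CHEMICAL if name in world.chemicals else EntityType.DISEASE
        cid = world.chemicals.get(name) or world.diseases[name]
        prefix = "The records described "
        b.add_sentence(
            f"{prefix}{name} ({sf}) in several subjects.",
            [(len(prefix), name, etype, cid)],
        )

    # events
    for c_name, d_name in zip(chems, diss):
        c_id = world.chemicals[c_name]
        d_id = world.diseases[d_name]
        lead = _pick(rng, _LEADS)
        tail = _pick(rng, _TAILS)
        in_kb = (c_id, d_id) in world.knowledge
        relational = False
        if not in_kb and rng.random() < cfg.kb_rate and world.knowledge:
            # re-draw the pair from the knowledge list for a knowledge event
            kb_sorted = sorted(world.knowledge)
            c_id, d_id = kb_sorted[int(rng.integers(len(kb_sorted)))]
            c_name = next(n for n, i in world.chemicals.items() if i == c_id)
            d_name = next(n for n, i in world.diseases.items() if i == d_id)
            in_kb = True
        if in_kb:
            orphan = _pick(rng, world.orphans)
            prefix = f"{lead} "
            mid = f"{prefix}{c_name}, {orphan} and "
            b.add_sentence(
                f"{mid}{d_name} {tail}.",
                [
                    (len(prefix), c_name, EntityType.CHEMICAL, c_id),
                    (len(f"{prefix}{c_name}, "), orphan, EntityType.DISEASE, UNMAPPED),
                    (len(mid), d_name, EntityType.DISEASE, d_id),
                ],
            )
            relational = True
            stats["kb_events"] = stats.get("kb_events", 0) + 1
        elif rng.random() < cfg.relation_trigger_rate:
            trig = _pick(rng, _TRIGGERS)
            prefix = f"{lead} "
            mid = f"{prefix}{c_name} {trig} "
            b.add_sentence(
                f"{mid}{d_name} {tail}.",
                [
                    (len(prefix), c_name, EntityType.CHEMICAL, c_id),
                    (len(mid), d_name, EntityType.DISEASE, d_id),
                ],
            )
            relational = True
            stats["trigger_events"] = stats.get("trigger_events", 0) + 1
        elif rng.random() < cfg.distractor_rate:
            # same-sentence trigger-free co-mention, one unmappable mention
            # between the pair — surface shape of a knowledge event
            stats["distractor_events"] = stats.get("distractor_events", 0) + 1
            orphan = _pick(rng, world.orphans)
            prefix = f"{lead} "
            mid = f"{prefix}{c_name}, {orphan} and "
            b.add_sentence(
                f"{mid}{d_name} {tail}.",
                [
                    (len(prefix), c_name, EntityType.CHEMICAL, c_id),
                    (len(f"{prefix}{c_name}, "), orphan, EntityType.DISEASE, UNMAPPED),
                    (len(mid), d_name, EntityType.DISEASE, d_id),
                ],
            )
        else:
            # cross-sentence trigger-free co-mention
            stats["distractor_events"] = stats.get("distractor_events", 0) + 1
            prefix = f"{lead} "
            b.add_sentence(
                f"{prefix}{c_name} was administered {tail}.",
                [(len(prefix), c_name, EntityType.CHEMICAL, c_id)],
            )
            prefix2 = "Signs consistent with "
            b.add_sentence(
                f"{prefix2}{d_name} were documented {_pick(rng, _TAILS)}.",
                [(len(prefix2), d_name, EntityType.DISEASE, d_id)],
            )
        if relational:
            b.relations.append(Relation(doc_id, c_id, d_id))
        if rng.random() < 0.5:
            b.add_sentence(_pick(rng, _FILLERS))

    # short-form references for abbreviated concepts
    for name, sf in sorted(abbrevs.items()):
        etype = EntityType.CHEMICAL if name in world.chemicals else EntityType.DISEASE
        cid = world.chemicals.get(name) or world.diseases[name]
        prefix = "Episodes attributed to "
        b.add_sentence(
            f"{prefix}{sf} resolved after discontinuation.",
            [(len(prefix), sf, etype, cid)],
        )

    while len(b.parts) < 4:
        b.add_sentence(_pick(rng, _FILLERS))
    return b.build()


def _candidate_lists(
    world: SyntheticWorld, rng: np.random.Generator
) -> dict[tuple[str, CandidateSource], NameCandidateList]:
    """Offline stand-ins for the name-normalization look-ups.

    The MeSH-style list always contains the correct dictionary name at a
    uniform random rank among dictionary distractors; the Wikipedia-style
    list contains it only half the time, padded with off-dictionary names.
    """
    all_names = sorted(world.chemicals) + sorted(world.diseases)
    fake = [f"{n} variant syndrome" for n in all_names]
    out: dict[tuple[str, CandidateSource], NameCandidateList] = {}
    for name in all_names:
        others = [n for n in all_names if n != name]
        mesh = [others[i] for i in rng.choice(len(others), 4, replace=False)]
        mesh.insert(int(rng.integers(5)), name)
        wiki = [fake[i] for i in rng.choice(len(fake), 4, replace=False)]
        if rng.random() < 0.5:
            wiki.insert(int(rng.integers(5)), name)
        key = canonicalize(name)
        out[(key, CandidateSource.MESH_SEARCH)] = NameCandidateList(
            key, CandidateSource.MESH_SEARCH, mesh
        )
        out[(key, CandidateSource.WIKIPEDIA)] = NameCandidateList(
            key, CandidateSource.WIKIPEDIA, wiki
        )
    return out


def generate_corpus(
    world: SyntheticWorld, cfg: GeneratorConfig
) -> SyntheticCorpus:
    """Generate documents and sidecar resources; 2:1 train/test split by
    document, fixed before any model sees the data."""
    rng = np.random.default_rng(cfg.seed + 1)
    stats: dict[str, int] = {}
    docs = [
        _generate_document(f"{90000000 + i}", world, cfg, rng, stats)
        for i in range(cfg.n_docs)
    ]
    n_train = (2 * cfg.n_docs) // 3
    return SyntheticCorpus(
        train=docs[:n_train],
        test=docs[n_train:],
        world=world,
        candidate_lists=_candidate_lists(world, np.random.default_rng(cfg.seed + 2)),
        stats=stats,
    )


def dictionary_tsv(world: SyntheticWorld) -> str:
    lines = [
        f"{e.surface_name}\t{e.concept_id}\t{e.etype.value}"
        for e in world.dictionary_entries()
    ]
    return "\n".join(lines) + "\n"


def knowledge_tsv(world: SyntheticWorld) -> str:
    return "\n".join(f"{c}\t{d}" for c, d in sorted(world.knowledge)) + "\n"


def candidates_tsv(
    lists: dict[tuple[str, CandidateSource], NameCandidateList],
    source: CandidateSource,
) -> str:
    rows = []
    for (text, src), clist in sorted(lists.items()):
        if src != source:
            continue
        for rank, name in enumerate(clist.candidates, start=1):
            rows.append(f"{text}\t{src.value}\t{rank}\t{name}")
    return "\n".join(rows) + "\n"


def corrupt_predictions(
    docs: Sequence[Document],
    noise: float,
    mode: str,
    seed: int,
    mentions_by_doc: dict[str, list[Mention]] | None = None,
) -> dict[str, list[Mention]]:
    """Derive corrupted prediction sets from gold (or given) mentions.

    ``BOUNDARY`` extends or shrinks a mention by one token, ``DROP`` deletes
    it, ``TYPE`` flips Chemical/Disease — each independently with probability
    ``noise``.
    """
    if mode not in {"BOUNDARY", "DROP", "TYPE"}:
        raise ValueError(f"unknown corruption mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: dict[str, list[Mention]] = {}
    for doc in docs:
        source = (
            mentions_by_doc[doc.doc_id]
            if mentions_by_doc is not None
            else doc.mentions
        )
        text = doc.text
        token_spans = [
            (t.start, t.end)
            for s in preprocess_document(doc)
            for t in s.tokens
        ]
        corrupted: list[Mention] = []
        for m in source:
            if rng.random() >= noise:
                corrupted.append(
                    Mention(m.doc_id, m.start, m.end, m.text, m.etype, m.concept_id)
                )
                continue
            if mode == "DROP":
                continue
            if mode == "TYPE":
                flipped = (
                    EntityType.DISEASE
                    if m.etype == EntityType.CHEMICAL
                    else EntityType.CHEMICAL
                )
                corrupted.append(
                    Mention(m.doc_id, m.start, m.end, m.text, flipped, m.concept_id)
                )
                continue
            inside = [i for i, (s, e) in enumerate(token_spans) if s >= m.start and e <= m.end]
            grow = rng.random() < 0.5 or len(inside) <= 1
            if grow:
                after = [i for i, (s, e) in enumerate(token_spans) if s >= m.end]
                before = [i for i, (s, e) in enumerate(token_spans) if e <= m.start]
                if rng.random() < 0.5 and after:
                    new = (m.start, token_spans[after[0]][1])
                elif before:
                    new = (token_spans[before[-1]][0], m.end)
                elif after:
                    new = (m.start, token_spans[after[0]][1])
                else:
                    new = (m.start, m.end)
            else:
                new = (m.start, token_spans[inside[-2]][1])
            corrupted.append(
                Mention(m.doc_id, new[0], new[1], text[new[0] : new[1]], m.etype, m.concept_id)
            )
        out[doc.doc_id] = corrupted
    return out
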