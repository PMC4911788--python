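"""Train/predict/evaluate orchestration over all pipeline stages.

A single YAML/JSON config file drives the pipeline; a trained model bundle
is a directory of JSON files (taggers, meta-classifier, optional re-ranker,
CID classifier with its fitted gap threshold) plus a manifest recording the
config hash and seed, so identical config + seed reproduce byte-identical
predictions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import cid as cid_mod
from .corpus import (
    Document,
    Mention,
    PubtatorError,
    dumps_pubtator,
    load_candidate_lists,
    load_dictionary,
    load_knowledge,
    parse_pubtator,
)
from .ensemble import MentionEnsemble, stacking_instances
from .evaluate import EvalLevel, EvalResult, evaluate
from .features import FeatureExtractor, FrequencyModel, Gazetteer
from .normalize import (
    CandidateReranker,
    DictionaryIndex,
    NormalizationResources,
    NormalizationStrategy,
    RankQuery,
    normalize_document,
)
from .preprocess import TaggedSentence, preprocess_document
from .corpus import EntityType, UNMAPPED
from .taggers import ChainCRFTagger, StructuredPerceptronTagger, load_tagger, project_labels

logger = logging.getLogger("cdrpipe")

__all__ = ["PipelineConfig", "ModelBundle", "run_train", "run_predict", "run_eval"]

_KNOWN_TOP = {"seed", "paths", "tagger", "ensemble", "norm", "cid"}
_KNOWN_PATHS = {
    "train_corpus",
    "dict_chemical",
    "dict_disease",
    "knowledge",
    "candidates_mesh",
    "candidates_wiki",
    "model_dir",
}


@dataclass
class PipelineConfig:
    seed: int
    paths: dict[str, str]
    tagger: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    norm: dict = field(default_factory=dict)
    cid: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_TOP
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        paths = dict(raw.get("paths", {}))
        unknown = set(paths) - _KNOWN_PATHS
        if unknown:
            raise ValueError(f"unknown path keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config requires a global seed")
        return cls(
            seed=int(raw["seed"]),
            paths=paths,
            tagger=dict(raw.get("tagger", {})),
            ensemble=dict(raw.get("ensemble", {})),
            norm=dict(raw.get("norm", {})),
            cid=dict(raw.get("cid", {})),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_mapping(raw)

    def validate_paths(self, require_training: bool) -> None:
        required = ["dict_chemical", "dict_disease", "model_dir"]
        if require_training:
            required += ["train_corpus"]
        for key in required:
            if key not in self.paths:
                raise ValueError(f"config missing required path {key!r}")
            if key != "model_dir" and not Path(self.paths[key]).exists():
                raise ValueError(f"path {key!r} does not exist: {self.paths[key]}")

    def digest(self) -> str:
        canon = json.dumps(
            {
                "seed": self.seed,
                "paths": {k: str(v) for k, v in sorted(self.paths.items())},
                "tagger": self.tagger,
                "ensemble": self.ensemble,
                "norm": self.norm,
                "cid": self.cid,
            },
            sort_keys=True,
        )
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class ModelBundle:
    extractor: FeatureExtractor
    crf: ChainCRFTagger
    margin: StructuredPerceptronTagger
    meta: MentionEnsemble
    resources: NormalizationResources
    strategy: NormalizationStrategy
    cid_model: cid_mod.CIDClassifier
    cid_cfg: cid_mod.FilterConfig
    knowledge: set[tuple[str, str]]


def _preprocess_all(docs: Sequence[Document]) -> dict[str, list[TaggedSentence]]:
    return {d.doc_id: preprocess_document(d) for d in docs}


def build_extractor(
    chem_entries, dis_entries, train_docs: Sequence[Document],
    sentences_by_doc: dict[str, list[TaggedSentence]],
) -> FeatureExtractor:
    freq = FrequencyModel().fit(
        [
            [t.text for s in sentences_by_doc[d.doc_id] for t in s.tokens]
            for d in train_docs
        ]
    )
    return FeatureExtractor(
        chem_gazetteer=Gazetteer.from_entries(chem_entries, EntityType.CHEMICAL),
        disease_gazetteer=Gazetteer.from_entries(dis_entries, EntityType.DISEASE),
        frequency_model=freq,
    )


def train_taggers(
    docs: Sequence[Document],
    sentences_by_doc: dict[str, list[TaggedSentence]],
    extractor: FeatureExtractor,
    tagger_cfg: dict,
    seed: int,
) -> tuple[ChainCRFTagger, StructuredPerceptronTagger]:
    sents: list[TaggedSentence] = []
    labels: list[list[str]] = []
    for d in docs:
        ds = sentences_by_doc[d.doc_id]
        sents.extend(ds)
        labels.extend(project_labels(d, ds))
    crf = ChainCRFTagger(
        extractor=extractor,
        l2=float(tagger_cfg.get("l2", 0.1)),
        max_iter=int(tagger_cfg.get("max_iter", 100)),
        seed=seed,
    ).fit(sents, labels)
    margin = StructuredPerceptronTagger(
        extractor=extractor,
        epochs=int(tagger_cfg.get("epochs", 10)),
        seed=seed + 1,
    ).fit(sents, labels)
    return crf, margin


def cross_validated_proposals(
    docs: Sequence[Document],
    sentences_by_doc: dict[str, list[TaggedSentence]],
    extractor: FeatureExtractor,
    tagger_cfg: dict,
    folds: int,
    seed: int,
) -> dict[str, dict[str, list[Mention]]]:
    """Per-document tagger proposals from document-level cross-validation.

    Every document's proposals come from taggers trained on the other folds,
    the standard stacking protocol.
    """
    proposals: dict[str, dict[str, list[Mention]]] = {}
    folds = min(folds, len(docs))
    for k in range(folds):
        held = [d for i, d in enumerate(docs) if i % folds == k]
        rest = [d for i, d in enumerate(docs) if i % folds != k]
        crf, margin = train_taggers(rest, sentences_by_doc, extractor, tagger_cfg, seed + k)
        for d in held:
            ds = sentences_by_doc[d.doc_id]
            proposals[d.doc_id] = {
                "CRF": crf.predict_mentions(d, ds),
                "MARGIN_STRUCT": margin.predict_mentions(d, ds),
            }
    return proposals


def train_cid_stage(
    docs: Sequence[Document],
    sentences_by_doc: dict[str, list[TaggedSentence]],
    cid_cfg_raw: dict,
    knowledge: set[tuple[str, str]],
    seed: int,
) -> tuple[cid_mod.CIDClassifier, cid_mod.FilterConfig]:
    window = int(cid_cfg_raw.get("window", 3))
    step2: list[cid_mod.CIDCandidate] = []
    for d in docs:
        cands = cid_mod.generate_step2_candidates(
            d, sentences_by_doc[d.doc_id], sentence_window=window
        )
        cid_mod.label_candidates(cands, d.relations)
        step2.extend(cands)
    raw_threshold = cid_cfg_raw.get("gap_threshold", cid_mod.AUTO)
    if raw_threshold == cid_mod.AUTO:
        threshold = cid_mod.fit_gap_threshold(step2)
    else:
        threshold = int(raw_threshold)
    cfg = cid_mod.FilterConfig(sentence_window=window, gap_threshold=threshold)
    kept = [c for c in step2 if c.word_gap <= threshold]
    n_pos = sum(c.label == "TRUE" for c in kept)
    logger.info(
        "cid filter: %d step-2 candidates, %d kept (threshold %d), %d/%d pos/neg",
        len(step2), len(kept), threshold, n_pos, len(kept) - n_pos,
    )
    model = cid_mod.CIDClassifier(
        C=float(cid_cfg_raw.get("C", 1.0)),
        class_weight=cid_cfg_raw.get("class_weight"),
        seed=seed,
    ).fit(kept, knowledge)
    return model, cfg


def _train_reranker(
    docs: Sequence[Document],
    resources: NormalizationResources,
    seed: int,
) -> CandidateReranker | None:
    queries: list[RankQuery] = []
    for d in docs:
        context = [m.text for m in d.mentions]
        for m in d.mentions:
            if m.concept_id == UNMAPPED:
                continue
            mesh, wiki = resources.lists_for(m.text)
            if mesh is None and wiki is None:
                continue
            queries.append(
                RankQuery(
                    mention_text=m.text,
                    context_mentions=[c for c in context if c != m.text],
                    mesh_list=mesh,
                    wiki_list=wiki,
                    gold_concept_id=m.concept_id,
                )
            )
    if not queries:
        return None
    try:
        return CandidateReranker(seed=seed).fit(
            queries, resources.chem_dictionary
        )
    except ValueError:
        return None


class _RerankDict(DictionaryIndex):
    """Union view over the chemical and disease dictionaries for re-ranker
    training, where candidate names may belong to either type."""

    def __init__(self, chem: DictionaryIndex, dis: DictionaryIndex):
        self._by_key = dict(dis._by_key)
        self._by_key.update(chem._by_key)


def run_train(config: PipelineConfig) -> Path:
    """Train every stage and write the model bundle; returns the bundle dir."""
    t0 = time.time()
    config.validate_paths(require_training=True)
    docs = parse_pubtator(Path(config.paths["train_corpus"]).read_text())
    if not docs:
        raise PubtatorError("training corpus contains no documents")
    chem_entries = load_dictionary(Path(config.paths["dict_chemical"]).read_text())
    dis_entries = load_dictionary(Path(config.paths["dict_disease"]).read_text())
    knowledge = (
        load_knowledge(Path(config.paths["knowledge"]).read_text())
        if "knowledge" in config.paths
        else set()
    )
    cand_lists = {}
    for key in ("candidates_mesh", "candidates_wiki"):
        if key in config.paths and Path(config.paths[key]).exists():
            cand_lists.update(
                load_candidate_lists(Path(config.paths[key]).read_text())
            )
    sentences_by_doc = _preprocess_all(docs)
    extractor = build_extractor(chem_entries, dis_entries, docs, sentences_by_doc)
    logger.info("preprocessed %d documents in %.1fs", len(docs), time.time() - t0)

    crf, margin = train_taggers(
        docs, sentences_by_doc, extractor, config.tagger, config.seed
    )
    logger.info("taggers trained in %.1fs", time.time() - t0)

    folds = int(config.ensemble.get("cv_folds", 5))
    proposals = cross_validated_proposals(
        docs, sentences_by_doc, extractor, config.tagger, folds, config.seed + 100
    )
    cands, labels = stacking_instances(docs, sentences_by_doc, proposals)
    meta = MentionEnsemble(
        C=float(config.ensemble.get("C", 1.0)),
        threshold=float(config.ensemble.get("threshold", 0.0)),
        cv_folds=folds,
        seed=config.seed + 200,
    ).fit(cands, labels)
    logger.info(
        "meta-classifier trained on %d candidates (%d positive) in %.1fs",
        len(cands), sum(labels), time.time() - t0,
    )

    chem_index = DictionaryIndex(chem_entries)
    dis_index = DictionaryIndex(dis_entries)
    resources = NormalizationResources(
        chem_dictionary=chem_index,
        disease_dictionary=dis_index,
        candidate_lists=cand_lists,
    )
    reranker = None
    if cand_lists:
        union = _RerankDict(chem_index, dis_index)
        union_resources = NormalizationResources(
            chem_dictionary=union,
            disease_dictionary=union,
            candidate_lists=cand_lists,
        )
        reranker = _train_reranker(docs, union_resources, config.seed + 300)

    cid_model, cid_cfg = train_cid_stage(
        docs, sentences_by_doc, config.cid, knowledge, config.seed + 400
    )

    model_dir = Path(config.paths["model_dir"])
    model_dir.mkdir(parents=True, exist_ok=True)
    (model_dir / "crf.json").write_text(json.dumps(crf.to_json()))
    (model_dir / "margin.json").write_text(json.dumps(margin.to_json()))
    (model_dir / "meta.json").write_text(
        json.dumps(
            {
                "feature_names": meta.feature_names_,
                "coef": np.asarray(meta.coef_).tolist(),
                "intercept": meta.intercept_,
                "threshold": meta.threshold,
            }
        )
    )
    if reranker is not None:
        (model_dir / "reranker.json").write_text(
            json.dumps(
                {
                    "feature_names": reranker.feature_names_,
                    "coef": np.asarray(reranker.coef_).tolist(),
                }
            )
        )
    (model_dir / "cid.json").write_text(
        json.dumps(
            {
                "feature_names": cid_model.feature_names_,
                "coef": np.asarray(cid_model.coef_).tolist(),
                "intercept": cid_model.intercept_,
                "window": cid_cfg.sentence_window,
                "gap_threshold": cid_cfg.gap_threshold,
            }
        )
    )
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_train_docs": len(docs),
        "strategy": config.norm.get("strategy", "MAP_DIRECT"),
    }
    (model_dir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True))
    logger.info("bundle written to %s in %.1fs", model_dir, time.time() - t0)
    return model_dir


def load_bundle(config: PipelineConfig) -> ModelBundle:
    config.validate_paths(require_training=False)
    model_dir = Path(config.paths["model_dir"])
    chem_entries = load_dictionary(Path(config.paths["dict_chemical"]).read_text())
    dis_entries = load_dictionary(Path(config.paths["dict_disease"]).read_text())
    knowledge = (
        load_knowledge(Path(config.paths["knowledge"]).read_text())
        if "knowledge" in config.paths
        else set()
    )
    cand_lists = {}
    for key in ("candidates_mesh", "candidates_wiki"):
        if key in config.paths and Path(config.paths[key]).exists():
            cand_lists.update(
                load_candidate_lists(Path(config.paths[key]).read_text())
            )
    # the extractor must be rebuilt from the same training corpus resources;
    # frequency statistics ship implicitly through the saved feature vocab,
    # so prediction only needs the gazetteers (unknown keys are dropped).
    extractor = FeatureExtractor(
        chem_gazetteer=Gazetteer.from_entries(chem_entries, EntityType.CHEMICAL),
        disease_gazetteer=Gazetteer.from_entries(dis_entries, EntityType.DISEASE),
        frequency_model=None,
    )
    if "train_corpus" in config.paths and Path(config.paths["train_corpus"]).exists():
        train_docs = parse_pubtator(Path(config.paths["train_corpus"]).read_text())
        sents = _preprocess_all(train_docs)
        extractor = build_extractor(chem_entries, dis_entries, train_docs, sents)
    crf = load_tagger(json.loads((model_dir / "crf.json").read_text()), extractor)
    margin = load_tagger(json.loads((model_dir / "margin.json").read_text()), extractor)
    meta_raw = json.loads((model_dir / "meta.json").read_text())
    meta = MentionEnsemble(threshold=float(meta_raw["threshold"]))
    meta.feature_names_ = meta_raw["feature_names"]
    meta.coef_ = np.asarray(meta_raw["coef"])
    meta.intercept_ = float(meta_raw["intercept"])
    chem_index = DictionaryIndex(chem_entries)
    dis_index = DictionaryIndex(dis_entries)
    reranker = None
    if (model_dir / "reranker.json").exists():
        rr = json.loads((model_dir / "reranker.json").read_text())
        reranker = CandidateReranker()
        reranker.feature_names_ = rr["feature_names"]
        reranker.coef_ = np.asarray(rr["coef"])
    resources = NormalizationResources(
        chem_dictionary=chem_index,
        disease_dictionary=dis_index,
        candidate_lists=cand_lists,
        reranker=reranker,
    )
    cid_raw = json.loads((model_dir / "cid.json").read_text())
    cid_model = cid_mod.CIDClassifier()
    cid_model.feature_names_ = cid_raw["feature_names"]
    cid_model.coef_ = np.asarray(cid_raw["coef"])
    cid_model.intercept_ = float(cid_raw["intercept"])
    cid_cfg = cid_mod.FilterConfig(
        sentence_window=int(cid_raw["window"]),
        gap_threshold=int(cid_raw["gap_threshold"]),
    )
    strategy = NormalizationStrategy(config.norm.get("strategy", "MAP_DIRECT"))
    return ModelBundle(
        extractor=extractor,
        crf=crf,
        margin=margin,
        meta=meta,
        resources=resources,
        strategy=strategy,
        cid_model=cid_model,
        cid_cfg=cid_cfg,
        knowledge=knowledge,
    )


def predict_documents(
    bundle: ModelBundle, docs: Sequence[Document]
) -> list[Document]:
    """End-to-end prediction: mentions -> concept IDs -> CID relations."""
    out: list[Document] = []
    for doc in docs:
        sentences = preprocess_document(doc)
        proposals = {
            "CRF": bundle.crf.predict_mentions(doc, sentences),
            "MARGIN_STRUCT": bundle.margin.predict_mentions(doc, sentences),
        }
        cands = MentionEnsemble.featurize(proposals, sentences)
        kept = bundle.meta.apply(cands)
        pred = Document(
            doc_id=doc.doc_id,
            title=doc.title,
            abstract=doc.abstract,
            mentions=[
                Mention(m.doc_id, m.start, m.end, doc.text[m.start : m.end], m.etype)
                for m in kept
            ],
        )
        normalize_document(pred, bundle.strategy, bundle.resources)
        pred.relations = cid_mod.extract_relations(
            pred, sentences, bundle.cid_model, bundle.cid_cfg, bundle.knowledge
        )
        out.append(pred)
    return out


def run_predict(config: PipelineConfig, corpus_path: str | Path) -> str:
    """Predict over a PubTator file; returns annotated PubTator text."""
    bundle = load_bundle(config)
    docs = parse_pubtator(Path(corpus_path).read_text())
    return dumps_pubtator(predict_documents(bundle, docs))


def run_eval(
    gold: Sequence[Document], pred: Sequence[Document]
) -> dict[str, EvalResult]:
    return {
        level.value: evaluate(gold, pred, level)
        for level in (EvalLevel.MENTION, EvalLevel.CONCEPT, EvalLevel.RELATION)
    }
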