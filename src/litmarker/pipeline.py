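"""End-to-end workflow: query resolution, extraction, classification, ranking.

The report stage answers "which biomarkers does the literature relate to
this disease?": resolve the user's query against the disease vocabulary by
fuzzy matching, scan the corpus for sentences containing both a query
disease and a biomarker, classify each candidate sentence with the fitted
relation model, mine article tables with the two rule patterns, merge all
evidence into per-pair :class:`~litmarker.relations.RelationAssertion`
records, and rank biomarkers by occurrence count. Reports are cached by a
content hash of all inputs, so a rerun with unchanged inputs is a cache
hit with an identical report.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .entity_extraction import candidate_pairs, extract_document
from .lexicon import EntityType, MatchPolicy, Term, TermList, build_automaton, normalize_term
from .relation_model import ModelConfig, RelationClassifier, mask_and_shape, predict_relation
from .relations import EntityRef, Evidence, RelationAssertion
from .table_mining import (
    DEFAULT_MICROBIOME_COLLECTIVES,
    CollectiveTermList,
    mine_tables,
    parse_tables,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QueryResolution",
    "PipelineConfig",
    "Report",
    "resolve_query",
    "load_corpus_jsonl",
    "run_pipeline",
    "rank_biomarkers",
]


@dataclass
class QueryResolution:
    matches: list[tuple[Term, float]]
    suggestions: list[tuple[Term, float]] = field(default_factory=list)


def _similarity(a: str, b: str) -> float:
    return difflib.SequenceMatcher(None, a, b).ratio()


def resolve_query(query: str, term_list: TermList, cutoff: float = 0.85) -> QueryResolution:
    """Fuzzy-match a free-text query against a vocabulary.

    Terms whose best synonym similarity reaches ``cutoff`` are returned in
    descending similarity order with exact matches first; with no term
    above the cutoff, the top three below it are offered as suggestions.
    """
    if not query.strip():
        raise ValueError("empty query")
    q = normalize_term(query)
    scored: list[tuple[Term, float]] = []
    for term in term_list:
        best = max(_similarity(q, normalize_term(s)) for s in term.synonyms)
        scored.append((term, best))
    scored.sort(key=lambda ts: (-ts[1], ts[0].canonical))
    matches = [(t, s) for t, s in scored if s >= cutoff]
    if matches:
        return QueryResolution(matches=matches)
    return QueryResolution(matches=[], suggestions=scored[:3])


def load_corpus_jsonl(path: str | Path) -> list[dict]:
    """One document per line: {doc_id, title, text, tables:[{caption, head, body}]}."""
    docs: list[dict] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                docs.append(json.loads(line))
            except json.JSONDecodeError:
                logger.warning("%s:%d: bad JSON line skipped", path, lineno)
    return docs


@dataclass
class PipelineConfig:
    """Everything the report is a function of."""

    type_pair: tuple[EntityType, EntityType] = (EntityType.DISEASE, EntityType.MICROBIOME)
    model_config: ModelConfig = field(default_factory=ModelConfig)
    positive_label: str = "positive"
    collectives: CollectiveTermList = DEFAULT_MICROBIOME_COLLECTIVES
    match_policy: MatchPolicy = field(default_factory=MatchPolicy)
    query: str | None = None  # restrict to diseases resolving from this query
    query_cutoff: float = 0.85
    include_tables: bool = True
    cache_dir: str | Path | None = None


@dataclass
class Report:
    assertions: list[RelationAssertion]

    def to_dict(self) -> dict:
        return {
            "assertions": [
                {
                    "entity1": [a.entity1.term_id, a.entity1.entity_type.value],
                    "entity2": [a.entity2.term_id, a.entity2.entity_type.value],
                    "relation": a.relation,
                    "confidence": a.confidence,
                    "occurrence_count": a.occurrence_count,
                    "evidence": [
                        {
                            "doc_id": e.doc_id,
                            "kind": e.kind,
                            "sent_index": e.sent_index,
                            "table_index": e.table_index,
                            "unit": e.unit,
                            "text": e.text,
                            "pattern": e.pattern,
                        }
                        for e in a.evidence
                    ],
                }
                for a in self.assertions
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("entity1\tentity2\trelation\toccurrences\tconfidence\n")
            for a in self.assertions:
                conf = "" if a.confidence is None else f"{a.confidence:.4f}"
                fh.write(
                    f"{a.entity1.term_id}\t{a.entity2.term_id}\t{a.relation}\t"
                    f"{a.occurrence_count}\t{conf}\n"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "Report":
        assertions = []
        for rec in data["assertions"]:
            assertions.append(
                RelationAssertion(
                    entity1=EntityRef(rec["entity1"][0], EntityType(rec["entity1"][1])),
                    entity2=EntityRef(rec["entity2"][0], EntityType(rec["entity2"][1])),
                    relation=rec["relation"],
                    confidence=rec["confidence"],
                    evidence=[Evidence(**e) for e in rec["evidence"]],
                )
            )
        return cls(assertions=assertions)


def _cache_key(docs: Sequence[dict], term_lists: Sequence[TermList], model, config: PipelineConfig) -> str:
    h = hashlib.sha256()
    for doc in docs:
        h.update(json.dumps(doc, sort_keys=True).encode())
    for tl in term_lists:
        for t in tl:
            h.update(f"{t.term_id}|{t.entity_type.value}|{'|'.join(t.synonyms)}".encode())
    try:
        h.update(pickle.dumps(model))
    except Exception:  # unpicklable backend: fall back to identity
        h.update(repr(model).encode())
    h.update(
        repr(
            (
                config.type_pair,
                config.model_config,
                config.positive_label,
                config.collectives.terms,
                config.match_policy,
                config.query,
                config.query_cutoff,
                config.include_tables,
            )
        ).encode()
    )
    return h.hexdigest()


def run_pipeline(
    documents: Sequence[dict],
    term_lists: Sequence[TermList],
    model: RelationClassifier | None,
    config: PipelineConfig | None = None,
) -> Report:
    """Execute the full extraction chain and return merged assertions.

    The report is a pure function of (documents, term lists, model,
    config); with ``cache_dir`` set, it is stored under a SHA-256 content
    key and reruns with unchanged inputs are served from the cache.
    """
    config = config or PipelineConfig()
    if model is None:
        raise ValueError(
            "no fitted relation model: run the train step first (litmarker train)"
        )
    cache_path = None
    if config.cache_dir is not None:
        key = _cache_key(documents, term_lists, model, config)
        cache_path = Path(config.cache_dir) / f"report-{key}.json"
        if cache_path.exists():
            logger.info("cache hit: %s", cache_path)
            return Report.from_dict(json.loads(cache_path.read_text(encoding="utf-8")))

    anchor_type, target_type = config.type_pair
    anchor_terms: dict[str, Term] = {}
    query_ids: set[str] | None = None
    anchor_list = next((tl for tl in term_lists if tl.entity_type == anchor_type), None)
    if config.query and anchor_list is not None:
        res = resolve_query(config.query, anchor_list, cutoff=config.query_cutoff)
        query_ids = {t.term_id for t, _ in res.matches}
    automaton = build_automaton(list(term_lists), policy=config.match_policy)

    merged: dict[tuple, RelationAssertion] = {}

    def add(assertion: RelationAssertion) -> None:
        key = (
            (assertion.entity1.term_id, assertion.entity1.entity_type),
            (assertion.entity2.term_id, assertion.entity2.entity_type),
        )
        if key in merged:
            merged[key].merge(assertion)
        else:
            merged[key] = assertion

    for doc in documents:
        doc_id = str(doc.get("doc_id", ""))
        text = " ".join(filter(None, [doc.get("title", ""), doc.get("text", "")]))
        for sentence, mentions in extract_document(doc_id, text, automaton):
            for pair in candidate_pairs(mentions, sentence, config.type_pair):
                anchor_m = (
                    pair.mention1
                    if pair.mention1.entity_type == anchor_type
                    else pair.mention2
                )
                target_m = pair.mention2 if anchor_m is pair.mention1 else pair.mention1
                if query_ids is not None and anchor_m.term_id not in query_ids:
                    continue
                pred = predict_relation(model, mask_and_shape(pair, config.model_config), config.model_config)
                if pred.label != config.positive_label:
                    continue
                add(
                    RelationAssertion(
                        entity1=EntityRef(anchor_m.term_id, anchor_m.entity_type),
                        entity2=EntityRef(target_m.term_id, target_m.entity_type),
                        relation="associated",
                        confidence=pred.confidence,
                        evidence=[
                            Evidence(
                                doc_id=doc_id,
                                kind="sentence",
                                sent_index=sentence.sent_index,
                                text=sentence.text,
                            )
                        ],
                    )
                )
        if config.include_tables:
            anchor_tl = [tl for tl in term_lists if tl.entity_type == anchor_type]
            target_tl = [tl for tl in term_lists if tl.entity_type == target_type]
            if anchor_tl and target_tl:
                for assertion in mine_tables(
                    parse_tables(doc),
                    build_automaton(anchor_tl, policy=config.match_policy),
                    build_automaton(target_tl, policy=config.match_policy),
                    collectives=config.collectives,
                ):
                    if query_ids is not None and assertion.entity1.term_id not in query_ids:
                        continue
                    add(assertion)

    assertions = [
        merged[k]
        for k in sorted(
            merged, key=lambda key: (key[0][0], key[1][0])
        )
    ]
    report = Report(assertions=assertions)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        cache_path.write_text(
            json.dumps(report.to_dict(), sort_keys=True), encoding="utf-8"
        )
    return report


def rank_biomarkers(
    assertions: Iterable[RelationAssertion],
    term_list: TermList | None = None,
    top_k: int | None = None,
) -> list[tuple[str, str, int]]:
    """Rank target entities by total evidence occurrences.

    Returns (term_id, display name, occurrence count) rows, descending by
    count with ties broken lexicographically by the display name (canonical
    when a vocabulary is supplied).
    """
    counts: dict[str, int] = {}
    for a in assertions:
        counts[a.entity2.term_id] = counts.get(a.entity2.term_id, 0) + a.occurrence_count

    def display(term_id: str) -> str:
        if term_list is not None:
            t = term_list.get(term_id)
            if t is not None:
                return t.canonical
        return term_id

    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], display(kv[0])))
    rows = [(tid, display(tid), c) for tid, c in ranked]
    return rows[:top_k] if top_k is not None else rows
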