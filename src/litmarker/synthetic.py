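"""Synthetic corpora with planted entities, co-occurrence structure and tables.

Every pipeline stage is testable without any document download: the
generator plants disease and microbe mentions in templated sentences so
that the realized sentence-level co-occurrence count of each planted pair
equals the requested count exactly, plants frequency-one pairs for the
negative rule (both eligible three-entity sentences and excluded
two-entity ones), emits caption-pattern and row-pattern tables, and
records full ground truth (pair counts, instance labels, table
assertions). A fixed seed yields a byte-identical corpus.

Defaults mirror the skewed co-occurrence profile the weak labeler was
designed for: a small vocabulary (20 diseases x 20 microbes) with one
dominant pair far above every other, a tail of rare pairs, and filler
sentences carrying no entities.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .entity_extraction import CandidatePair, candidate_pairs, match_entities, split_and_tokenize
from .lexicon import EntityType, MatchAutomaton, Term, TermList, build_automaton
from .weak_labeling import LabeledInstance

__all__ = [
    "CorpusSpec",
    "SyntheticCorpus",
    "generate",
    "make_term_lists",
    "generate_instances",
    "BINARY_CUES",
    "GRANULAR_CUES",
]

# cue grammars: label -> the single planted cue token (None = no cue)
BINARY_CUES: dict[str, str | None] = {"positive": "associated", "negative": None}
GRANULAR_CUES: dict[str, str] = {
    "Predictive": "predicts",
    "Prognostic": "survival",
    "Diagnostic": "diagnostic",
    "Predisposing": "risk",
    "Treatment": "treatment",
}


def make_term_lists(n_diseases: int = 20, n_microbes: int = 20) -> dict[str, TermList]:
    """Invented two-token vocabularies exercising multi-token longest match."""
    diseases = [
        Term(
            term_id=f"D{i:03d}",
            entity_type=EntityType.DISEASE,
            canonical=f"dorvexin{i} syndrome",
            synonyms=(f"dorvexin{i} syndrome", f"dorvexin{i}"),
        )
        for i in range(n_diseases)
    ]
    microbes = [
        Term(
            term_id=f"M{i:03d}",
            entity_type=EntityType.MICROBIOME,
            canonical=f"Bacterius genomi{i}",
            synonyms=(f"Bacterius genomi{i}",),
        )
        for i in range(n_microbes)
    ]
    return {
        "disease": TermList(entity_type=EntityType.DISEASE, terms=diseases),
        "microbiome": TermList(entity_type=EntityType.MICROBIOME, terms=microbes),
    }


@dataclass(frozen=True)
class CorpusSpec:
    """What to plant; counts are realized exactly or generation errors out."""

    seed: int = 0
    n_docs: int = 20
    n_diseases: int = 20
    n_microbes: int = 20
    # (disease index, microbe index, sentence co-occurrence count)
    pair_counts: tuple[tuple[int, int, int], ...] = ()
    n_negative_triples: int = 0  # freq-1 pairs in 3-entity sentences (eligible negatives)
    n_excluded_negatives: int = 0  # freq-1 pairs in 2-entity sentences (excluded by rule)
    filler_per_doc: int = 3
    tables_a: int = 0  # caption-pattern tables
    tables_a_targets: int = 5  # microbes listed in each pattern-A body
    tables_b: int = 0  # row-pattern tables (one pair per row)
    tables_b_rows: int = 3
    positive_cue: str = "associated"
    max_sentences_per_doc: int = 200

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("need at least one document")
        for d, m, c in self.pair_counts:
            if c < 0 or d < 0 or m < 0:
                raise ValueError("pair counts and indices must be non-negative")
            if d >= self.n_diseases or m >= self.n_microbes:
                raise ValueError(f"pair index ({d},{m}) outside lexicon sizes")


@dataclass
class Truth:
    """Ground truth the generator guarantees."""

    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    # (doc_id, sent_index, disease_id, microbe_id, label, cue)
    instances: list[tuple[str, int, str, str, str, str | None]] = field(default_factory=list)
    table_assertions: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass
class SyntheticCorpus:
    documents: list[dict]
    term_lists: dict[str, TermList]
    truth: Truth
    spec: CorpusSpec

    def write_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for doc in self.documents:
                fh.write(json.dumps(doc, sort_keys=True) + "\n")

    def write_term_tsvs(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, tl in self.term_lists.items():
            p = directory / f"{name}.tsv"
            with p.open("w", encoding="utf-8") as fh:
                fh.write("term_id\tentity_type\tcanonical\tsynonyms\n")
                for t in tl:
                    fh.write(
                        f"{t.term_id}\t{t.entity_type.value}\t{t.canonical}\t"
                        + "|".join(t.synonyms)
                        + "\n"
                    )
            paths[name] = p
        return paths


def _positive_sentence(microbe: str, disease: str, cue: str, k: int) -> str:
    return f"Records indicate that {microbe} was {cue} with {disease} in cohort {k}."


def _triple_sentence(m1: str, m2: str, disease: str) -> str:
    return f"Levels of {m1} and {m2} were measured across {disease} cohorts."


def _two_entity_sentence(microbe: str, disease: str) -> str:
    return f"Samples of {microbe} were compared with {disease} controls."


def _filler_sentence(k: int) -> str:
    return f"The cohort design followed standard enrollment protocols in wave {k}."


def generate(spec: CorpusSpec) -> SyntheticCorpus:
    """Realize the spec; raises on infeasible sentence budgets or pair reuse."""
    rng = random.Random(spec.seed)
    lists = make_term_lists(spec.n_diseases, spec.n_microbes)
    diseases = lists["disease"].terms
    microbes = lists["microbiome"].terms
    truth = Truth()

    sentences: list[tuple[str, str, str, str | None]] = []  # text, d_id, m_id, cue
    used_pairs: set[tuple[int, int]] = set()
    k = 0
    for d, m, count in spec.pair_counts:
        if (d, m) in used_pairs:
            raise ValueError(f"pair ({d},{m}) planted twice")
        used_pairs.add((d, m))
        truth.pair_counts[(diseases[d].term_id, microbes[m].term_id)] = count
        for _ in range(count):
            k += 1
            sentences.append(
                (
                    _positive_sentence(
                        microbes[m].canonical, diseases[d].canonical, spec.positive_cue, k
                    ),
                    diseases[d].term_id,
                    microbes[m].term_id,
                    spec.positive_cue,
                )
            )

    def take_fresh_microbes(d: int, n: int) -> list[int]:
        found = [m for m in range(spec.n_microbes) if (d, m) not in used_pairs][:n]
        if len(found) < n:
            raise ValueError("not enough unused (disease, microbe) pairs for negatives")
        used_pairs.update((d, m) for m in found)
        return found

    for j in range(spec.n_negative_triples):
        d1 = j % spec.n_diseases
        m1, m2 = take_fresh_microbes(d1, 2)
        truth.pair_counts[(diseases[d1].term_id, microbes[m1].term_id)] = 1
        truth.pair_counts[(diseases[d1].term_id, microbes[m2].term_id)] = 1
        sentences.append(
            (
                _triple_sentence(
                    microbes[m1].canonical, microbes[m2].canonical, diseases[d1].canonical
                ),
                diseases[d1].term_id,
                microbes[m1].term_id,
                None,
            )
        )

    for j in range(spec.n_excluded_negatives):
        d = (j + 1) % spec.n_diseases
        (m,) = take_fresh_microbes(d, 1)
        truth.pair_counts[(diseases[d].term_id, microbes[m].term_id)] = 1
        sentences.append(
            (
                _two_entity_sentence(microbes[m].canonical, diseases[d].canonical),
                diseases[d].term_id,
                microbes[m].term_id,
                None,
            )
        )

    budget = spec.n_docs * spec.max_sentences_per_doc
    n_filler = spec.filler_per_doc * spec.n_docs
    if len(sentences) + n_filler > budget:
        raise ValueError(
            f"spec requires {len(sentences) + n_filler} sentences but budget is {budget} "
            f"({spec.n_docs} docs x {spec.max_sentences_per_doc})"
        )

    rng.shuffle(sentences)
    per_doc: list[list[tuple[str, str, str, str | None]]] = [[] for _ in range(spec.n_docs)]
    for i, sent in enumerate(sentences):
        per_doc[i % spec.n_docs].append(sent)

    documents: list[dict] = []
    table_docs = _make_tables(spec, diseases, microbes, truth)
    for doc_idx in range(spec.n_docs):
        doc_id = f"doc{doc_idx:04d}"
        doc_sents = list(per_doc[doc_idx])
        for f in range(spec.filler_per_doc):
            doc_sents.append((_filler_sentence(doc_idx * spec.filler_per_doc + f), "", "", None))
        rng.shuffle(doc_sents)
        text = " ".join(s[0] for s in doc_sents)
        for idx, (_, d_id, m_id, cue) in enumerate(doc_sents):
            if d_id:
                label = "positive" if cue else "negative"
                truth.instances.append((doc_id, idx, d_id, m_id, label, cue))
        documents.append(
            {
                "doc_id": doc_id,
                "title": f"Synthetic study {doc_idx}",
                "text": text,
                "tables": table_docs.get(doc_idx, []),
            }
        )
    return SyntheticCorpus(documents=documents, term_lists=lists, truth=truth, spec=spec)


def _make_tables(
    spec: CorpusSpec, diseases: Sequence[Term], microbes: Sequence[Term], truth: Truth
) -> dict[int, list[dict]]:
    """Plant pattern-A (caption) and pattern-B (row) tables round-robin over docs."""
    tables: dict[int, list[dict]] = {}
    mi = 0
    for t in range(spec.tables_a):
        d = diseases[t % len(diseases)]
        targets = [microbes[(mi + j) % len(microbes)] for j in range(spec.tables_a_targets)]
        mi += spec.tables_a_targets
        tables.setdefault(t % spec.n_docs, []).append(
            {
                "caption": f"Differentially abundant bacteria in {d.canonical} patients",
                "head": ["Microbe", "Direction"],
                "body": [[m.canonical, "up"] for m in targets],
            }
        )
        for m in targets:
            truth.table_assertions.append((d.term_id, m.term_id, "caption_pattern"))
    for t in range(spec.tables_b):
        d = diseases[(t + 7) % len(diseases)]
        rows = []
        for j in range(spec.tables_b_rows):
            m = microbes[(mi + j) % len(microbes)]
            rows.append([d.canonical, m.canonical, "0.01"])
            truth.table_assertions.append((d.term_id, m.term_id, "row_pattern"))
        mi += spec.tables_b_rows
        tables.setdefault((spec.tables_a + t) % spec.n_docs, []).append(
            {
                "caption": "Findings reported across cohorts",
                "head": ["Condition", "Taxon", "p-value"],
                "body": rows,
            }
        )
    return tables


def generate_instances(
    cue_by_label: Mapping[str, str | None],
    n_per_label: int,
    seed: int = 0,
    n_entities: int = 20,
    automaton: MatchAutomaton | None = None,
) -> list[LabeledInstance]:
    """Labeled (sentence, pair) instances whose label is a function of one cue token.

    The separable family used for learnability checks: class templates are
    identical except for the cue token ("associated" vs "examined" for the
    binary grammar; one verb per granular label). Mention spans come from
    the real matcher, so masking sees exactly what production sees.
    """
    rng = random.Random(seed)
    lists = make_term_lists(n_entities, n_entities)
    auto = automaton or build_automaton(list(lists.values()))
    diseases = lists["disease"].terms
    microbes = lists["microbiome"].terms
    out: list[LabeledInstance] = []
    for label in sorted(cue_by_label):
        cue = cue_by_label[label] or "examined"
        for i in range(n_per_label):
            d = diseases[rng.randrange(len(diseases))]
            m = microbes[rng.randrange(len(microbes))]
            text = _positive_sentence(m.canonical, d.canonical, cue, i)
            sent = split_and_tokenize(text, doc_id=f"syn-{label}-{i}")[0]
            mentions = match_entities(sent, auto)
            pairs = candidate_pairs(
                mentions, sent, (EntityType.DISEASE, EntityType.MICROBIOME)
            )
            if not pairs:
                raise RuntimeError("generated sentence lost its planted pair")
            out.append(LabeledInstance(pair=pairs[0], label=label, provenance="manual"))
    rng.shuffle(out)
    return out
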