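"""Output records: entity-pair relation assertions with evidence pointers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexicon import EntityType

__all__ = ["Evidence", "RelationAssertion", "EntityRef"]


@dataclass(frozen=True)
class EntityRef:
    term_id: str
    entity_type: EntityType


@dataclass(frozen=True)
class Evidence:
    """Pointer to the sentence or table unit supporting an assertion."""

    doc_id: str
    kind: str  # "sentence" | "table"
    sent_index: int | None = None
    table_index: int | None = None
    unit: str | None = None  # table unit, e.g. "caption", "head", "row:3"
    text: str | None = None
    pattern: str | None = None  # caption_pattern | row_pattern for table evidence


@dataclass
class RelationAssertion:
    """(entity1, entity2, relation, evidence, confidence) — the pipeline's output unit.

    ``occurrence_count`` is the number of distinct evidence items, the
    quantity the ranked biomarker report sorts on.
    """

    entity1: EntityRef
    entity2: EntityRef
    relation: str  # "associated" or a granular label
    evidence: list[Evidence] = field(default_factory=list)
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("assertion requires at least one evidence item")

    @property
    def occurrence_count(self) -> int:
        return len({(e.doc_id, e.kind, e.sent_index, e.table_index, e.unit) for e in self.evidence})

    def merge(self, other: "RelationAssertion") -> None:
        seen = {(e.doc_id, e.kind, e.sent_index, e.table_index, e.unit) for e in self.evidence}
        for e in other.evidence:
            k = (e.doc_id, e.kind, e.sent_index, e.table_index, e.unit)
            if k not in seen:
                self.evidence.append(e)
                seen.add(k)
        if other.confidence is not None:
            self.confidence = max(self.confidence or 0.0, other.confidence)
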