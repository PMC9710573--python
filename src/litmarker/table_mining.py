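"""Rule-based relation extraction from article tables.

Tables carry many disease-biomarker relations that never appear in prose.
Two co-occurrence patterns are mined from each table tuple
(caption, head, body rows):

* caption pattern — the caption names a disease together with a collective
  noun of the biomarker class ("bacteria", "microbiome"); every specific
  biomarker listed in the body is then asserted as related to that disease.
* row pattern — a disease and a specific biomarker co-occur within one row
  (or the caption itself); each such in-unit pair is asserted directly.

Mention detection inside captions and cells reuses the dictionary matcher
and rule filters of :mod:`litmarker.entity_extraction`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .entity_extraction import filter_mentions, match_entities, split_and_tokenize
from .lexicon import EntityType, MatchAutomaton, TermList, build_automaton
from .relations import EntityRef, Evidence, RelationAssertion

logger = logging.getLogger(__name__)

__all__ = [
    "TableRecord",
    "CollectiveTermList",
    "DEFAULT_MICROBIOME_COLLECTIVES",
    "parse_tables",
    "parse_jats_tables",
    "caption_pattern",
    "row_pattern",
    "mine_tables",
]

_WS = re.compile(r"\s+")


def _clean(cell: object) -> str:
    return _WS.sub(" ", str(cell)).strip()


@dataclass(frozen=True)
class TableRecord:
    """One table as a (caption, head, body) tuple; rows may be ragged."""

    doc_id: str
    caption: str
    head: tuple[str, ...]
    body: tuple[tuple[str, ...], ...]
    table_index: int = 0


@dataclass(frozen=True)
class CollectiveTermList:
    """Generic class nouns ("bacteria", "microbiome") signalling a biomarker listing."""

    entity_type: EntityType
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("collective term list must be non-empty")
        object.__setattr__(self, "terms", tuple(t.casefold() for t in self.terms))

    def present_in(self, tokens: Sequence[str]) -> bool:
        lowered = {t.casefold() for t in tokens}
        return any(t in lowered for t in self.terms)


DEFAULT_MICROBIOME_COLLECTIVES = CollectiveTermList(
    entity_type=EntityType.MICROBIOME,
    terms=(
        "microbiome",
        "microbiota",
        "microbe",
        "microbes",
        "bacteria",
        "bacterium",
        "microorganism",
        "microorganisms",
        "flora",
    ),
)


def parse_tables(document: dict) -> list[TableRecord]:
    """Read the ``tables`` field of a JSONL document record.

    Each entry must be ``{caption, head: [...], body: [[...]]}``; cell text
    is whitespace-normalized, malformed entries are skipped with a warning.
    """
    doc_id = str(document.get("doc_id", ""))
    out: list[TableRecord] = []
    for idx, tab in enumerate(document.get("tables", []) or []):
        try:
            caption = _clean(tab.get("caption", ""))
            head = tuple(_clean(c) for c in tab.get("head", []) or [])
            body = tuple(
                tuple(_clean(c) for c in row) for row in tab.get("body", []) or []
            )
        except (AttributeError, TypeError):
            logger.warning("doc %s: malformed table #%d skipped", doc_id, idx)
            continue
        out.append(TableRecord(doc_id=doc_id, caption=caption, head=head, body=body, table_index=idx))
    return out


def parse_jats_tables(source: str | Path, doc_id: str = "") -> list[TableRecord]:
    """Read ``<table-wrap>`` elements from JATS-like XML; nested markup is flattened."""
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text(encoding="utf-8")
    root = etree.fromstring(text.encode("utf-8"))
    records: list[TableRecord] = []
    for idx, wrap in enumerate(root.iter("table-wrap")):
        cap_el = wrap.find(".//caption")
        caption = _clean(" ".join(cap_el.itertext())) if cap_el is not None else ""
        head: tuple[str, ...] = ()
        body: list[tuple[str, ...]] = []
        for table in wrap.iter("table"):
            thead = table.find("thead")
            if thead is not None:
                cells = thead.findall(".//th") + thead.findall(".//td")
                head = tuple(_clean(" ".join(c.itertext())) for c in cells)
            tbody = table.find("tbody")
            rows = (tbody if tbody is not None else table).findall(".//tr")
            for tr in rows:
                cells = tr.findall("td") + tr.findall("th")
                if cells:
                    body.append(tuple(_clean(" ".join(c.itertext())) for c in cells))
        records.append(
            TableRecord(doc_id=doc_id, caption=caption, head=head, body=tuple(body), table_index=idx)
        )
    return records


def _as_automaton(lex: TermList | MatchAutomaton) -> MatchAutomaton:
    return lex if isinstance(lex, MatchAutomaton) else build_automaton(lex)


def _unit_mentions(text: str, automaton: MatchAutomaton):
    """Distinct (term_id, entity_type) mentions in one table unit's text."""
    found = []
    for sent in split_and_tokenize(text):
        raw = match_entities(sent, automaton)
        found.extend(filter_mentions(raw, sent, context=None))
    return found


def caption_pattern(
    table: TableRecord,
    anchor: TermList | MatchAutomaton,
    target: TermList | MatchAutomaton,
    collectives: CollectiveTermList = DEFAULT_MICROBIOME_COLLECTIVES,
) -> list[RelationAssertion]:
    """Caption names anchor + collective noun => every body target is related.

    Empty output whenever the caption lacks either an anchor mention or a
    collective term.
    """
    anchor_auto = _as_automaton(anchor)
    target_auto = _as_automaton(target)
    cap_tokens = [
        t.text for s in split_and_tokenize(table.caption) for t in s.tokens
    ]
    if not collectives.present_in(cap_tokens):
        return []
    anchors = {
        (m.term_id, m.entity_type) for m in _unit_mentions(table.caption, anchor_auto)
    }
    if not anchors:
        return []
    targets: dict[tuple[str, EntityType], str] = {}
    for r, row in enumerate(table.body):
        for cell in row:
            for m in _unit_mentions(cell, target_auto):
                targets.setdefault((m.term_id, m.entity_type), f"row:{r}")
    out = []
    for (a_id, a_type) in sorted(anchors):
        for (t_id, t_type), unit in sorted(targets.items()):
            out.append(
                RelationAssertion(
                    entity1=EntityRef(a_id, a_type),
                    entity2=EntityRef(t_id, t_type),
                    relation="associated",
                    evidence=[
                        Evidence(
                            doc_id=table.doc_id,
                            kind="table",
                            table_index=table.table_index,
                            unit=unit,
                            text=table.caption,
                            pattern="caption_pattern",
                        )
                    ],
                )
            )
    return out


def row_pattern(
    table: TableRecord,
    anchor: TermList | MatchAutomaton,
    target: TermList | MatchAutomaton,
    include_head: bool = True,
) -> list[RelationAssertion]:
    """Anchor and specific target co-occur in a row (or caption) => related.

    The caption and (optionally) the head row each count as one unit;
    duplicate pairs across units are merged, so the same pair seen in three
    rows yields one assertion with three evidence items.
    """
    anchor_auto = _as_automaton(anchor)
    target_auto = _as_automaton(target)
    units: list[tuple[str, str]] = [("caption", table.caption)]
    if include_head and table.head:
        units.append(("head", " | ".join(table.head)))
    units.extend((f"row:{r}", " | ".join(row)) for r, row in enumerate(table.body))
    merged: dict[tuple, RelationAssertion] = {}
    for unit_name, unit_text in units:
        if not unit_text.strip():
            continue
        anchors = {(m.term_id, m.entity_type) for m in _unit_mentions(unit_text, anchor_auto)}
        targets = {(m.term_id, m.entity_type) for m in _unit_mentions(unit_text, target_auto)}
        for a in sorted(anchors):
            for t in sorted(targets):
                if a == t:
                    continue
                ev = Evidence(
                    doc_id=table.doc_id,
                    kind="table",
                    table_index=table.table_index,
                    unit=unit_name,
                    text=unit_text,
                    pattern="row_pattern",
                )
                key = (a, t)
                if key in merged:
                    merged[key].merge(
                        RelationAssertion(
                            entity1=EntityRef(*a), entity2=EntityRef(*t),
                            relation="associated", evidence=[ev],
                        )
                    )
                else:
                    merged[key] = RelationAssertion(
                        entity1=EntityRef(*a), entity2=EntityRef(*t),
                        relation="associated", evidence=[ev],
                    )
    return [merged[k] for k in sorted(merged)]


def mine_tables(
    tables: Iterable[TableRecord],
    anchor: TermList | MatchAutomaton,
    target: TermList | MatchAutomaton,
    collectives: CollectiveTermList = DEFAULT_MICROBIOME_COLLECTIVES,
    include_head: bool = True,
) -> list[RelationAssertion]:
    """Run both patterns over tables and merge assertions per entity pair."""
    anchor_auto = _as_automaton(anchor)
    target_auto = _as_automaton(target)
    merged: dict[tuple, RelationAssertion] = {}
    for table in tables:
        for assertion in caption_pattern(table, anchor_auto, target_auto, collectives) + row_pattern(
            table, anchor_auto, target_auto, include_head=include_head
        ):
            key = (
                (assertion.entity1.term_id, assertion.entity1.entity_type),
                (assertion.entity2.term_id, assertion.entity2.entity_type),
            )
            if key in merged:
                merged[key].merge(assertion)
            else:
                merged[key] = assertion
    return [merged[k] for k in sorted(merged)]
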