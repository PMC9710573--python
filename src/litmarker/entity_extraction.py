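"""Sentence splitting, tokenization, dictionary matching and mention filters.

The extraction contract: split a document into sentences, tokenize with
character offsets, run left-to-right greedy longest-match recognition
against the compiled :class:`~litmarker.lexicon.MatchAutomaton`, then apply
two rule filters that clean common dictionary false positives:

1. dot-prefix rule — a surface like ``s. pneumonia`` (single letter + dot)
   is discarded;
2. short-term rule — surfaces shorter than 4 characters are discarded
   unless the same document previously defined them via the pattern
   ``long form (ABBR)``.

Both thresholds follow the pipeline's published filtering rules; the
abbreviation whitelist is scoped per document with definition-before-use
semantics (the defining occurrence itself is kept).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import TOKEN_RE, EntityType, MatchAutomaton

__all__ = [
    "Token",
    "Sentence",
    "EntityMention",
    "CandidatePair",
    "DocumentContext",
    "split_sentences",
    "split_and_tokenize",
    "match_entities",
    "filter_mentions",
    "candidate_pairs",
    "extract_document",
]


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # char offset into sentence text, half-open [start, end)
    end: int


@dataclass(frozen=True)
class Sentence:
    doc_id: str
    sent_index: int
    text: str
    tokens: tuple[Token, ...]

    def token_texts(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass(frozen=True)
class EntityMention:
    """A located, typed occurrence of a dictionary term in one sentence."""

    term_id: str
    entity_type: EntityType
    doc_id: str
    sent_index: int
    token_start: int  # token span [token_start, token_end)
    token_end: int
    char_start: int  # char offsets into sentence text
    char_end: int
    surface: str


@dataclass(frozen=True)
class CandidatePair:
    """Two distinct, non-overlapping mentions of the requested types in one sentence."""

    sentence: Sentence
    mention1: EntityMention
    mention2: EntityMention

    def key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """Unordered pair key: sorted ((type, term_id), (type, term_id))."""
        a = (self.mention1.entity_type.value, self.mention1.term_id)
        b = (self.mention2.entity_type.value, self.mention2.term_id)
        return (a, b) if a <= b else (b, a)


# split after ./!/? when followed by whitespace and an upper-case/digit/opening char;
# a lower-case continuation ("s. pneumonia") never splits
_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"'\[])")


def split_sentences(text: str) -> list[tuple[int, str]]:
    """Return (char offset, sentence text) pairs; offsets index into ``text``."""
    out: list[tuple[int, str]] = []
    pos = 0
    for m in _SENT_BOUNDARY.finditer(text):
        chunk = text[pos : m.start()]
        if chunk.strip():
            out.append((pos, chunk))
        pos = m.end()
    tail = text[pos:]
    if tail.strip():
        out.append((pos, tail))
    return out


def split_and_tokenize(text: str, doc_id: str = "") -> list[Sentence]:
    """Split a document into tokenized sentences.

    Empty or whitespace-only input yields an empty list. Token offsets are
    half-open character spans into each sentence's text; every alphanumeric
    run lands in exactly one token.
    """
    sentences: list[Sentence] = []
    for idx, (_, sent_text) in enumerate(split_sentences(text)):
        tokens = tuple(
            Token(m.group(), m.start(), m.end()) for m in TOKEN_RE.finditer(sent_text)
        )
        sentences.append(Sentence(doc_id=doc_id, sent_index=idx, text=sent_text, tokens=tokens))
    return sentences


def match_entities(sentence: Sentence, automaton: MatchAutomaton) -> list[EntityMention]:
    """Greedy left-to-right longest-match recognition.

    At each token position the longest automaton match starting there is
    emitted (one mention per payload when distinct terms tie on the same
    longest span) and scanning resumes after it, so emitted spans never
    overlap.
    """
    toks = sentence.token_texts()
    mentions: list[EntityMention] = []
    i = 0
    n = len(toks)
    while i < n:
        hit = automaton.longest_match(toks, i)
        if hit is None:
            i += 1
            continue
        end, payloads = hit
        c0 = sentence.tokens[i].start
        c1 = sentence.tokens[end - 1].end
        surface = sentence.text[c0:c1]
        for p in payloads:
            mentions.append(
                EntityMention(
                    term_id=p.term_id,
                    entity_type=p.entity_type,
                    doc_id=sentence.doc_id,
                    sent_index=sentence.sent_index,
                    token_start=i,
                    token_end=end,
                    char_start=c0,
                    char_end=c1,
                    surface=surface,
                )
            )
        i = end
    return mentions


_DOT_PREFIX = re.compile(r"^[A-Za-z]\.\s")


@dataclass
class DocumentContext:
    """Per-document abbreviation whitelist with definition positions.

    A definition event is a mention immediately followed by the token
    sequence ``( X )``; ``X`` becomes a whitelisted short form from its
    definition position onward.
    """

    definitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def observe(self, sentence: Sentence, mentions: Sequence[EntityMention]) -> None:
        toks = sentence.token_texts()
        ends = {m.token_end for m in mentions}
        for end in ends:
            if (
                end + 2 < len(toks)
                and toks[end] == "("
                and toks[end + 2] == ")"
                and toks[end + 1].isalnum()
            ):
                short = toks[end + 1]
                pos = (sentence.sent_index, end + 1)
                if short not in self.definitions or pos < self.definitions[short]:
                    self.definitions[short] = pos

    def defined_before(self, surface: str, sent_index: int, token_start: int) -> bool:
        pos = self.definitions.get(surface)
        return pos is not None and pos <= (sent_index, token_start)


def filter_mentions(
    mentions: Iterable[EntityMention],
    sentence: Sentence,
    context: DocumentContext | None = None,
    min_chars: int = 4,
) -> list[EntityMention]:
    """Apply the dot-prefix and short-term rules; never adds mentions."""
    kept: list[EntityMention] = []
    for m in mentions:
        if _DOT_PREFIX.match(m.surface):
            continue
        if len(m.surface) < min_chars:
            if context is None or not context.defined_before(
                m.surface, m.sent_index, m.token_start
            ):
                continue
        kept.append(m)
    return kept


def candidate_pairs(
    mentions: Sequence[EntityMention],
    sentence: Sentence,
    type_pair: tuple[EntityType, EntityType],
) -> list[CandidatePair]:
    """All unordered cross-type pairs of non-overlapping mentions, ordered by span start."""
    ta, tb = type_pair
    left = [m for m in mentions if m.entity_type == ta]
    right = [m for m in mentions if m.entity_type == tb]
    pairs: list[CandidatePair] = []
    for a in left:
        for b in right:
            if a is b:
                continue
            if a.token_end <= b.token_start or b.token_end <= a.token_start:
                m1, m2 = (a, b) if a.token_start <= b.token_start else (b, a)
                pairs.append(CandidatePair(sentence=sentence, mention1=m1, mention2=m2))
    pairs.sort(key=lambda p: (p.mention1.token_start, p.mention2.token_start))
    return pairs


def extract_document(
    doc_id: str,
    text: str,
    automaton: MatchAutomaton,
    min_chars: int = 4,
) -> list[tuple[Sentence, list[EntityMention]]]:
    """Full per-document flow: split, match, harvest abbreviations, filter.

    Sentences are processed in order so an abbreviation definition in an
    earlier sentence licenses short-form mentions in later ones.
    """
    ctx = DocumentContext()
    out: list[tuple[Sentence, list[EntityMention]]] = []
    for sent in split_and_tokenize(text, doc_id=doc_id):
        raw = match_entities(sent, automaton)
        ctx.observe(sent, raw)
        out.append((sent, filter_mentions(raw, sent, ctx, min_chars=min_chars)))
    return out
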