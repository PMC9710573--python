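"""Entity vocabularies and the longest-match automaton.

Term lists are the dictionaries the whole pipeline matches against: one
:class:`Term` per biomedical entity (disease, microbial taxon, gene,
metabolite, ...), each carrying a canonical name plus synonyms. All synonyms
of all loaded lists are compiled into a single token-level trie
(:class:`MatchAutomaton`) supporting left-to-right maximal-munch matching in
time linear in sentence length.

Matching policy
---------------
Synonyms are normalized (NFC, whitespace collapse, flanking punctuation
strip) and matched case-insensitively, except short all-uppercase synonyms
(gene-symbol style, e.g. ``EMT``), which require an exact-case surface match
to limit symbol/abbreviation collisions. Both behaviors are configurable via
:class:`MatchPolicy`.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "EntityType",
    "Term",
    "TermList",
    "MatchPolicy",
    "MatchAutomaton",
    "normalize_term",
    "load_term_list",
    "build_automaton",
]


class EntityType(str, Enum):
    """Entity classes the pipeline recognizes."""

    DISEASE = "disease"
    MICROBIOME = "microbiome"
    GENE = "gene"
    METABOLITE = "metabolite"
    DRUG = "drug"
    PROTEIN = "protein"
    OTHER = "other"


_WS_RE = re.compile(r"\s+")
# flanking punctuation only; internal dots/hyphens are meaningful (e.g. "s. pneumonia")
_FLANK_RE = re.compile(r"^[\s\.,;:!\?\"'`\(\)\[\]\{\}]+|[\s\.,;:!\?\"'`\(\)\[\]\{\}]+$")

# one token per alphanumeric run; every punctuation character is its own token
TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def normalize_term(s: str, case_fold: bool = True, collapse_ws: bool = True) -> str:
    """Normalize a synonym or query string (idempotent)."""
    s = unicodedata.normalize("NFC", s)
    s = _FLANK_RE.sub("", s)
    if collapse_ws:
        s = _WS_RE.sub(" ", s)
    if case_fold:
        s = s.casefold()
    return s


def tokenize_term(s: str) -> list[str]:
    """Tokenize a synonym exactly as sentences are tokenized."""
    return TOKEN_RE.findall(s)


@dataclass(frozen=True)
class Term:
    """One entity with its synonym set (canonical name included)."""

    term_id: str
    entity_type: EntityType
    canonical: str
    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValueError(f"term {self.term_id!r}: empty canonical name")
        if not self.synonyms:
            raise ValueError(f"term {self.term_id!r}: no synonyms")


@dataclass
class TermList:
    """A typed vocabulary; the unit the matcher is compiled from."""

    entity_type: EntityType
    terms: list[Term] = field(default_factory=list)
    case_fold: bool = True
    collapse_ws: bool = True

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.terms:
            if t.term_id in seen:
                raise ValueError(f"duplicate term_id {t.term_id!r}")
            seen.add(t.term_id)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms)

    def get(self, term_id: str) -> Term | None:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        return None

    def all_synonyms(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out.update(t.synonyms)
        return out


def load_term_list(
    path: str | Path,
    entity_type: EntityType | str,
    strict: bool = False,
) -> TermList:
    """Load a TSV term list: columns term_id, entity_type, canonical, synonyms.

    Synonyms are pipe-separated; the canonical name is always included and
    duplicates (after normalization) are stored once. Lines starting with
    ``#`` are comments. Malformed rows are skipped with a warning, or raise
    in ``strict`` mode. An empty file (or one yielding no terms) is an error.
    """
    entity_type = EntityType(entity_type)
    path = Path(path)
    terms: list[Term] = []
    n_skipped = 0
    with path.open(encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[:4] != ["term_id", "entity_type", "canonical", "synonyms"]:
                    raise ValueError(
                        f"{path}: expected header term_id/entity_type/canonical/synonyms"
                    )
                continue
            fields = line.split("\t")
            if len(fields) < 4 or not fields[0] or not fields[2]:
                msg = f"{path}:{lineno}: malformed row ({line[:60]!r})"
                if strict:
                    raise ValueError(msg)
                logger.warning("%s -- skipped", msg)
                n_skipped += 1
                continue
            term_id, row_type, canonical, syn_field = fields[:4]
            raw_syns = [canonical] + [s for s in syn_field.split("|") if s.strip()]
            seen_norm: set[str] = set()
            syns: list[str] = []
            for s in raw_syns:
                key = normalize_term(s)
                if key and key not in seen_norm:
                    seen_norm.add(key)
                    syns.append(_WS_RE.sub(" ", unicodedata.normalize("NFC", s)).strip())
            terms.append(
                Term(
                    term_id=term_id,
                    entity_type=EntityType(row_type) if row_type else entity_type,
                    canonical=canonical,
                    synonyms=tuple(syns),
                )
            )
    if not terms:
        raise ValueError(f"{path}: no terms loaded")
    logger.info("%s: loaded %d terms (%d rows skipped)", path, len(terms), n_skipped)
    return TermList(entity_type=entity_type, terms=terms)


@dataclass(frozen=True)
class MatchPolicy:
    """Case policy for matching.

    ``uppercase_exact_max_len``: synonyms that are all-uppercase and at most
    this many characters (gene-symbol style) must match the surface text
    exactly; 0 disables the exception. ``case_fold`` turns global
    case-insensitivity on/off.
    """

    case_fold: bool = True
    uppercase_exact_max_len: int = 6

    def requires_exact_case(self, synonym: str) -> bool:
        return (
            self.case_fold
            and 0 < len(synonym) <= self.uppercase_exact_max_len
            and synonym == synonym.upper()
            and any(c.isalpha() for c in synonym)
        )


@dataclass(frozen=True)
class _Payload:
    term_id: str
    entity_type: EntityType
    exact_surface: str | None  # non-None => surface must equal this exactly


class _Node:
    __slots__ = ("children", "payloads")

    def __init__(self) -> None:
        self.children: dict[str, _Node] = {}
        self.payloads: list[_Payload] = []


class MatchAutomaton:
    """Token-sequence trie over normalized synonyms with leaf payloads.

    Keys are lowercase token sequences; leaf payloads carry
    (term_id, entity_type) plus an optional exact-case surface constraint.
    """

    def __init__(self, policy: MatchPolicy | None = None) -> None:
        self.policy = policy or MatchPolicy()
        self._root = _Node()
        self.max_depth = 0
        self._n_synonyms = 0

    def insert(self, synonym: str, term_id: str, entity_type: EntityType) -> None:
        norm = normalize_term(synonym, case_fold=False)
        tokens = tokenize_term(norm)
        if not tokens:
            return
        exact = norm if self.policy.requires_exact_case(norm) else None
        node = self._root
        for tok in tokens:
            key = tok.casefold() if self.policy.case_fold else tok
            node = node.children.setdefault(key, _Node())
        payload = _Payload(term_id, entity_type, exact)
        if payload not in node.payloads:
            node.payloads.append(payload)
        self.max_depth = max(self.max_depth, len(tokens))
        self._n_synonyms += 1

    def __len__(self) -> int:
        return self._n_synonyms

    def _key(self, token: str) -> str:
        return token.casefold() if self.policy.case_fold else token

    def contains(self, phrase: str) -> bool:
        """Membership of a synonym phrase (ignoring case constraints)."""
        node = self._root
        for tok in tokenize_term(normalize_term(phrase, case_fold=False)):
            node = node.children.get(self._key(tok))  # type: ignore[assignment]
            if node is None:
                return False
        return bool(node.payloads)

    def longest_match(
        self, tokens: Sequence[str], start: int
    ) -> tuple[int, list[_Payload]] | None:
        """Longest match beginning at ``tokens[start]``.

        Returns (end index exclusive, valid payloads) of the deepest node
        whose payloads survive the exact-case check against the surface, or
        None. Visits at most ``max_depth`` nodes.
        """
        node = self._root
        best: tuple[int, list[_Payload]] | None = None
        i = start
        limit = min(len(tokens), start + self.max_depth)
        while i < limit:
            node = node.children.get(self._key(tokens[i]))  # type: ignore[assignment]
            if node is None:
                break
            i += 1
            if node.payloads:
                surface = " ".join(tokens[start:i])
                valid = [
                    p
                    for p in node.payloads
                    if p.exact_surface is None or _surface_eq(tokens[start:i], p.exact_surface)
                ]
                if valid:
                    best = (i, valid)
        return best


def _surface_eq(tokens: Sequence[str], exact: str) -> bool:
    return tokenize_term(exact) == list(tokens)


def build_automaton(
    lists: TermList | Iterable[TermList],
    policy: MatchPolicy | None = None,
) -> MatchAutomaton:
    """Compile one or more term lists into a single longest-match automaton."""
    if isinstance(lists, TermList):
        lists = [lists]
    auto = MatchAutomaton(policy=policy)
    for tl in lists:
        for term in tl:
            for syn in term.synonyms:
                auto.insert(syn, term.term_id, term.entity_type)
    if len(auto) == 0:
        raise ValueError("no synonyms to compile: empty term list union")
    return auto
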