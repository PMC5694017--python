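"""Sentence segmentation, dictionary mention recognition and connective rules.

The relation-mining model works on flat token sequences.  Within each
sentence, gene symbols, GO accessions and GO term names are recognised by
maximal case-insensitive dictionary matching, and every within-sentence
mention pair is classified as semantically *related*, *unrelated* or
*unmarked* from the connective tokens strictly between the two mentions:

* a contrasting conjunction between the mentions (``but``, ``whereas`` ...)
  marks the pair unrelated — contrast always wins, even when a linking
  phrase is also present ("geneA binds with geneB but not with geneC"
  relates A to B and not A to C);
* otherwise a similarity conjunction (``and``, ``or`` ...) or a linking
  phrase (``binds to``, ``interacts with`` ...) marks the pair related;
* otherwise the pair is unmarked: it still counts as a sentence-level
  co-occurrence but not as a semantic one.

The connective sets ship as a JSON data file and can be replaced by the
caller; the defaults are frozen so runs are reproducible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

from girem.corpus_io import AbstractDoc, GeneLexicon, GoAnnotationTable, ValidationError

__all__ = [
    "Sentence",
    "Mention",
    "RuleLexicon",
    "Verdict",
    "split_sentences",
    "tokenize",
    "find_mentions",
    "EntityMatcher",
    "classify_pair_semantics",
]

# Word tokens only; GO accessions keep their colon.  Punctuation is not
# tokenized — connective and dictionary matching operate on word sequences.
_TOKEN_RE = re.compile(r"GO:\d{7}|[A-Za-z0-9][A-Za-z0-9'\-]*")

# Common abbreviations that must not terminate a sentence.
_ABBREV = {
    "e.g", "i.e", "al", "etc", "vs", "cf", "ca", "approx", "resp",
    "fig", "figs", "ref", "refs", "no", "dr", "st",
}

_TERMINATOR_RE = re.compile(r"[.!?]+")


class Verdict(str, Enum):
    """Semantic verdict for a within-sentence mention pair."""

    RELATED = "related"
    UNRELATED = "unrelated"
    UNMARKED = "unmarked"


@dataclass(frozen=True)
class Sentence:
    """A sentence of an abstract with token-aligned character spans."""

    doc_id: str
    sent_index: int
    text: str
    token_spans: tuple[tuple[int, int], ...]

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.text[s:e] for s, e in self.token_spans)


@dataclass(frozen=True)
class Mention:
    """A recognised entity occurrence inside one sentence."""

    entity_kind: str  # "gene" | "go_term"
    entity_id: str
    span: tuple[int, int]  # character offsets within the sentence, half-open
    matched_text: str


@dataclass(frozen=True)
class RuleLexicon:
    """Connective phrase sets driving the semantic verdict rules."""

    contrasting_conjunctions: frozenset[str]
    similarity_conjunctions: frozenset[str]
    linking_phrases: frozenset[str]
    negation_markers: frozenset[str]

    def __post_init__(self) -> None:
        positive = self.similarity_conjunctions | self.linking_phrases
        overlap = self.contrasting_conjunctions & positive
        if overlap:
            raise ValidationError(
                f"phrases cannot be both contrasting and similarity/linking: {sorted(overlap)}"
            )

    @staticmethod
    def _norm(phrases) -> frozenset[str]:
        return frozenset(" ".join(p.lower().split()) for p in phrases)

    @classmethod
    def from_dict(cls, obj: dict) -> "RuleLexicon":
        return cls(
            contrasting_conjunctions=cls._norm(obj["contrasting_conjunctions"]),
            similarity_conjunctions=cls._norm(obj["similarity_conjunctions"]),
            linking_phrases=cls._norm(obj["linking_phrases"]),
            negation_markers=cls._norm(obj["negation_markers"]),
        )

    @classmethod
    def load(cls, path: str | Path | None = None) -> "RuleLexicon":
        """Load a rule lexicon from JSON; with no path, the shipped default."""
        if path is None:
            text = resources.files("girem.data").joinpath("rules.json").read_text("utf-8")
        else:
            text = Path(path).read_text("utf-8")
        return cls.from_dict(json.loads(text))


def tokenize(text: str) -> tuple[tuple[int, int], ...]:
    """Character spans of the word tokens of ``text`` (punctuation dropped)."""
    return tuple(m.span() for m in _TOKEN_RE.finditer(text))


def _sentence_boundaries(text: str) -> Iterator[tuple[int, int]]:
    start = 0
    for m in _TERMINATOR_RE.finditer(text):
        end = m.end()
        rest = text[end:]
        # A boundary must be followed by whitespace then an upper-case letter,
        # digit or opening bracket/quote — or end the text.
        if rest.strip() and not re.match(r"\s+[\"'(\[]?[A-Z0-9]", rest):
            continue
        prev = text[: m.start()].rsplit(None, 1)
        word = prev[-1] if prev else ""
        word = word.strip("([{\"'”’)]}").rstrip(".")
        wl = word.lower()
        # Skip abbreviation-internal periods ("e.g.", "et al.", "i.e.").
        if wl in _ABBREV or "." in wl:
            continue
        if text[start:end].strip():
            yield (start, end)
        start = end
    if text[start:].strip():
        yield (start, len(text))


def split_sentences(doc: AbstractDoc) -> list[Sentence]:
    """Rule-based sentence segmentation (terminal punctuation + abbreviation list).

    The concatenation of sentence texts plus separators covers the abstract;
    degenerate text yields a single sentence.
    """
    sentences: list[Sentence] = []
    for start, end in _sentence_boundaries(doc.text):
        chunk = doc.text[start:end]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        s_text = chunk[lead : len(chunk) - trail] if trail else chunk[lead:]
        sentences.append(
            Sentence(
                doc_id=doc.doc_id,
                sent_index=len(sentences),
                text=s_text,
                token_spans=tokenize(s_text),
            )
        )
    return sentences


def _stem(token: str) -> str:
    """Light plural stripper used for GO term names only."""
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 4 and token.endswith("sses"):
        return token[:-2]
    if (
        len(token) > 3
        and token.endswith("s")
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    return token


class EntityMatcher:
    """Pre-compiled dictionary matcher for gene symbols, GO ids and GO names.

    Gene symbols are matched verbatim (case-insensitively): stemming symbols
    would create false hits on common words.  GO term names are matched
    case-insensitively with plural stripping on both sides.  At each token
    position the longest match wins; matches never overlap.
    """

    def __init__(self, lexicon: GeneLexicon, go_table: GoAnnotationTable) -> None:
        # (priority, kind, entity_id) keyed by token tuple; priority breaks
        # equal-length ties deterministically: gene > GO id > GO name.
        self._exact: dict[tuple[str, ...], tuple[int, str, str]] = {}
        self._stemmed: dict[tuple[str, ...], tuple[int, str, str]] = {}
        for gene_id in sorted(lexicon.entries):
            key = tuple(
                lexicon.entries[gene_id][s:e].casefold()
                for s, e in tokenize(lexicon.entries[gene_id])
            )
            if key:
                self._exact.setdefault(key, (0, "gene", gene_id))
        seen_terms: dict[str, tuple[str, str]] = {}
        for gene_id in sorted(go_table.records):
            for go_id, go_name in sorted(go_table.records[gene_id]):
                seen_terms.setdefault(go_id, (go_id, go_name))
        for go_id, (ident, name) in sorted(seen_terms.items()):
            self._exact.setdefault((ident.casefold(),), (1, "go_term", go_id))
            name_key = tuple(
                _stem(name[s:e].casefold()) for s, e in tokenize(name)
            )
            if name_key:
                self._stemmed.setdefault(name_key, (2, "go_term", go_id))
        lengths = {len(k) for k in self._exact} | {len(k) for k in self._stemmed}
        self._max_len = max(lengths, default=0)

    def find(self, sentence: Sentence) -> list[Mention]:
        spans = sentence.token_spans
        raw = [sentence.text[s:e].casefold() for s, e in spans]
        stemmed = [_stem(t) for t in raw]
        mentions: list[Mention] = []
        i = 0
        while i < len(spans):
            best: tuple[int, int, str, str] | None = None  # (length, prio, kind, id)
            for length in range(min(self._max_len, len(spans) - i), 0, -1):
                if best is not None:
                    break
                candidates = []
                hit = self._exact.get(tuple(raw[i : i + length]))
                if hit is not None:
                    candidates.append(hit)
                hit = self._stemmed.get(tuple(stemmed[i : i + length]))
                if hit is not None:
                    candidates.append(hit)
                if candidates:
                    prio, kind, ident = min(candidates)
                    best = (length, prio, kind, ident)
            if best is None:
                i += 1
                continue
            length, _prio, kind, ident = best
            start, end = spans[i][0], spans[i + length - 1][1]
            mentions.append(
                Mention(
                    entity_kind=kind,
                    entity_id=ident,
                    span=(start, end),
                    matched_text=sentence.text[start:end],
                )
            )
            i += length
        return mentions


def find_mentions(
    sentence: Sentence, lexicon: GeneLexicon, go_table: GoAnnotationTable
) -> list[Mention]:
    """Dictionary scan of one sentence; see :class:`EntityMatcher`.

    For corpus-scale work build one ``EntityMatcher`` and reuse it — this
    convenience wrapper recompiles the dictionaries on every call.
    """
    return EntityMatcher(lexicon, go_table).find(sentence)


def _phrase_present(tokens: Sequence[str], phrase: str) -> bool:
    ptoks = phrase.split()
    n = len(ptoks)
    if n == 0 or n > len(tokens):
        return False
    return any(list(tokens[i : i + n]) == ptoks for i in range(len(tokens) - n + 1))


def classify_pair_semantics(
    sentence: Sentence, a: Mention, b: Mention, rules: RuleLexicon
) -> Verdict:
    """Apply the connective rules to the tokens strictly between two mentions.

    Precondition: ``a`` starts before ``b`` and the spans do not overlap.
    The verdict is a function of the inter-mention text only.
    """
    if a.span[0] >= b.span[0]:
        raise ValueError("mention a must start before mention b")
    if a.span[1] > b.span[0]:
        raise ValueError(f"overlapping mention spans: {a.span} and {b.span}")
    between = [
        sentence.text[s:e].casefold()
        for s, e in sentence.token_spans
        if s >= a.span[1] and e <= b.span[0]
    ]
    if any(_phrase_present(between, p) for p in rules.contrasting_conjunctions):
        return Verdict.UNRELATED
    positive = rules.similarity_conjunctions | rules.linking_phrases
    if any(_phrase_present(between, p) for p in positive):
        return Verdict.RELATED
    return Verdict.UNMARKED
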