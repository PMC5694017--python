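"""Readers and writers for the pipeline's file formats.

All downstream stages consume the validated containers defined here:

* abstract corpus — JSON-lines, one object per abstract with ``"id"`` and
  ``"text"`` fields;
* gene lexicon — TSV with header ``gene_id<TAB>symbol`` mapping a stable
  gene identifier to its primary symbol;
* GO annotation table — TSV ``gene_id<TAB>go_id<TAB>go_name``, one row per
  gene–term association;
* benchmark edge list — TSV ``gene_a<TAB>gene_b<TAB>score`` of
  experimentally supported interactions.

Gene pairs are always stored in a canonical order (lexicographically
smaller ``gene_id`` first) so that features, labels and predictions are
well defined and runs are byte-reproducible.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CorpusError",
    "CorpusFormatError",
    "SchemaError",
    "ValidationError",
    "AbstractDoc",
    "GeneLexicon",
    "GoAnnotationTable",
    "BenchmarkEdges",
    "canonical_pair",
    "read_corpus",
    "write_corpus",
    "read_lexicon",
    "write_lexicon",
    "read_go_table",
    "write_go_table",
    "read_edges",
    "write_edges",
    "read_feature_table",
    "write_feature_table",
    "write_edge_predictions",
    "read_edge_predictions",
]

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


class CorpusError(ValueError):
    """Base class for input-validation failures."""


class CorpusFormatError(CorpusError):
    """A line or record could not be parsed."""


class SchemaError(CorpusError):
    """A table is missing required columns."""


class ValidationError(CorpusError):
    """Parsed content violates an invariant (duplicate ids, collisions...)."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical order.

    The lexicographically smaller gene_id is always first.  Self-pairs are
    rejected: a gene cannot interact with itself in this model.
    """
    if a == b:
        raise ValidationError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class AbstractDoc:
    """One abstract: an opaque document id (e.g. a PMID) and its free text."""

    doc_id: str
    text: str


@dataclass(frozen=True)
class GeneLexicon:
    """Mapping gene_id -> primary symbol, with an injective reverse lookup."""

    entries: dict[str, str]
    symbol_to_gene: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        reverse: dict[str, str] = {}
        for gene_id, symbol in self.entries.items():
            if not symbol or not symbol.strip():
                raise ValidationError(f"empty symbol for gene {gene_id!r}")
            key = symbol.casefold()
            if key in reverse and reverse[key] != gene_id:
                raise ValidationError(
                    f"case-folded symbol collision: {symbol!r} maps to both "
                    f"{reverse[key]!r} and {gene_id!r}"
                )
            reverse[key] = gene_id
        object.__setattr__(self, "symbol_to_gene", reverse)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.entries)


@dataclass(frozen=True)
class GoAnnotationTable:
    """Mapping gene_id -> set of (go_id, go_name) annotations."""

    records: dict[str, frozenset[tuple[str, str]]]

    def __post_init__(self) -> None:
        for gene_id, terms in self.records.items():
            for go_id, _name in terms:
                if not _GO_ID_RE.match(go_id):
                    raise ValidationError(
                        f"malformed GO accession {go_id!r} for gene {gene_id!r}"
                    )

    def terms_of(self, gene_id: str) -> frozenset[tuple[str, str]]:
        return self.records.get(gene_id, frozenset())

    def genes_of_term(self) -> dict[str, tuple[str, ...]]:
        """Invert the table: go_id -> sorted tuple of annotated genes."""
        inv: dict[str, set[str]] = {}
        for gene_id, terms in self.records.items():
            for go_id, _name in terms:
                inv.setdefault(go_id, set()).add(gene_id)
        return {k: tuple(sorted(v)) for k, v in inv.items()}


@dataclass(frozen=True)
class BenchmarkEdges:
    """Set of experimentally supported gene-gene edges, canonically ordered."""

    edges: frozenset[tuple[str, str]]
    scores: dict[tuple[str, str], int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-edge not allowed: {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise ValidationError(f"edge not in canonical order: ({a!r}, {b!r})")

    def neighbors(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return {g: frozenset(ns) for g, ns in adj.items()}


# ---------------------------------------------------------------------------
# corpus I/O


def _normalize_text(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def read_corpus(path: str | Path) -> list[AbstractDoc]:
    """Read a JSON-lines abstract corpus.

    Each line is an object with string fields ``"id"`` and ``"text"``.
    Raises :class:`CorpusFormatError` naming the offending line on parse
    failure and :class:`ValidationError` on duplicate ids or empty text.
    """
    docs: list[AbstractDoc] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            if not isinstance(obj, dict) or "id" not in obj or "text" not in obj:
                raise CorpusFormatError(f'line {lineno}: expected fields "id" and "text"')
            doc_id, text = str(obj["id"]), _normalize_text(str(obj["text"]))
            if doc_id in seen:
                raise ValidationError(f"line {lineno}: duplicate abstract id {doc_id!r}")
            if not text.strip():
                raise ValidationError(f"line {lineno}: empty abstract text for {doc_id!r}")
            seen.add(doc_id)
            docs.append(AbstractDoc(doc_id=doc_id, text=text))
    return docs


def write_corpus(docs: Iterable[AbstractDoc], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps({"id": doc.doc_id, "text": doc.text}, sort_keys=True))
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV helpers


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file, expected header {required}")
        header = header_line.rstrip("\n").split("\t")
        missing = [col for col in required if col not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}; header was {header}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            values = line.rstrip("\n").split("\t")
            if len(values) != len(header):
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(values)}"
                )
            rows.append(dict(zip(header, values)))
    return rows


def read_lexicon(path: str | Path) -> GeneLexicon:
    rows = _read_tsv(path, ("gene_id", "symbol"))
    entries: dict[str, str] = {}
    for row in rows:
        gene_id = row["gene_id"]
        if gene_id in entries:
            raise ValidationError(f"duplicate gene_id {gene_id!r} in lexicon")
        entries[gene_id] = _normalize_text(row["symbol"])
    return GeneLexicon(entries=entries)


def write_lexicon(lexicon: GeneLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tsymbol\n")
        for gene_id in sorted(lexicon.entries):
            fh.write(f"{gene_id}\t{lexicon.entries[gene_id]}\n")


def read_go_table(path: str | Path, lexicon: GeneLexicon | None = None) -> GoAnnotationTable:
    """Read the GO annotation TSV.

    If a lexicon is supplied, every annotated gene must be present in it.
    """
    rows = _read_tsv(path, ("gene_id", "go_id", "go_name"))
    records: dict[str, set[tuple[str, str]]] = {}
    for row in rows:
        gene_id = row["gene_id"]
        if lexicon is not None and gene_id not in lexicon.entries:
            raise ValidationError(f"GO table annotates unknown gene {gene_id!r}")
        records.setdefault(gene_id, set()).add((row["go_id"], _normalize_text(row["go_name"])))
    return GoAnnotationTable(records={g: frozenset(t) for g, t in records.items()})


def write_go_table(table: GoAnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tgo_id\tgo_name\n")
        for gene_id in sorted(table.records):
            for go_id, go_name in sorted(table.records[gene_id]):
                fh.write(f"{gene_id}\t{go_id}\t{go_name}\n")


def read_edges(path: str | Path) -> BenchmarkEdges:
    rows = _read_tsv(path, ("gene_a", "gene_b", "score"))
    edges: set[tuple[str, str]] = set()
    scores: dict[tuple[str, str], int] = {}
    for row in rows:
        pair = canonical_pair(row["gene_a"], row["gene_b"])
        edges.add(pair)
        if row["score"] != "":
            score = int(row["score"])
            if not 0 <= score <= 1000:
                raise ValidationError(f"edge score out of range [0, 1000]: {score}")
            scores[pair] = score
    return BenchmarkEdges(edges=frozenset(edges), scores=scores)


def write_edges(edges: BenchmarkEdges, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b in sorted(edges.edges):
            score = edges.scores.get((a, b))
            fh.write(f"{a}\t{b}\t{'' if score is None else score}\n")


# ---------------------------------------------------------------------------
# feature table and predictions

_LABEL_TO_STR = {1: "1", 0: "0", None: "NA"}
_STR_TO_LABEL = {"1": 1, "0": 0, "NA": None}


def write_feature_table(rows, path: str | Path) -> None:
    """Write labeled feature rows as TSV (gene_a, gene_b, w1..w9, label).

    ``rows`` is a sequence of :class:`girem.labeling.LabeledPair` (or any
    object with ``features`` and ``label`` attributes).  Rows are written in
    canonical pair order; floats use shortest round-trip representation so
    reading the file back reproduces the in-memory values exactly.
    """
    header = ["gene_a", "gene_b"] + [f"w{i}" for i in range(1, 10)] + ["label"]
    ordered = sorted(rows, key=lambda r: (r.features.gene_a, r.features.gene_b))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in ordered:
            pf = row.features
            ws = "\t".join(repr(float(v)) for v in pf.w)
            fh.write(f"{pf.gene_a}\t{pf.gene_b}\t{ws}\t{_LABEL_TO_STR[row.label]}\n")


def read_feature_table(path: str | Path):
    """Read a feature-table TSV back into LabeledPair rows."""
    from girem.features import PairFeatures
    from girem.labeling import LabeledPair

    cols = ["gene_a", "gene_b"] + [f"w{i}" for i in range(1, 10)] + ["label"]
    rows = _read_tsv(path, cols)
    out = []
    for row in rows:
        pair = canonical_pair(row["gene_a"], row["gene_b"])
        w = tuple(float(row[f"w{i}"]) for i in range(1, 10))
        if row["label"] not in _STR_TO_LABEL:
            raise ValidationError(f"bad label {row['label']!r}; expected 0, 1 or NA")
        out.append(
            LabeledPair(
                features=PairFeatures(gene_a=pair[0], gene_b=pair[1], w=w),
                label=_STR_TO_LABEL[row["label"]],
            )
        )
    return out


def write_edge_predictions(
    predictions: Iterable[tuple[tuple[str, str], float, int]], path: str | Path
) -> None:
    """Write (pair, probability, predicted_class) rows in canonical order."""
    rows = []
    for pair, prob, cls in predictions:
        if not 0.0 <= prob <= 1.0:
            raise ValidationError(f"probability out of [0, 1]: {prob!r} for {pair}")
        rows.append((canonical_pair(*pair), float(prob), int(cls)))
    rows.sort(key=lambda r: r[0])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tprobability\tpredicted_class\n")
        for (a, b), prob, cls in rows:
            fh.write(f"{a}\t{b}\t{prob!r}\t{cls}\n")


def read_edge_predictions(path: str | Path) -> list[tuple[tuple[str, str], float, int]]:
    rows = _read_tsv(path, ("gene_a", "gene_b", "probability", "predicted_class"))
    return [
        (
            canonical_pair(row["gene_a"], row["gene_b"]),
            float(row["probability"]),
            int(row["predicted_class"]),
        )
        for row in rows
    ]
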