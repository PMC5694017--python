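"""Three-level co-occurrence tallies and the nine-dimensional pair features.

Every candidate gene pair (g_x, g_y) is represented by nine ratio weights,
three per text level alpha in {A (abstract), S (sentence), SE (semantic)}:

    W_N = sum_i co(g_x, g_y)_i / (sum_i so(g_x)_i + sum_i so(g_y)_i)

* W1–W3 — direct gene–gene co-occurrence at A / S / SE;
* W4–W6 — co-occurrence of the first gene with the GO-term group of the
  second gene, GOs(g_y), at A / S / SE;
* W7–W9 — the mirror image: second gene with GOs(g_x).

Per-unit statuses are binary: a gene (or GO group) either is or is not
mentioned in a given abstract or sentence, regardless of multiplicity.  A
mention of one GO term counts as a group occurrence for *every* gene
annotated with that term.  The semantic level restricts sentence-level
co-occurrences to those whose connective pattern marks the two mentions as
related; because a lone mention has no partner to be related to, SE-level
weights reuse the sentence-level solo counts in their denominators, which
makes W3 <= W2 and keeps every weight inside [0, 0.5].

Candidate pairs are the pairs with at least one abstract-level
co-occurrence, i.e. the pairs actually found together in the literature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from girem.corpus_io import (
    AbstractDoc,
    GeneLexicon,
    GoAnnotationTable,
    canonical_pair,
)
from girem.extraction import EntityMatcher, RuleLexicon, Verdict, classify_pair_semantics, split_sentences

__all__ = [
    "LEVELS",
    "FIRST_WITH_GOS_OF_SECOND",
    "SECOND_WITH_GOS_OF_FIRST",
    "TalliedCorpus",
    "PairFeatures",
    "tally",
    "pair_weight",
    "gene_go_weight",
    "build_feature_matrix",
]

LEVELS = ("A", "S", "SE")

FIRST_WITH_GOS_OF_SECOND = "first_gene_with_GOs_of_second"
SECOND_WITH_GOS_OF_FIRST = "second_gene_with_GOs_of_first"

# SE-level solo counts are not defined by the counting model (a solo mention
# has no partner); denominators at SE reuse the sentence-level solos.
_SOLO_LEVEL = {"A": "A", "S": "S", "SE": "S"}


@dataclass
class TalliedCorpus:
    """Accumulated solo/co-occurrence counts at the three text levels."""

    genes: frozenset[str]
    solo_gene: dict[str, Counter] = field(default_factory=dict)
    solo_go: dict[str, Counter] = field(default_factory=dict)
    co_gene: dict[str, Counter] = field(default_factory=dict)
    co_gene_go: dict[str, Counter] = field(default_factory=dict)
    unit_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for level in LEVELS:
            self.solo_gene.setdefault(level, Counter())
            self.solo_go.setdefault(level, Counter())
            self.co_gene.setdefault(level, Counter())
            self.co_gene_go.setdefault(level, Counter())
            self.unit_counts.setdefault(level, 0)

    def _check(self, *gene_ids: str) -> None:
        for g in gene_ids:
            if g not in self.genes:
                raise KeyError(f"unknown gene {g!r}")

    def solo_gene_count(self, g: str, level: str) -> int:
        self._check(g)
        return self.solo_gene[_SOLO_LEVEL[level]][g]

    def solo_go_count(self, g: str, level: str) -> int:
        self._check(g)
        return self.solo_go[_SOLO_LEVEL[level]][g]

    def co_count(self, gx: str, gy: str, level: str) -> int:
        self._check(gx, gy)
        return self.co_gene[level][canonical_pair(gx, gy)]

    def co_gene_go_count(self, g: str, other: str, level: str) -> int:
        """Co-occurrences of gene ``g`` with the GO group of gene ``other``."""
        self._check(g, other)
        return self.co_gene_go[level][(g, other)]


@dataclass(frozen=True)
class PairFeatures:
    """One candidate pair with its nine weights (a row of the matrix X)."""

    gene_a: str
    gene_b: str
    w: tuple[float, ...]  # (W1, ..., W9)

    def __post_init__(self) -> None:
        if len(self.w) != 9:
            raise ValueError(f"expected 9 weights, got {len(self.w)}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


def _sentence_units(
    doc: AbstractDoc,
    matcher: EntityMatcher,
    go_to_genes: dict[str, tuple[str, ...]],
    rules: RuleLexicon,
):
    """Yield per-sentence binary statuses for one abstract.

    For each sentence: the genes mentioned, the genes whose GO group is
    mentioned, and the semantically related gene–gene / gene–GO-group pairs.
    Mentions are deduplicated per entity (first occurrence kept) before
    verdicts are taken, matching the binary per-unit counting.
    """
    for sentence in split_sentences(doc):
        mentions = matcher.find(sentence)
        gene_mentions: dict[str, object] = {}
        go_mentions: dict[str, object] = {}
        for m in mentions:
            if m.entity_kind == "gene":
                gene_mentions.setdefault(m.entity_id, m)
            else:
                go_mentions.setdefault(m.entity_id, m)
        genes_present = set(gene_mentions)
        go_groups_present = {
            g
            for go_id in go_mentions
            for g in go_to_genes.get(go_id, ())
        }
        se_gene_pairs: set[tuple[str, str]] = set()
        se_gene_go: set[tuple[str, str]] = set()
        any_related = False
        gene_list = sorted(gene_mentions)
        for i, gx in enumerate(gene_list):
            for gy in gene_list[i + 1 :]:
                m1, m2 = gene_mentions[gx], gene_mentions[gy]
                if m1.span[0] > m2.span[0]:
                    m1, m2 = m2, m1
                if classify_pair_semantics(sentence, m1, m2, rules) is Verdict.RELATED:
                    se_gene_pairs.add(canonical_pair(gx, gy))
                    any_related = True
        for gx in gene_list:
            gm = gene_mentions[gx]
            for go_id in sorted(go_mentions):
                om = go_mentions[go_id]
                first, second = (gm, om) if gm.span[0] <= om.span[0] else (om, gm)
                if first.span[1] > second.span[0]:
                    continue  # nested/overlapping spans carry no connective
                if classify_pair_semantics(sentence, first, second, rules) is Verdict.RELATED:
                    any_related = True
                    for gy in go_to_genes.get(go_id, ()):
                        if gy != gx:
                            se_gene_go.add((gx, gy))
        yield genes_present, go_groups_present, se_gene_pairs, se_gene_go, any_related


def tally(
    corpus: Sequence[AbstractDoc],
    lexicon: GeneLexicon,
    go_table: GoAnnotationTable,
    rules: RuleLexicon | None = None,
) -> TalliedCorpus:
    """Accumulate binary solo/co-occurrence statuses over the whole corpus."""
    if rules is None:
        rules = RuleLexicon.load()
    matcher = EntityMatcher(lexicon, go_table)
    go_to_genes = go_table.genes_of_term()
    t = TalliedCorpus(genes=lexicon.gene_ids)

    for doc in corpus:
        a_genes: set[str] = set()
        a_go_groups: set[str] = set()
        for genes, go_groups, se_pairs, se_gene_go, any_related in _sentence_units(
            doc, matcher, go_to_genes, rules
        ):
            t.unit_counts["S"] += 1
            if any_related:
                t.unit_counts["SE"] += 1
            for g in genes:
                t.solo_gene["S"][g] += 1
            for g in go_groups:
                t.solo_go["S"][g] += 1
            genes_sorted = sorted(genes)
            for i, gx in enumerate(genes_sorted):
                for gy in genes_sorted[i + 1 :]:
                    t.co_gene["S"][canonical_pair(gx, gy)] += 1
            for gx in genes_sorted:
                for gy in sorted(go_groups):
                    if gy != gx:
                        t.co_gene_go["S"][(gx, gy)] += 1
            for pair in se_pairs:
                t.co_gene["SE"][pair] += 1
            for key in se_gene_go:
                t.co_gene_go["SE"][key] += 1
            a_genes |= genes
            a_go_groups |= go_groups

        t.unit_counts["A"] += 1
        for g in a_genes:
            t.solo_gene["A"][g] += 1
        for g in a_go_groups:
            t.solo_go["A"][g] += 1
        genes_sorted = sorted(a_genes)
        for i, gx in enumerate(genes_sorted):
            for gy in genes_sorted[i + 1 :]:
                t.co_gene["A"][canonical_pair(gx, gy)] += 1
        for gx in genes_sorted:
            for gy in sorted(a_go_groups):
                if gy != gx:
                    t.co_gene_go["A"][(gx, gy)] += 1
    return t


def _ratio(co: int, so_sum: int) -> float:
    # Zero denominator means no evidence at all for either member.
    return co / so_sum if so_sum > 0 else 0.0


def pair_weight(t: TalliedCorpus, gx: str, gy: str, level: str) -> float:
    """Direct gene–gene weight (W1, W2 or W3 depending on ``level``)."""
    if gx == gy:
        raise ValueError("pair members must be distinct")
    co = t.co_count(gx, gy, level)
    denom = t.solo_gene_count(gx, level) + t.solo_gene_count(gy, level)
    return _ratio(co, denom)


def gene_go_weight(t: TalliedCorpus, gx: str, gy: str, level: str, direction: str) -> float:
    """Gene-to-GO-group weight (W4–W6 or W7–W9 depending on ``direction``)."""
    if gx == gy:
        raise ValueError("pair members must be distinct")
    if direction == FIRST_WITH_GOS_OF_SECOND:
        g, other = gx, gy
    elif direction == SECOND_WITH_GOS_OF_FIRST:
        g, other = gy, gx
    else:
        raise ValueError(f"unknown direction {direction!r}")
    co = t.co_gene_go_count(g, other, level)
    denom = t.solo_gene_count(g, level) + t.solo_go_count(other, level)
    return _ratio(co, denom)


def build_feature_matrix(t: TalliedCorpus, go_table: GoAnnotationTable) -> list[PairFeatures]:
    """One feature row per candidate pair, in canonical pair order."""
    rows: list[PairFeatures] = []
    for gx, gy in sorted(p for p, c in t.co_gene["A"].items() if c > 0):
        w = tuple(
            [pair_weight(t, gx, gy, level) for level in LEVELS]
            + [gene_go_weight(t, gx, gy, level, FIRST_WITH_GOS_OF_SECOND) for level in LEVELS]
            + [gene_go_weight(t, gx, gy, level, SECOND_WITH_GOS_OF_FIRST) for level in LEVELS]
        )
        rows.append(PairFeatures(gene_a=gx, gene_b=gy, w=w))
    return rows


def feature_matrix_array(rows: Iterable[PairFeatures]) -> np.ndarray:
    """Stack feature rows into the (n_pairs, 9) design matrix X."""
    return np.asarray([r.w for r in rows], dtype=float).reshape(-1, 9)
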