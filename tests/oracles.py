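"""Independent brute-force oracles used by the test suite.

These deliberately recount everything the slow way — iterating entities and
pairs over every abstract and sentence — so they share no accumulation
logic with the production tally, and recompute metrics from first
principles (pairwise comparisons for AUC, term-by-term sums for the
likelihood).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from girem.corpus_io import canonical_pair
from girem.extraction import EntityMatcher, Verdict, classify_pair_semantics, split_sentences


def _unit_statuses(corpus, lexicon, go_table, rules):
    """Per-sentence and per-abstract entity statuses, recomputed from scratch.

    Returns (sentence_units, abstract_units) where a sentence unit is
    (genes_mentioned, go_groups_mentioned, related_gene_pairs,
    related_gene_go_pairs) and an abstract unit is (genes, go_groups).
    """
    matcher = EntityMatcher(lexicon, go_table)
    go_to_genes = go_table.genes_of_term()
    sentence_units = []
    abstract_units = []
    for doc in corpus:
        doc_genes: set[str] = set()
        doc_go_groups: set[str] = set()
        for sent in split_sentences(doc):
            mentions = matcher.find(sent)
            first_gene: dict[str, object] = {}
            first_go: dict[str, object] = {}
            for m in mentions:
                target = first_gene if m.entity_kind == "gene" else first_go
                target.setdefault(m.entity_id, m)
            genes = set(first_gene)
            go_groups = {
                g for go_id in first_go for g in go_to_genes.get(go_id, ())
            }
            related_pairs = set()
            any_related = False
            for gx, gy in combinations(sorted(genes), 2):
                m1, m2 = sorted(
                    (first_gene[gx], first_gene[gy]), key=lambda m: m.span[0]
                )
                if classify_pair_semantics(sent, m1, m2, rules) is Verdict.RELATED:
                    related_pairs.add(canonical_pair(gx, gy))
                    any_related = True
            related_gene_go = set()
            for gx in sorted(genes):
                for go_id in sorted(first_go):
                    m1, m2 = sorted(
                        (first_gene[gx], first_go[go_id]), key=lambda m: m.span[0]
                    )
                    if m1.span[1] > m2.span[0]:
                        continue
                    if classify_pair_semantics(sent, m1, m2, rules) is Verdict.RELATED:
                        any_related = True
                        for gy in go_to_genes.get(go_id, ()):
                            if gy != gx:
                                related_gene_go.add((gx, gy))
            sentence_units.append(
                (genes, go_groups, related_pairs, related_gene_go, any_related)
            )
            doc_genes |= genes
            doc_go_groups |= go_groups
        abstract_units.append((doc_genes, doc_go_groups))
    return sentence_units, abstract_units


def bruteforce_tallies(corpus, lexicon, go_table, rules):
    """Recount every solo/co statistic by iterating pairs x units."""
    sentence_units, abstract_units = _unit_statuses(corpus, lexicon, go_table, rules)
    genes = sorted(lexicon.entries)
    out = {
        "unit_counts": {
            "A": len(abstract_units),
            "S": len(sentence_units),
            "SE": sum(1 for unit in sentence_units if unit[4]),
        },
        "solo_gene": {"A": {}, "S": {}},
        "solo_go": {"A": {}, "S": {}},
        "co_gene": {"A": {}, "S": {}, "SE": {}},
        "co_gene_go": {"A": {}, "S": {}, "SE": {}},
    }
    for g in genes:
        out["solo_gene"]["A"][g] = sum(1 for gs, _ in abstract_units if g in gs)
        out["solo_gene"]["S"][g] = sum(1 for gs, *_ in sentence_units if g in gs)
        out["solo_go"]["A"][g] = sum(1 for _, gos in abstract_units if g in gos)
        out["solo_go"]["S"][g] = sum(
            1 for _gs, gos, *_ in sentence_units if g in gos
        )
    for gx, gy in combinations(genes, 2):
        pair = canonical_pair(gx, gy)
        out["co_gene"]["A"][pair] = sum(
            1 for gs, _ in abstract_units if gx in gs and gy in gs
        )
        out["co_gene"]["S"][pair] = sum(
            1 for gs, *_ in sentence_units if gx in gs and gy in gs
        )
        out["co_gene"]["SE"][pair] = sum(
            1 for unit in sentence_units if pair in unit[2]
        )
    for gx in genes:
        for gy in genes:
            if gx == gy:
                continue
            key = (gx, gy)
            out["co_gene_go"]["A"][key] = sum(
                1 for gs, gos in abstract_units if gx in gs and gy in gos
            )
            out["co_gene_go"]["S"][key] = sum(
                1 for gs, gos, *_ in sentence_units if gx in gs and gy in gos
            )
            out["co_gene_go"]["SE"][key] = sum(
                1 for unit in sentence_units if key in unit[3]
            )
    return out


def bruteforce_weights(tallies: dict, gx: str, gy: str) -> tuple[float, ...]:
    """The nine ratio weights recomputed by direct arithmetic."""

    def ratio(co, so_sum):
        return co / so_sum if so_sum > 0 else 0.0

    pair = canonical_pair(gx, gy)
    gx, gy = pair
    w = []
    for level in ("A", "S", "SE"):
        solo_level = "S" if level == "SE" else level
        w.append(
            ratio(
                tallies["co_gene"][level][pair],
                tallies["solo_gene"][solo_level][gx]
                + tallies["solo_gene"][solo_level][gy],
            )
        )
    for g, other in ((gx, gy), (gy, gx)):
        for level in ("A", "S", "SE"):
            solo_level = "S" if level == "SE" else level
            w.append(
                ratio(
                    tallies["co_gene_go"][level][(g, other)],
                    tallies["solo_gene"][solo_level][g]
                    + tallies["solo_go"][solo_level][other],
                )
            )
    return tuple(w)


def pairwise_auc(probs, truth) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2."""
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos = probs[truth == 1]
    neg = probs[truth == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (pos.size * neg.size))


def sum_of_terms_loglik(beta, X, y, w, lam, penalize_intercept=False) -> float:
    """Scalar-loop weighted penalized log-likelihood (no vectorization)."""
    total = 0.0
    for i in range(len(y)):
        eta = sum(X[i][j] * beta[j] for j in range(len(beta)))
        total += w[i] * (y[i] * eta - math.log(1.0 + math.exp(eta)))
    penalty = 0.0
    for j, b in enumerate(beta):
        if j == 0 and not penalize_intercept:
            continue
        penalty += b * b
    return total - 0.5 * lam * penalty
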