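"""Synthetic corpus generator with a planted gene-interaction network.

The generator emulates the statistical structure the pipeline assumes: a
hidden interaction network over a small gene set, and abstracts whose
sentences co-mention gene pairs — interacting pairs more often than
non-interacting ones, and joined by different connectives.  Each abstract
draws a handful of genes; every pair among them co-occurs in a sentence
with probability ``related_cooccur_rate`` (if it is a planted edge) or
``unrelated_cooccur_rate`` (if not).  Co-mention sentences for edges use
similarity/linking connectives ("and", "interacts with", ...); co-mention
sentences for non-edges use a contrasting conjunction with probability
``contrast_rate_for_unrelated`` and otherwise the same positive templates,
so setting equal co-occurrence rates and a zero contrast rate produces a
corpus carrying no signal at all.  Genes not co-mentioned in an abstract
get solo sentences, and co-mention sentences occasionally carry a
follow-up sentence joining the first gene to a GO term of its partner,
which feeds the gene-to-GO-group features.

Everything is drawn from a single seeded generator in a fixed order, so a
configuration maps to byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from girem.corpus_io import (
    AbstractDoc,
    BenchmarkEdges,
    GeneLexicon,
    GoAnnotationTable,
    canonical_pair,
    write_corpus,
    write_edges,
    write_go_table,
    write_lexicon,
)

__all__ = ["SynthConfig", "SynthData", "generate", "write_inputs"]

# Connectives must match the shipped rule lexicon so extraction fires on them.
_POSITIVE_CONNECTIVES = (
    "and",
    "or",
    "interacts with",
    "binds to",
    "binds with",
    "associates with",
    "associated with",
)
_CONTRAST_TEMPLATES = (
    "{a} is induced whereas {b} is suppressed in tumor cells.",
    "{a} but not {b} was detected in these samples.",
    "{a} increased although {b} decreased upon treatment.",
)
_SOLO_TEMPLATES = (
    "{a} was profiled in patient samples.",
    "Expression of {a} was measured across tissues.",
    "{a} showed variable abundance in the cohort.",
)
# Share of co-mention sentences that get a follow-up gene-to-GO sentence.
_GO_FOLLOWUP_RATE = 0.3


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generated corpus.

    Defaults are the strong-signal regime used throughout the test suite:
    30 genes, 500 abstracts, interacting pairs co-mentioned in 60% of their
    shared abstracts versus 5% for non-interacting pairs, and 90% of
    non-edge co-mentions phrased contrastively.
    """

    n_genes: int = 30
    n_go_terms: int = 20
    go_terms_per_gene: int = 2
    n_abstracts: int = 500
    sentences_per_abstract: int = 5
    true_network_density: float = 0.12
    related_cooccur_rate: float = 0.6
    unrelated_cooccur_rate: float = 0.05
    contrast_rate_for_unrelated: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if not 0.0 <= self.true_network_density <= 1.0:
            raise ValueError("true_network_density must lie in [0, 1]")
        for name in (
            "related_cooccur_rate",
            "unrelated_cooccur_rate",
            "contrast_rate_for_unrelated",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.related_cooccur_rate < self.unrelated_cooccur_rate:
            raise ValueError(
                "related_cooccur_rate must be >= unrelated_cooccur_rate "
                "(the planted signal cannot be negative)"
            )
        if not 1 <= self.go_terms_per_gene <= max(self.n_go_terms, 1):
            raise ValueError("go_terms_per_gene must lie in [1, n_go_terms]")


@dataclass(frozen=True)
class SynthData:
    """Generated inputs plus the planted ground-truth network."""

    corpus: tuple[AbstractDoc, ...]
    lexicon: GeneLexicon
    go_table: GoAnnotationTable
    benchmark: BenchmarkEdges
    truth_edges: frozenset[tuple[str, str]]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(1, n + 1)]


def _positive_sentence(a: str, b: str, rng: np.random.Generator) -> str:
    conn = _POSITIVE_CONNECTIVES[rng.integers(len(_POSITIVE_CONNECTIVES))]
    return f"{a} {conn} {b} were detected in tumor cells."


def _contrast_sentence(a: str, b: str, rng: np.random.Generator) -> str:
    template = _CONTRAST_TEMPLATES[rng.integers(len(_CONTRAST_TEMPLATES))]
    return template.format(a=a, b=b)


def generate(cfg: SynthConfig) -> SynthData:
    """Generate corpus, lexicon, GO table and benchmark from the config."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg.n_genes)
    lexicon = GeneLexicon(entries={g: f"GENE{g[1:]}" for g in gene_ids})

    go_ids = [f"GO:{1000000 + k:07d}" for k in range(1, cfg.n_go_terms + 1)]
    go_names = {go_id: f"process{k + 1:03d} pathway" for k, go_id in enumerate(go_ids)}
    records: dict[str, frozenset[tuple[str, str]]] = {}
    for g in gene_ids:
        chosen = rng.choice(cfg.n_go_terms, size=cfg.go_terms_per_gene, replace=False)
        records[g] = frozenset((go_ids[k], go_names[go_ids[k]]) for k in sorted(chosen))
    go_table = GoAnnotationTable(records=records)

    truth: set[tuple[str, str]] = set()
    for i, gx in enumerate(gene_ids):
        for gy in gene_ids[i + 1 :]:
            if rng.random() < cfg.true_network_density:
                truth.add(canonical_pair(gx, gy))
    if not truth and cfg.true_network_density > 0:
        raise ValueError(
            "planted network came out empty; raise true_network_density or n_genes"
        )

    genes_per_abstract = max(2, min(cfg.n_genes, cfg.sentences_per_abstract))
    symbols = lexicon.entries
    go_names_of: dict[str, tuple[str, ...]] = {
        g: tuple(sorted(name for _gid, name in records[g])) for g in gene_ids
    }

    docs: list[AbstractDoc] = []
    for doc_no in range(1, cfg.n_abstracts + 1):
        subset_idx = rng.choice(cfg.n_genes, size=genes_per_abstract, replace=False)
        subset = [gene_ids[i] for i in sorted(subset_idx)]
        sentences: list[str] = []
        comentioned: set[str] = set()
        for i, gx in enumerate(subset):
            for gy in subset[i + 1 :]:
                is_edge = canonical_pair(gx, gy) in truth
                p_co = cfg.related_cooccur_rate if is_edge else cfg.unrelated_cooccur_rate
                if rng.random() >= p_co:
                    continue
                contrastive = (not is_edge) and rng.random() < cfg.contrast_rate_for_unrelated
                a, b = symbols[gx], symbols[gy]
                if contrastive:
                    sentences.append(_contrast_sentence(a, b, rng))
                else:
                    sentences.append(_positive_sentence(a, b, rng))
                comentioned.update((gx, gy))
                if rng.random() < _GO_FOLLOWUP_RATE and go_names_of[gy]:
                    go_name = go_names_of[gy][rng.integers(len(go_names_of[gy]))]
                    if contrastive:
                        sentences.append(_contrast_sentence(a, go_name, rng))
                    else:
                        sentences.append(_positive_sentence(a, go_name, rng))
        for g in subset:
            if g not in comentioned:
                template = _SOLO_TEMPLATES[rng.integers(len(_SOLO_TEMPLATES))]
                sentences.append(template.format(a=symbols[g]))
        docs.append(AbstractDoc(doc_id=f"PMID{doc_no:07d}", text=" ".join(sentences)))

    benchmark = BenchmarkEdges(
        edges=frozenset(truth), scores={pair: 900 for pair in sorted(truth)}
    )
    return SynthData(
        corpus=tuple(docs),
        lexicon=lexicon,
        go_table=go_table,
        benchmark=benchmark,
        truth_edges=frozenset(truth),
    )


def write_inputs(data: SynthData, outdir: str | Path) -> dict[str, Path]:
    """Write the four pipeline input files (plus the truth network)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.jsonl",
        "lexicon": outdir / "lexicon.tsv",
        "go_table": outdir / "go_annotations.tsv",
        "edges": outdir / "benchmark_edges.tsv",
        "truth": outdir / "truth_edges.tsv",
    }
    write_corpus(data.corpus, paths["corpus"])
    write_lexicon(data.lexicon, paths["lexicon"])
    write_go_table(data.go_table, paths["go_table"])
    write_edges(data.benchmark, paths["edges"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(data.truth_edges):
            fh.write(f"{a}\t{b}\n")
    return paths
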