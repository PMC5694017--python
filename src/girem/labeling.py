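"""Training-class assignment from a benchmark interaction network.

A candidate pair is labeled positive (1) when it is an edge of the
benchmark network.  Declaring non-relation is harder than declaring
relation, so the negative class (0) is restricted to pairs that are not an
edge *and* whose two genes share no benchmark neighbor — the pairs with the
least circumstantial evidence of interaction.  Everything else stays
unlabeled and is scored only at prediction time.

A gene absent from the benchmark vertex set has an empty neighbor set, so
its pairs vacuously satisfy the no-common-neighbor condition and are
labeled 0.  Note this treats "never observed interacting" as negative
evidence, not as "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from girem.corpus_io import BenchmarkEdges
from girem.features import PairFeatures

__all__ = ["LabeledPair", "assign_labels", "label_counts"]


@dataclass(frozen=True)
class LabeledPair:
    """A feature row with its class: 1, 0 or None (unlabeled)."""

    features: PairFeatures
    label: int | None

    def __post_init__(self) -> None:
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


def assign_labels(rows: Sequence[PairFeatures], bench: BenchmarkEdges) -> list[LabeledPair]:
    """Label every feature row from the benchmark network.

    Every row receives exactly one of {1, 0, unlabeled}; row order is
    preserved.
    """
    if not bench.edges:
        raise ValueError("benchmark edge set is empty")
    adjacency = bench.neighbors()
    empty: frozenset[str] = frozenset()
    labeled: list[LabeledPair] = []
    for row in rows:
        pair = row.pair
        if pair in bench.edges:
            label: int | None = 1
        elif not (adjacency.get(pair[0], empty) & adjacency.get(pair[1], empty)):
            label = 0
        else:
            label = None
        labeled.append(LabeledPair(features=row, label=label))
    return labeled


def label_counts(rows: Sequence[LabeledPair]) -> dict[str, int]:
    """Class sizes: positives, negatives and unlabeled rows."""
    counts = {"positive": 0, "negative": 0, "unlabeled": 0}
    for row in rows:
        if row.label == 1:
            counts["positive"] += 1
        elif row.label == 0:
            counts["negative"] += 1
        else:
            counts["unlabeled"] += 1
    return counts
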