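"""Bootstrap lambda tuning, classification metrics, ROC/AUC and the network.

The ridge strength is selected by repeated balanced resampling: for each
candidate lambda, ``rounds`` balanced training samples are drawn with
replacement from the labeled pairs, a model is fitted on each, and both
per-class accuracies are measured on the out-of-bag labeled rows.  The
chosen lambda maximizes the *minimum* of the two mean class accuracies
(the most conservative reading of "high accuracy for both classes"); ties
break toward the smaller lambda.  The same resampling sequence is replayed
for every lambda so the comparison is paired and fully deterministic given
the seed.

Metrics follow the usual confusion-matrix identities (recall, precision,
F-value as their harmonic mean, true-negative rate) and the ROC is swept
across every distinct predicted probability, with AUC by the trapezoidal
rule — numerically identical to the Mann-Whitney statistic with ties
counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from girem.labeling import LabeledPair
from girem.wlr import WlrConfig, WlrModel, fit, predict

__all__ = [
    "BootstrapReport",
    "EvalReport",
    "RelationGraph",
    "bootstrap_tune",
    "crossfit_predict",
    "evaluate",
    "roc_curve",
    "build_network",
]


@dataclass(frozen=True)
class BootstrapReport:
    """Per-round and mean class accuracies for one lambda."""

    lam: float
    rounds: int
    per_round: tuple[tuple[float, float], ...]  # (accuracy_class0, accuracy_class1)
    mean_accuracy_class0: float
    mean_accuracy_class1: float


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and the scalar metrics derived from them."""

    tp: int
    fp: int
    fn: int
    tn: int
    recall: float
    precision: float
    f_value: float
    tnr: float
    accuracy_class0: float
    accuracy_class1: float
    auc: float | None
    roc_points: tuple[tuple[float, float], ...]  # (FPR, TPR)


@dataclass(frozen=True)
class RelationGraph:
    """Predicted relation network: all pairs classified as related."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]  # (gene_a, gene_b, probability)


def _labeled_arrays(labeled: Sequence[LabeledPair]) -> tuple[np.ndarray, np.ndarray]:
    rows = [lp for lp in labeled if lp.label is not None]
    X = np.asarray([lp.features.w for lp in rows], dtype=float).reshape(-1, 9)
    y = np.asarray([lp.label for lp in rows], dtype=float)
    return X, y


def bootstrap_tune(
    labeled: Sequence[LabeledPair],
    lambda_grid: Sequence[float],
    rounds: int,
    train_size: int,
    seed: int,
    base_cfg: WlrConfig | None = None,
) -> tuple[float, dict[float, BootstrapReport]]:
    """Select the ridge strength by balanced bootstrap resampling.

    ``train_size`` is the total balanced sample size (half per class).
    Returns the winning lambda and a report per grid value.
    """
    if len(lambda_grid) == 0:
        raise ValueError("lambda grid is empty")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    X, y = _labeled_arrays(labeled)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    half = max(1, train_size // 2)
    for name, idx in (("positive", pos_idx), ("negative", neg_idx)):
        if idx.size == 0:
            raise ValueError(f"no labeled rows in the {name} class")
    pop_rate = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
    base_cfg = base_cfg or WlrConfig()

    reports: dict[float, BootstrapReport] = {}
    for lam in lambda_grid:
        # fresh generator per lambda: every grid value sees the same draws
        rng = np.random.default_rng(seed)
        per_round: list[tuple[float, float]] = []
        for _ in range(rounds):
            take_pos = rng.choice(pos_idx, size=half, replace=True)
            take_neg = rng.choice(neg_idx, size=half, replace=True)
            train = np.concatenate([take_pos, take_neg])
            cfg = replace(
                base_cfg,
                lam=float(lam),
                pop_event_rate=pop_rate,
                sample_event_rate=0.5,
            )
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                model = fit(X[train], y[train], cfg)
            oob = np.setdiff1d(np.arange(y.size), train)
            if oob.size == 0:
                oob = np.arange(y.size)
            _, classes = predict(model, X[oob])
            acc0 = _class_accuracy(classes, y[oob], 0)
            acc1 = _class_accuracy(classes, y[oob], 1)
            per_round.append((acc0, acc1))
        arr = np.asarray(per_round, dtype=float)
        reports[float(lam)] = BootstrapReport(
            lam=float(lam),
            rounds=rounds,
            per_round=tuple((float(a), float(b)) for a, b in per_round),
            mean_accuracy_class0=float(np.nanmean(arr[:, 0])),
            mean_accuracy_class1=float(np.nanmean(arr[:, 1])),
        )

    def score(lam: float) -> tuple[float, float]:
        r = reports[lam]
        return (min(r.mean_accuracy_class0, r.mean_accuracy_class1), -lam)

    best = max((float(l) for l in lambda_grid), key=score)
    return best, reports


def crossfit_predict(
    labeled: Sequence[LabeledPair],
    lam: float,
    train_size: int,
    seed: int,
    folds: int = 5,
    base_cfg: WlrConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score every labeled pair with a model that never saw it.

    The labeled rows are split into ``folds`` folds; each fold is scored by
    a model fitted on a balanced draw from the remaining folds, with Q/H
    weights (Q = labeled event rate, H = 1/2).  Returns (probabilities,
    classes, truth) aligned over all labeled rows.  In-sample scoring
    flatters a flexible fit; cross-fitting keeps accuracy and AUC honest.
    """
    import warnings as _warnings

    X, y = _labeled_arrays(labeled)
    if np.unique(y).size < 2:
        raise ValueError("need both classes among the labeled rows")
    rng = np.random.default_rng(seed)
    n = y.size
    perm = rng.permutation(n)
    half = max(1, train_size // 2)
    pop_rate = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
    base_cfg = base_cfg or WlrConfig()
    probs = np.zeros(n)
    classes = np.zeros(n, dtype=int)
    for f in range(min(folds, n)):
        test = perm[f::folds]
        pool = np.setdiff1d(perm, test)
        pos = pool[y[pool] == 1]
        neg = pool[y[pool] == 0]
        if pos.size == 0 or neg.size == 0:
            raise ValueError("a fold's training pool lost one class; use fewer folds")
        take_pos = rng.choice(pos, size=half, replace=half > pos.size)
        take_neg = rng.choice(neg, size=half, replace=half > neg.size)
        train = np.concatenate([take_pos, take_neg])
        cfg = replace(
            base_cfg, lam=float(lam), pop_event_rate=pop_rate, sample_event_rate=0.5
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            model = fit(X[train], y[train], cfg)
        p, c = predict(model, X[test])
        probs[test] = p
        classes[test] = c
    return probs, classes, y.astype(int)


def _class_accuracy(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    mask = truth == cls
    if not np.any(mask):
        return float("nan")
    return float(np.mean(pred[mask] == cls))


def roc_curve(probs: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR) sweeping every distinct probability as cutoff."""
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth, dtype=int)
    order = np.argsort(-probs, kind="stable")
    probs_sorted = probs[order]
    truth_sorted = truth[order]
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    tp = np.cumsum(truth_sorted == 1)
    fp = np.cumsum(truth_sorted == 0)
    distinct = np.flatnonzero(np.diff(probs_sorted, append=-np.inf))
    tpr = np.concatenate([[0.0], tp[distinct] / max(n_pos, 1)])
    fpr = np.concatenate([[0.0], fp[distinct] / max(n_neg, 1)])
    return fpr, tpr


def evaluate(
    pred_classes: Sequence[int],
    pred_probs: Sequence[float],
    truth: Sequence[int],
) -> EvalReport:
    """Confusion counts, scalar metrics, ROC points and trapezoidal AUC."""
    pred_classes = np.asarray(pred_classes, dtype=int)
    probs = np.asarray(pred_probs, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if not (pred_classes.size == probs.size == truth.size):
        raise ValueError("inputs must have equal length")
    tp = int(np.sum((pred_classes == 1) & (truth == 1)))
    fp = int(np.sum((pred_classes == 1) & (truth == 0)))
    fn = int(np.sum((pred_classes == 0) & (truth == 1)))
    tn = int(np.sum((pred_classes == 0) & (truth == 0)))

    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    if math.isnan(recall) or math.isnan(precision) or recall + precision == 0:
        f_value = 0.0 if not (math.isnan(recall) or math.isnan(precision)) else float("nan")
    else:
        f_value = 2 * recall * precision / (recall + precision)
    tnr = tn / (tn + fp) if tn + fp else float("nan")

    single_class = not (np.any(truth == 1) and np.any(truth == 0))
    if single_class:
        auc: float | None = None
        roc_pts: tuple[tuple[float, float], ...] = ()
    else:
        fpr, tpr = roc_curve(probs, truth)
        auc = float(np.trapezoid(tpr, fpr))
        roc_pts = tuple((float(a), float(b)) for a, b in zip(fpr, tpr))

    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        recall=recall,
        precision=precision,
        f_value=f_value,
        tnr=tnr,
        accuracy_class0=tnr,
        accuracy_class1=recall,
        auc=auc,
        roc_points=roc_pts,
    )


def build_network(
    predictions: Sequence[tuple[tuple[str, str], float, int]],
) -> RelationGraph:
    """Graph of all pairs predicted related; nodes are the incident genes."""
    edges = sorted(
        (pair[0], pair[1], float(prob))
        for pair, prob, cls in predictions
        if cls == 1
    )
    nodes = sorted({g for a, b, _ in edges for g in (a, b)})
    return RelationGraph(nodes=tuple(nodes), edges=tuple(edges))
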