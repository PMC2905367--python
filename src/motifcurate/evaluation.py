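"""Ranking-performance evaluation: ROC/AUC, score-label correlation, MIE,
and the training-set-size iteration study.

The ROC curve is swept over all score thresholds in descending order with
tied scores processed as one block (producing a diagonal segment), and the
area under it is computed by the trapezoid rule — which makes it equal to
the Mann-Whitney pair-counting statistic with ties counted 1/2.

``performance`` is the correlation coefficient between calculated paper
scores (in [-1, 1]) and the actual 0/1 labels; it is the single number the
iteration study records per training-size cell.

``mie`` (minimotif identification efficiency) is the percentage of papers
in a fully-labeled set that contain minimotifs; it is used to compare
literature-search strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import Document, bag_of_words
from .scoring import (
    PaperScore,
    ZeroVarianceError,
    pearson,
    score_bag,
    train_from_bags,
)

__all__ = [
    "EvaluationError",
    "RocCurve",
    "IterationResult",
    "roc_curve",
    "performance",
    "mie",
    "iterate_training_sizes",
]


class EvaluationError(ValueError):
    """Invalid evaluation input (single-class labels, unknown labels, ...)."""


@dataclass
class RocCurve:
    """Sensitivity/specificity trace: (FPR, TPR) points plus trapezoid AUC."""

    points: list[tuple[float, float]]
    auc: float

    def to_tsv(self) -> str:
        lines = ["fpr\ttpr"]
        lines += [f"{fpr:.6f}\t{tpr:.6f}" for fpr, tpr in self.points]
        lines.append(f"#auc={self.auc:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class IterationResult:
    """Rows of (n_negative, n_positive, performance), in printed-table order."""

    rows: list[tuple[int, int, float]]

    def to_tsv(self) -> str:
        lines = ["negative_papers\tpositive_papers\tpaper_score"]
        lines += [f"{nn}\t{np_}\t{perf:.6f}" for nn, np_, perf in self.rows]
        return "\n".join(lines) + "\n"


def _aligned(
    scores: Sequence[PaperScore], labels: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    missing = [s.pmid for s in scores if s.pmid not in labels]
    if missing:
        raise EvaluationError(f"no label for pmids {missing[:5]}")
    y = np.array([int(labels[s.pmid]) for s in scores])
    if not set(np.unique(y)) <= {0, 1}:
        raise EvaluationError("labels must be 0 or 1")
    x = np.array([s.pc for s in scores], dtype=float)
    return x, y


def roc_curve(
    scores: Sequence[PaperScore], labels: Mapping[str, int]
) -> RocCurve:
    """ROC over all thresholds descending, ties blocked; AUC by trapezoid."""
    x, y = _aligned(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires both a positive and a negative")
    order = np.argsort(-x, kind="stable")
    xs, ys = x[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(xs)
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:  # tie block
            j += 1
        tp += int(ys[i:j].sum())
        fp += (j - i) - int(ys[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points, auc)


def performance(
    scores: Sequence[PaperScore], labels: Mapping[str, int]
) -> float:
    """Pearson correlation between paper scores and 0/1 labels.

    Constant score vectors (degenerate) yield 0.0.
    """
    x, y = _aligned(scores, labels)
    if len(set(y.tolist())) < 2:
        raise EvaluationError("performance requires both classes present")
    try:
        return pearson(x, y.astype(float))
    except ZeroVarianceError:
        return 0.0


def mie(docs: Sequence[Document]) -> float:
    """Percentage of papers in a fully-labeled set that contain minimotifs."""
    if not docs:
        raise EvaluationError("MIE of an empty paper set is undefined")
    unknown = [d.pmid for d in docs if d.label == "unknown"]
    if unknown:
        raise EvaluationError(
            f"MIE requires known labels; unknown for pmids {unknown[:5]}"
        )
    n_pos = sum(1 for d in docs if d.label == "positive")
    return 100.0 * n_pos / len(docs)


def iterate_training_sizes(
    pos_pool: Sequence[Document],
    neg_pool: Sequence[Document],
    pos_sizes: Sequence[int],
    neg_sizes: Sequence[int],
    test_docs: Sequence[Document],
    test_labels: Mapping[str, int],
    stoplist: set[str],
    seed: int,
    replicates: int = 1,
) -> IterationResult:
    """Performance across a grid of (positive, negative) training-set sizes.

    For each cell the requested numbers of documents are drawn from the
    pools without replacement (seeded per replicate and cell), a lexicon is
    trained, the test documents are scored, and ``performance`` is recorded;
    with ``replicates > 1`` the cell value is the mean across replicates.
    Rows are emitted positive-size-major with the negative size varying
    fastest, matching the printed iteration-table layout.
    """
    pool_pmids = {d.pmid for d in pos_pool} | {d.pmid for d in neg_pool}
    if {d.pmid for d in pos_pool} & {d.pmid for d in neg_pool}:
        raise EvaluationError("positive and negative pools overlap")
    clash = pool_pmids & {d.pmid for d in test_docs}
    if clash:
        raise EvaluationError(
            f"test set must be disjoint from the training pools "
            f"(shared pmids {sorted(clash)[:5]})"
        )
    for n in pos_sizes:
        if n > len(pos_pool):
            raise EvaluationError(
                f"requested {n} positive papers but pool has {len(pos_pool)}"
            )
    for n in neg_sizes:
        if n > len(neg_pool):
            raise EvaluationError(
                f"requested {n} negative papers but pool has {len(neg_pool)}"
            )
    if replicates < 1:
        raise EvaluationError("replicates must be >= 1")

    pos_bags = [bag_of_words(d, stoplist) for d in pos_pool]
    neg_bags = [bag_of_words(d, stoplist) for d in neg_pool]
    test_bags = [(d.pmid, bag_of_words(d, stoplist)) for d in test_docs]

    rows: list[tuple[int, int, float]] = []
    for ip, n_pos in enumerate(pos_sizes):
        for ineg, n_neg in enumerate(neg_sizes):
            cell = []
            for rep in range(replicates):
                rng = np.random.default_rng([seed, rep, ip, ineg])
                pi = rng.choice(len(pos_bags), size=n_pos, replace=False)
                ni = rng.choice(len(neg_bags), size=n_neg, replace=False)
                lexicon = train_from_bags(
                    [pos_bags[i] for i in pi], [neg_bags[i] for i in ni]
                )
                scored = [
                    PaperScore(pmid, *score_bag(bag, lexicon))
                    for pmid, bag in test_bags
                ]
                cell.append(performance(scored, test_labels))
            rows.append((n_neg, n_pos, float(np.mean(cell))))
    return IterationResult(rows)
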