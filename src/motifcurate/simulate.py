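"""Synthetic labeled abstract corpora with controlled word enrichment.

Documents are multinomial bags of words over a shared vocabulary.  A set of
positive-marker words has its probability mass multiplied by ``effect``
(then renormalised) in positive-class documents, and symmetrically a set of
negative-marker words is enriched in negative-class documents; unknown-class
documents are drawn from a 50/50 mixture of the two class distributions.
With equal-sized marker sets the two class normalisers coincide, so the
expected positive/negative enrichment ratio of a marker word equals
``effect`` exactly — which gives training, scoring and evaluation a ground
truth to recover.

Bags are rendered to text (title = the first three sampled tokens,
abstract = the rest) so the MEDLINE reader, tokenizer and stop-word filter
are exercised end-to-end on generated corpora.  Everything is deterministic
given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document

__all__ = ["SyntheticSpec", "SyntheticCorpus", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic corpus.

    Defaults emulate abstract-scale documents: a 500-word working
    vocabulary, ~120 informative tokens per document, 20 marker words per
    class, and a two-fold marker enrichment.
    """

    vocab_size: int = 500
    n_marker_pos: int = 20
    n_marker_neg: int = 20
    effect: float = 2.0
    doc_length_mean: int = 120
    n_pos: int = 200
    n_neg: int = 200
    n_unknown: int = 100
    seed: int = 0
    pmid_start: int = 1

    def __post_init__(self) -> None:
        if self.n_marker_pos + self.n_marker_neg > self.vocab_size:
            raise ValueError(
                "marker words exceed the vocabulary "
                f"({self.n_marker_pos}+{self.n_marker_neg} > {self.vocab_size})"
            )
        if self.effect < 1:
            raise ValueError("effect must be >= 1")
        if self.doc_length_mean < 1:
            raise ValueError("doc_length_mean must be positive")
        if min(self.n_pos, self.n_neg, self.n_unknown) < 0:
            raise ValueError("document counts must be >= 0")
        if min(self.n_marker_pos, self.n_marker_neg) < 0:
            raise ValueError("marker counts must be >= 0")


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its marker-word ground truth."""

    corpus: Corpus
    pos_markers: list[str]
    neg_markers: list[str]
    spec: SyntheticSpec = field(repr=False)


def _class_probs(
    vocab_size: int, marker_idx: np.ndarray, effect: float
) -> np.ndarray:
    p = np.ones(vocab_size)
    p[marker_idx] *= effect
    return p / p.sum()


def generate(spec: SyntheticSpec) -> SyntheticCorpus:
    """Draw a labeled corpus from the generative model described above."""
    rng = np.random.default_rng(spec.seed)
    vocab = np.array(
        [f"pmk{i:03d}" for i in range(spec.n_marker_pos)]
        + [f"nmk{i:03d}" for i in range(spec.n_marker_neg)]
        + [
            f"bg{i:05d}"
            for i in range(
                spec.vocab_size - spec.n_marker_pos - spec.n_marker_neg
            )
        ]
    )
    pos_idx = np.arange(spec.n_marker_pos)
    neg_idx = np.arange(
        spec.n_marker_pos, spec.n_marker_pos + spec.n_marker_neg
    )
    p_pos = _class_probs(spec.vocab_size, pos_idx, spec.effect)
    p_neg = _class_probs(spec.vocab_size, neg_idx, spec.effect)

    labels = (
        ["positive"] * spec.n_pos
        + ["negative"] * spec.n_neg
        + ["unknown"] * spec.n_unknown
    )
    docs: list[Document] = []
    for i, label in enumerate(labels):
        if label == "positive":
            p = p_pos
        elif label == "negative":
            p = p_neg
        else:  # 50/50 mixture for unreviewed documents
            p = p_pos if rng.random() < 0.5 else p_neg
        length = max(5, int(rng.poisson(spec.doc_length_mean)))
        counts = rng.multinomial(length, p)
        tokens = np.repeat(vocab, counts)
        rng.shuffle(tokens)
        docs.append(
            Document(
                pmid=str(spec.pmid_start + i),
                title=" ".join(tokens[:3]),
                abstract=" ".join(tokens[3:]),
                journal="Synthetic Corpus",
                year=2010,
                authors=["Generator S"],
                affiliation="in silico",
                label=label,
            )
        )
    return SyntheticCorpus(
        Corpus(docs),
        vocab[pos_idx].tolist(),
        vocab[neg_idx].tolist(),
        spec,
    )
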