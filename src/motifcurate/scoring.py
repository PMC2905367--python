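"""The paper-scoring (PS) algorithm: enrichment-difference lexicon + Pearson.

Training: for every non-stop word *w* occurring in the positive set P or
negative set N of labeled abstracts, the enrichment of *w* in one article is
its occurrence count divided by the article's size (token count after
stop-word removal).  The word's score is

    S(w) = mean enrichment of w over P  -  mean enrichment of w over N

which lies in [-1, 1]: positive scores mark words associated with minimotif
content, negative scores words associated with its absence.

Scoring: an unlabeled article is turned into the vector *v* of enrichments
of each lexicon word in that article (zero for absent words), and its score
*pc* is the Pearson correlation between *v* and the score vector *S*.
Because Pearson correlation is invariant to positive scaling of either
argument, using raw counts instead of enrichments for *v* yields the same
*pc*; the test suite certifies this.

Degenerate cases (empty documents, documents sharing no word with the
lexicon, zero-variance vectors) score 0 with an explicit flag, so that
ranking is total: such papers sort to the middle instead of failing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus import BagOfWords, Document, bag_of_words

__all__ = [
    "ScoringError",
    "TrainingError",
    "ZeroVarianceError",
    "DegenerateDocumentError",
    "ScoredLexicon",
    "PaperScore",
    "word_enrichment",
    "pearson",
    "train_lexicon",
    "train_from_bags",
    "score_paper",
    "score_bag",
    "rank_papers",
    "write_lexicon",
    "read_lexicon",
    "write_scores",
    "read_scores",
]


class ScoringError(ValueError):
    """Base class for scoring/training failures."""


class TrainingError(ScoringError):
    """Invalid training input (empty class, overlap, zero-length document)."""


class ZeroVarianceError(ScoringError):
    """One of the correlated vectors is constant."""


class DegenerateDocumentError(ScoringError):
    """Enrichment requested on a zero-length document."""


@dataclass
class ScoredLexicon:
    """Ordered term vector W with aligned per-word scores S.

    Words are kept in sorted lexicographic order so that identical training
    input yields a bit-identical lexicon.
    """

    words: list[str]
    scores: np.ndarray
    n_pos: int
    n_neg: int
    _index: dict[str, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.words) != self.scores.shape[0]:
            raise ScoringError("scores not aligned to words")
        if len(set(self.words)) != len(self.words):
            raise ScoringError("lexicon words must be distinct")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ScoringError("lexicon requires n_pos >= 1 and n_neg >= 1")
        if self.scores.size and (
            self.scores.min() < -1.0 or self.scores.max() > 1.0
        ):
            raise ScoringError("lexicon scores must lie in [-1, 1]")
        self._index = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    @property
    def index(self) -> dict[str, int]:
        return self._index


@dataclass(frozen=True)
class PaperScore:
    """Pearson score of one paper; ``degenerate`` marks a fallback zero."""

    pmid: str
    pc: float
    degenerate: bool = False


def word_enrichment(word: str, bag: BagOfWords) -> float:
    """Occurrence count of ``word`` divided by the document's size."""
    if bag.length == 0:
        raise DegenerateDocumentError(
            "enrichment undefined on a zero-length document"
        )
    return bag.counts.get(word, 0) / bag.length


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation cov(X, Y) / (sigma_X * sigma_Y).

    Raises :class:`ZeroVarianceError` when either vector is constant.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ScoringError("pearson requires two vectors of equal length")
    if xa.size < 2:
        raise ScoringError("pearson requires length >= 2")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ZeroVarianceError("constant vector has no defined correlation")
    r = float(xc @ yc) / denom
    return min(1.0, max(-1.0, r))


def train_from_bags(
    pos_bags: Sequence[BagOfWords], neg_bags: Sequence[BagOfWords]
) -> ScoredLexicon:
    """Train a lexicon from pre-computed bags (see :func:`train_lexicon`)."""
    if not pos_bags or not neg_bags:
        raise TrainingError("both training classes must be non-empty")
    for bags, name in ((pos_bags, "positive"), (neg_bags, "negative")):
        for i, bag in enumerate(bags):
            if bag.length == 0:
                raise TrainingError(
                    f"zero-length document in {name} training set (index {i})"
                )
    vocab = sorted(
        set().union(*(b.counts.keys() for b in pos_bags)).union(
            *(b.counts.keys() for b in neg_bags)
        )
    )
    index = {w: i for i, w in enumerate(vocab)}
    pos_sum = np.zeros(len(vocab))
    neg_sum = np.zeros(len(vocab))
    for bag in pos_bags:
        for w, c in bag.counts.items():
            pos_sum[index[w]] += c / bag.length
    for bag in neg_bags:
        for w, c in bag.counts.items():
            neg_sum[index[w]] += c / bag.length
    scores = pos_sum / len(pos_bags) - neg_sum / len(neg_bags)
    return ScoredLexicon(vocab, scores, len(pos_bags), len(neg_bags))


def train_lexicon(
    pos_docs: Sequence[Document],
    neg_docs: Sequence[Document],
    stoplist: set[str],
) -> ScoredLexicon:
    """Train a scored lexicon from positive and negative abstract sets.

    The two sets must be non-empty and disjoint by PMID; every document
    must have at least one non-stop token.
    """
    if not pos_docs or not neg_docs:
        raise TrainingError("both training classes must be non-empty")
    overlap = {d.pmid for d in pos_docs} & {d.pmid for d in neg_docs}
    if overlap:
        raise TrainingError(
            f"training sets overlap on pmids {sorted(overlap)[:5]}"
        )
    return train_from_bags(
        [bag_of_words(d, stoplist) for d in pos_docs],
        [bag_of_words(d, stoplist) for d in neg_docs],
    )


def score_bag(bag: BagOfWords, lexicon: ScoredLexicon) -> tuple[float, bool]:
    """Score one bag against the lexicon; returns ``(pc, degenerate)``."""
    if len(lexicon) < 2:
        raise ScoringError("scoring requires a lexicon with >= 2 words")
    if bag.length == 0:
        return 0.0, True
    v = np.zeros(len(lexicon))
    index = lexicon.index
    hit = False
    for w, c in bag.counts.items():
        i = index.get(w)
        if i is not None:
            v[i] = c / bag.length
            hit = True
    if not hit:
        return 0.0, True
    try:
        return pearson(v, lexicon.scores), False
    except ZeroVarianceError:
        return 0.0, True


def score_paper(
    doc: Document, lexicon: ScoredLexicon, stoplist: set[str]
) -> PaperScore:
    """Score one document; words outside the lexicon are ignored."""
    pc, degenerate = score_bag(bag_of_words(doc, stoplist), lexicon)
    return PaperScore(doc.pmid, pc, degenerate)


def _pmid_key(pmid: str) -> tuple[int, int | str]:
    # numeric PMIDs sort numerically, everything else lexicographically after
    return (0, int(pmid)) if pmid.isdigit() else (1, pmid)


def rank_papers(
    scores: Iterable[PaperScore], limit: int = 1000
) -> list[PaperScore]:
    """Order papers by descending score, ties broken by ascending PMID.

    At most ``limit`` rows are returned (default 1000, the display cap).
    """
    ordered = sorted(scores, key=lambda s: (-s.pc, _pmid_key(s.pmid)))
    return ordered[:limit] if limit is not None else ordered


def write_lexicon(lexicon: ScoredLexicon) -> str:
    """Serialise a lexicon as TSV: header comment, then word<TAB>score."""
    lines = [f"#n_pos={lexicon.n_pos} n_neg={lexicon.n_neg}"]
    lines += [
        f"{w}\t{s:.6f}" for w, s in zip(lexicon.words, lexicon.scores)
    ]
    return "\n".join(lines) + "\n"


_LEXICON_HEADER_RE = re.compile(r"#n_pos=(\d+) n_neg=(\d+)")


def read_lexicon(text: str) -> ScoredLexicon:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ScoringError("empty lexicon file")
    m = _LEXICON_HEADER_RE.match(lines[0])
    if not m:
        raise ScoringError("lexicon file lacks the '#n_pos=.. n_neg=..' header")
    words: list[str] = []
    scores: list[float] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ScoringError(f"lexicon line {lineno}: expected 2 columns")
        words.append(parts[0])
        scores.append(float(parts[1]))
    return ScoredLexicon(words, np.array(scores), int(m.group(1)), int(m.group(2)))


def write_scores(scores: Iterable[PaperScore]) -> str:
    lines = ["pmid\tpc\tdegenerate"]
    lines += [
        f"{s.pmid}\t{s.pc:.6f}\t{int(s.degenerate)}" for s in scores
    ]
    return "\n".join(lines) + "\n"


def read_scores(text: str) -> list[PaperScore]:
    out: list[PaperScore] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if parts == ["pmid", "pc", "degenerate"]:
            continue
        if len(parts) != 3:
            raise ScoringError(f"scores line {lineno}: expected 3 columns")
        out.append(PaperScore(parts[0], float(parts[1]), bool(int(parts[2]))))
    return out
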