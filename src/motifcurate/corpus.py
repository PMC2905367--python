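"""Abstract records and their bag-of-words form.

This module holds the document model shared by the whole toolkit: one
:class:`Document` per literature abstract (PMID, title, abstract text,
bibliographic metadata and an optional curation label), a :class:`Corpus`
container enforcing PMID uniqueness, and the tokenisation / stop-word /
bag-of-words pipeline that turns free text into the count form the scoring
algorithm consumes.

I/O covers the two flat formats used throughout: tag-prefixed MEDLINE
records (``PMID-``, ``TI  -``, ``AB  -``, ...) and a JSON-lines dialect with
one object per line.  MEDLINE parsing is delegated to :mod:`Bio.Medline`;
the writer produces records that round-trip through that parser.
"""

from __future__ import annotations

import json
import re
import textwrap
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Iterable, Iterator, Sequence

from Bio import Medline

__all__ = [
    "LABELS",
    "CorpusError",
    "Document",
    "Corpus",
    "BagOfWords",
    "tokenize",
    "remove_stopwords",
    "bag_of_words",
    "load_stopwords",
    "parse_medline",
    "write_medline",
    "read_jsonl",
    "write_jsonl",
    "read_labels",
    "write_labels",
]

#: The three curation labels a document may carry.
LABELS = ("positive", "negative", "unknown")


class CorpusError(ValueError):
    """Raised for malformed records, duplicate PMIDs or invalid labels."""


@dataclass
class Document:
    """One abstract record.

    ``label`` records whether the paper is known to contain a minimotif
    (``positive``), known not to (``negative``) or has not been reviewed
    (``unknown``, the default).  ``score`` stays ``None`` until the paper
    has been scored.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    journal: str = ""
    year: int | None = None
    authors: list[str] = field(default_factory=list)
    affiliation: str = ""
    label: str = "unknown"
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise CorpusError("document requires a non-empty pmid")
        if self.label not in LABELS:
            raise CorpusError(
                f"invalid label {self.label!r}; expected one of {LABELS}"
            )


@dataclass
class Corpus:
    """An ordered collection of documents with unique PMIDs."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.pmid in seen:
                raise CorpusError(f"duplicate pmid {doc.pmid!r} in corpus")
            seen.add(doc.pmid)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def with_label(self, label: str) -> list[Document]:
        if label not in LABELS:
            raise CorpusError(f"invalid label {label!r}")
        return [d for d in self.documents if d.label == label]

    @property
    def positives(self) -> list[Document]:
        return self.with_label("positive")

    @property
    def negatives(self) -> list[Document]:
        return self.with_label("negative")

    @property
    def unknowns(self) -> list[Document]:
        return self.with_label("unknown")


@dataclass
class BagOfWords:
    """Word counts of one document after stop-word removal.

    ``length`` is the total surviving token count and equals the sum of
    ``counts``; zero-length bags (empty title and abstract) are legal here
    but rejected by downstream enrichment computations.
    """

    counts: dict[str, int]
    length: int

    def __post_init__(self) -> None:
        if self.length != sum(self.counts.values()):
            raise CorpusError("bag length does not equal the sum of counts")
        if any(c < 1 for c in self.counts.values()):
            raise CorpusError("bag counts must be >= 1")


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Split text into lower-cased maximal alphanumeric runs.

    Punctuation (including hyphens) separates tokens, so ``"SH3-domain"``
    yields ``["sh3", "domain"]``.  Order is preserved; empty text yields an
    empty list.
    """
    return _TOKEN_RE.findall(text.lower())


def remove_stopwords(tokens: Sequence[str], stoplist: set[str]) -> list[str]:
    """Drop tokens present in ``stoplist`` (assumed lower-cased)."""
    return [t for t in tokens if t not in stoplist]


def bag_of_words(doc: Document, stoplist: set[str]) -> BagOfWords:
    """Bag of words over the document's title plus abstract.

    The scoring text is the concatenation of title and abstract; document
    "size" (the enrichment denominator) is the token count remaining after
    stop-word removal.
    """
    tokens = remove_stopwords(
        tokenize(doc.title) + tokenize(doc.abstract), stoplist
    )
    counts = Counter(tokens)
    return BagOfWords(dict(counts), sum(counts.values()))


def load_stopwords(path: str | None = None) -> set[str]:
    """Load a stop-word list: one word per line, ``#`` comments allowed.

    With no ``path`` the packaged default English list is used.
    """
    if path is None:
        text = (
            resources.files("motifcurate") / "data" / "stopwords.txt"
        ).read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    words: set[str] = set()
    for line in text.splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return words


def _as_str(value: str | list[str] | None) -> str:
    if value is None:
        return ""
    if isinstance(value, list):
        return " ".join(value)
    return value


def parse_medline(text: str) -> list[Document]:
    """Parse tag-prefixed MEDLINE flat text into documents.

    Records are separated by blank lines; continuation lines begin with
    whitespace.  A record without a PMID raises :class:`CorpusError` naming
    the record index; duplicate PMIDs raise as well.  A record with no
    ``AB`` field yields an empty abstract.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    for index, rec in enumerate(Medline.parse(StringIO(text))):
        pmid = rec.get("PMID", "").strip()
        if not pmid:
            raise CorpusError(f"MEDLINE record {index} has no PMID")
        if pmid in seen:
            raise CorpusError(f"duplicate PMID {pmid!r} (record {index})")
        seen.add(pmid)
        year: int | None = None
        dp = rec.get("DP", "")
        m = re.match(r"\s*(\d{4})", dp)
        if m:
            year = int(m.group(1))
        docs.append(
            Document(
                pmid=pmid,
                title=rec.get("TI", ""),
                abstract=rec.get("AB", ""),
                journal=rec.get("JT", ""),
                year=year,
                authors=list(rec.get("AU", [])),
                affiliation=_as_str(rec.get("AD")),
            )
        )
    return docs


def _medline_field(tag: str, text: str) -> list[str]:
    # MEDLINE wraps long values onto continuation lines indented 6 spaces.
    chunks = textwrap.wrap(
        text, width=74, break_long_words=False, break_on_hyphens=False
    )
    if not chunks:
        return []
    head = f"{tag:<4}- {chunks[0]}"
    return [head] + [" " * 6 + c for c in chunks[1:]]


def write_medline(docs: Iterable[Document]) -> str:
    """Render documents as MEDLINE flat text that `parse_medline` reads back."""
    blocks: list[str] = []
    for doc in docs:
        lines = [f"PMID- {doc.pmid}"]
        lines += _medline_field("TI", doc.title)
        lines += _medline_field("AB", doc.abstract)
        lines += _medline_field("JT", doc.journal)
        if doc.year is not None:
            lines.append(f"DP  - {doc.year}")
        for author in doc.authors:
            lines += _medline_field("AU", author)
        lines += _medline_field("AD", doc.affiliation)
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


_JSONL_KEYS = (
    "pmid",
    "title",
    "abstract",
    "journal",
    "year",
    "authors",
    "affiliation",
    "label",
)


def read_jsonl(text: str) -> list[Document]:
    """Read the JSON-lines dialect: one object per line, keys as documented."""
    docs: list[Document] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusError(f"line {lineno}: invalid JSON ({exc})") from exc
        unknown = set(obj) - set(_JSONL_KEYS)
        if unknown:
            raise CorpusError(f"line {lineno}: unknown keys {sorted(unknown)}")
        pmid = str(obj.get("pmid", ""))
        if not pmid:
            raise CorpusError(f"line {lineno}: missing pmid")
        if pmid in seen:
            raise CorpusError(f"line {lineno}: duplicate pmid {pmid!r}")
        seen.add(pmid)
        docs.append(
            Document(
                pmid=pmid,
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
                journal=obj.get("journal", ""),
                year=obj.get("year"),
                authors=list(obj.get("authors", [])),
                affiliation=obj.get("affiliation", ""),
                label=obj.get("label", "unknown"),
            )
        )
    return docs


def write_jsonl(docs: Iterable[Document]) -> str:
    lines = []
    for doc in docs:
        obj = {
            "pmid": doc.pmid,
            "title": doc.title,
            "abstract": doc.abstract,
            "journal": doc.journal,
            "year": doc.year,
            "authors": doc.authors,
            "affiliation": doc.affiliation,
            "label": doc.label,
        }
        lines.append(json.dumps(obj, sort_keys=True))
    return "\n".join(lines) + ("\n" if lines else "")


def read_labels(text: str) -> dict[str, str]:
    """Read a labels TSV (``pmid<TAB>label``); a header row is optional."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise CorpusError(f"labels line {lineno}: expected 2 columns")
        pmid, label = parts
        if lineno == 1 and (pmid, label) == ("pmid", "label"):
            continue
        if label not in LABELS:
            raise CorpusError(f"labels line {lineno}: invalid label {label!r}")
        if pmid in labels:
            raise CorpusError(f"labels line {lineno}: duplicate pmid {pmid!r}")
        labels[pmid] = label
    return labels


def write_labels(docs: Iterable[Document]) -> str:
    lines = ["pmid\tlabel"]
    lines += [f"{doc.pmid}\t{doc.label}" for doc in docs]
    return "\n".join(lines) + "\n"


def apply_labels(corpus: Corpus, labels: dict[str, str]) -> None:
    """Attach labels (by PMID) to corpus documents in place."""
    for doc in corpus:
        if doc.pmid in labels:
            label = labels[doc.pmid]
            if label not in LABELS:
                raise CorpusError(f"invalid label {label!r} for {doc.pmid}")
            doc.label = label
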