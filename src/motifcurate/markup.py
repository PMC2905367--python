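"""Abstract keyword markup: attribute-driven highlighting of abstracts.

Terms drawn from the annotation database's attribute vocabularies are
matched case-insensitively as whole words in an abstract and assigned one
of six colors by category — minimotif (purple), activity (blue), target
(orange), putative minimotif (red), affinity (yellow), protein domain
(green) — and the literal word "motif" is additionally bolded.

Overlapping candidate matches are resolved by a fixed category priority
(minimotif > putative_minimotif > activity > target > affinity >
protein_domain > motif bolding), with the longer match preferred within a
category; the emitted spans are non-overlapping and sorted.  Rendering
targets HTML with inline styles; stripping the tags recovers the escaped
abstract text byte-for-byte.
"""

from __future__ import annotations

import html
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MarkupError",
    "CATEGORY_PRIORITY",
    "CATEGORY_COLORS",
    "MOTIF_BOLD",
    "KeywordCatalog",
    "HighlightSpan",
    "highlight",
    "render_html",
    "load_terms",
]


class MarkupError(ValueError):
    """Invalid catalog or spans."""


#: Categories in overlap-priority order (highest first).
CATEGORY_PRIORITY = (
    "minimotif",
    "putative_minimotif",
    "activity",
    "target",
    "affinity",
    "protein_domain",
)

#: Pseudo-category for bolding the literal word "motif".
MOTIF_BOLD = "motif_bold"

CATEGORY_COLORS: dict[str, str] = {
    "minimotif": "purple",
    "activity": "blue",
    "target": "orange",
    "putative_minimotif": "red",
    "affinity": "yellow",
    "protein_domain": "green",
    MOTIF_BOLD: "bold",
}


@dataclass
class KeywordCatalog:
    """Per-category term sets; the category set is closed."""

    categories: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.categories) - set(CATEGORY_PRIORITY)
        if unknown:
            raise MarkupError(
                f"unknown categories {sorted(unknown)}; valid categories: "
                + ", ".join(CATEGORY_PRIORITY)
            )
        for cat, terms in self.categories.items():
            if any(not t for t in terms):
                raise MarkupError(f"empty term in category {cat!r}")
        for cat in CATEGORY_PRIORITY:
            self.categories.setdefault(cat, set())


@dataclass(frozen=True)
class HighlightSpan:
    """0-based half-open character span with its category and color."""

    start: int
    end: int
    category: str
    color: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MarkupError("span must satisfy 0 <= start < end")


def _word_regex(term: str) -> re.Pattern[str]:
    # whole-word: no letter/digit immediately adjacent to the match
    return re.compile(
        r"(?<![0-9A-Za-z])" + re.escape(term) + r"(?![0-9A-Za-z])",
        re.IGNORECASE,
    )


def highlight(text: str, catalog: KeywordCatalog) -> list[HighlightSpan]:
    """Compute non-overlapping, sorted highlight spans for an abstract."""
    candidates: list[tuple[int, int, int, str]] = []
    for prio, cat in enumerate(CATEGORY_PRIORITY):
        for term in catalog.categories.get(cat, ()):
            for m in _word_regex(term).finditer(text):
                candidates.append((prio, m.start(), m.end(), cat))
    for m in _word_regex("motif").finditer(text):
        candidates.append((len(CATEGORY_PRIORITY), m.start(), m.end(), MOTIF_BOLD))

    # priority first, longer match next, then earliest position
    candidates.sort(key=lambda c: (c[0], -(c[2] - c[1]), c[1]))
    accepted: list[HighlightSpan] = []
    taken: list[tuple[int, int]] = []
    for _, start, end, cat in candidates:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        accepted.append(HighlightSpan(start, end, cat, CATEGORY_COLORS[cat]))
    accepted.sort(key=lambda s: s.start)
    return accepted


def render_html(text: str, spans: Sequence[HighlightSpan]) -> str:
    """Wrap spans in color-styled HTML; tags strip back to the escaped text."""
    ordered = sorted(spans, key=lambda s: s.start)
    prev_end = 0
    for span in ordered:
        if span.start < prev_end:
            raise MarkupError("overlapping spans must be resolved before rendering")
        if span.end > len(text):
            raise MarkupError("span exceeds text bounds")
        prev_end = span.end
    parts: list[str] = []
    cursor = 0
    for span in ordered:
        parts.append(html.escape(text[cursor : span.start]))
        inner = html.escape(text[span.start : span.end])
        if span.color == "bold":
            parts.append(f"<b>{inner}</b>")
        else:
            parts.append(
                f'<span style="color: {span.color}" class="{span.category}">'
                f"{inner}</span>"
            )
        cursor = span.end
    parts.append(html.escape(text[cursor:]))
    return "".join(parts)


def load_terms(lines: Iterable[str]) -> set[str]:
    """Read a one-term-per-line catalog file; '#' comments and blanks skipped."""
    terms: set[str] = set()
    for line in lines:
        term = line.split("#", 1)[0].strip()
        if term:
            terms.add(term)
    return terms


def catalog_from_files(paths: Mapping[str, str]) -> KeywordCatalog:
    """Build a catalog from {category: path} of one-term-per-line files."""
    categories: dict[str, set[str]] = {}
    for cat, path in paths.items():
        with open(path, encoding="utf-8") as fh:
            categories[cat] = load_terms(fh)
    return KeywordCatalog(categories)
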