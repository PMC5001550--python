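"""Core data model: documents, stand-off mentions, annotation sets and runs.

All character offsets in this package are 0-based, half-open ``[start, end)``
and counted in Unicode code points of the raw section text, separately for the
title (``T``) and the abstract (``A``).  No text normalisation is ever applied
before offsets are taken; slice fidelity (``text == section[start:end]``) is
enforced at load time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import InvariantError

SECTIONS = ("T", "A")

#: Chemical-entity mention classes used in the patent-abstract chemistry task.
CEMP_CLASSES = (
    "SYSTEMATIC",
    "TRIVIAL",
    "FAMILY",
    "FORMULA",
    "ABBREVIATIONS",
    "IDENTIFIERS",
    "MULTIPLE",
    "NO CLASS",
)

#: Gene/protein-related-object mention classes.
GPRO_CLASSES = (
    "NESTED MENTIONS",
    "IDENTIFIER",
    "FULL NAME",
    "ABBREVIATION",
)

PROVENANCES = ("manual", "automatic", "accepted", "predicted")


@dataclass(frozen=True)
class Document:
    """A title + abstract pair addressed by a unique document identifier."""

    doc_id: str
    title: str
    abstract: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise InvariantError("doc_id must be non-empty")
        if not self.title and not self.abstract:
            raise InvariantError(
                f"document {self.doc_id!r}: title and abstract are both empty"
            )

    def section_text(self, section: str) -> str:
        if section == "T":
            return self.title
        if section == "A":
            return self.abstract
        raise ValueError(f"unknown section {section!r} (expected 'T' or 'A')")


class Corpus:
    """Ordered collection of :class:`Document`, keyed by ``doc_id``."""

    def __init__(self, documents: Iterable[Document] = ()) -> None:
        self._docs: dict[str, Document] = {}
        for doc in documents:
            self.add(doc)

    def add(self, doc: Document) -> None:
        if doc.doc_id in self._docs:
            raise InvariantError(f"duplicate doc_id {doc.doc_id!r}")
        self._docs[doc.doc_id] = doc

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._docs

    def __getitem__(self, doc_id: str) -> Document:
        return self._docs[doc_id]

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs.values())

    def __len__(self) -> int:
        return len(self._docs)

    @property
    def doc_ids(self) -> list[str]:
        return list(self._docs)

    def section_text(self, doc_id: str, section: str) -> str:
        return self._docs[doc_id].section_text(section)


@dataclass(frozen=True)
class Mention:
    """A stand-off annotation: one contiguous span in one document section.

    ``provenance`` records how the mention came to exist: ``manual`` (expert
    annotation), ``automatic`` (propagated recommendation awaiting review),
    ``accepted`` (recommendation kept after review) or ``predicted`` (system
    output under evaluation).
    """

    doc_id: str
    section: str
    start: int
    end: int
    text: str
    cls: Optional[str] = None
    provenance: str = "manual"
    confidence: Optional[float] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise InvariantError(
                f"section must be one of {SECTIONS}, got {self.section!r}"
            )
        if not (0 <= self.start < self.end):
            raise InvariantError(
                f"invalid span [{self.start}, {self.end}) in {self.doc_id}"
            )
        if self.provenance not in PROVENANCES:
            raise InvariantError(f"unknown provenance {self.provenance!r}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise InvariantError(f"confidence {self.confidence} outside [0, 1]")
        if self.rank is not None and self.rank < 1:
            raise InvariantError(f"rank must be >= 1, got {self.rank}")

    @property
    def span_key(self) -> tuple[str, str, int, int]:
        """Identity used for exact matching: (doc, section, start, end)."""
        return (self.doc_id, self.section, self.start, self.end)

    def overlaps(self, other: "Mention") -> bool:
        """True when the two spans share at least one code point."""
        return (
            self.doc_id == other.doc_id
            and self.section == other.section
            and self.start < other.end
            and other.start < self.end
        )

    def replace(self, **changes) -> "Mention":
        return dataclasses.replace(self, **changes)


def _sort_key(m: Mention) -> tuple:
    return (m.doc_id, m.section, m.start, m.end, m.cls or "")


@dataclass
class AnnotationSet:
    """A validated gold/curated annotation set over one corpus.

    Invariants: no two mentions in the same document section overlap (which
    subsumes the no-nesting rule for exclusive annotation classes), and every
    mention's class, when present, belongs to ``class_inventory``.
    """

    task: str = "custom"
    class_inventory: tuple[str, ...] = ()
    mentions: list[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.class_inventory = tuple(self.class_inventory)
        self.validate()

    def validate(self) -> None:
        by_section: dict[tuple[str, str], list[Mention]] = {}
        for m in self.mentions:
            if self.class_inventory and m.cls is not None and m.cls not in self.class_inventory:
                raise InvariantError(
                    f"class {m.cls!r} not in inventory for task {self.task}"
                )
            by_section.setdefault((m.doc_id, m.section), []).append(m)
        for (doc_id, section), group in by_section.items():
            group.sort(key=lambda m: (m.start, m.end))
            for a, b in zip(group, group[1:]):
                if a.start < b.end and b.start < a.end:
                    raise InvariantError(
                        f"overlapping mentions in {doc_id}/{section}: "
                        f"[{a.start},{a.end}) {a.text!r} and "
                        f"[{b.start},{b.end}) {b.text!r}"
                    )

    def by_doc(self) -> dict[str, list[Mention]]:
        out: dict[str, list[Mention]] = {}
        for m in sorted(self.mentions, key=_sort_key):
            out.setdefault(m.doc_id, []).append(m)
        return out

    def by_section(self, doc_id: str, section: str) -> list[Mention]:
        return sorted(
            (m for m in self.mentions if m.doc_id == doc_id and m.section == section),
            key=lambda m: m.start,
        )

    def replace_mentions(self, mentions: Iterable[Mention]) -> "AnnotationSet":
        return AnnotationSet(
            task=self.task,
            class_inventory=self.class_inventory,
            mentions=list(mentions),
        )

    def __len__(self) -> int:
        return len(self.mentions)


MAX_RUNS_PER_TEAM = 5


@dataclass
class PredictionRun:
    """One system submission: a deduplicated set of predicted mentions.

    Predicted mentions may overlap each other (systems emit what they emit);
    only exact span duplicates are collapsed at load time.
    """

    team_id: str
    run_id: int
    mentions: list[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.run_id <= MAX_RUNS_PER_TEAM):
            raise InvariantError(
                f"run_id must be in [1, {MAX_RUNS_PER_TEAM}], got {self.run_id}"
            )
        seen: set[tuple] = set()
        for m in self.mentions:
            if m.span_key in seen:
                raise InvariantError(f"duplicate predicted span {m.span_key}")
            seen.add(m.span_key)

    def by_doc(self) -> dict[str, list[Mention]]:
        out: dict[str, list[Mention]] = {}
        for m in sorted(self.mentions, key=_sort_key):
            out.setdefault(m.doc_id, []).append(m)
        return out

    def __len__(self) -> int:
        return len(self.mentions)


@dataclass
class ValidationReport:
    """Outcome of structural submission checks; never raised, always returned."""

    errors: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add_error(self, line: int, code: str, message: str) -> None:
        self.errors.append((line, code, message))

    def add_warning(self, line: int, code: str, message: str) -> None:
        self.warnings.append((line, code, message))

    def extend(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)


def inventory_for_task(task: str) -> tuple[str, ...]:
    """Default class inventory for the built-in task labels."""
    if task == "CEMP":
        return CEMP_CLASSES
    if task == "GPRO":
        return GPRO_CLASSES
    return ()
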