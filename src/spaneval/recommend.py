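"""Semi-automatic annotation: propagate manual annotations by exact,
case-insensitive matching, revise the suggestions, and accept the remainder.

The workflow mirrors dictionary-based recommendation in curation projects: a
lexicon is built from the annotation history (every manually annotated surface
form with its class frequencies), each document is scanned for unlabelled
occurrences of those forms, a curator removes or edits the bad suggestions,
and whatever remains is implicitly accepted into the gold set.

Case-insensitivity means full Unicode case folding (``str.casefold``), the
same normalisation used when grouping error terms.  Matching never crosses the
title/abstract boundary and suggested spans never overlap existing
annotations or each other; overlapping candidates are resolved greedily,
longest span first, then leftmost.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional
import unicodedata

from .errors import InvariantError
from .types import AnnotationSet, Corpus, Mention


@dataclass
class LexiconEntry:
    display: str                      # most frequent original casing
    class_counts: Counter = field(default_factory=Counter)
    total: int = 0
    last_seen: dict = field(default_factory=dict)  # class -> input index


@dataclass
class Lexicon:
    """Case-folded surface forms harvested from manual annotations."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, folded_form: str) -> bool:
        return folded_form in self.entries

    def majority_class(self, folded_form: str) -> Optional[str]:
        """The most frequent class for a form; ties go to the class whose most
        recent contributing annotation came last in input order."""
        entry = self.entries[folded_form]
        if not entry.class_counts:
            return None
        return max(
            entry.class_counts,
            key=lambda c: (entry.class_counts[c], entry.last_seen.get(c, -1)),
        )


def build_lexicon(aset: AnnotationSet) -> Lexicon:
    """One entry per distinct case-folded surface form of the manual set."""
    lex = Lexicon()
    casing_counts: dict[str, Counter] = {}
    casing_first: dict[str, dict[str, int]] = {}
    for i, m in enumerate(aset.mentions):
        folded = m.text.casefold()
        entry = lex.entries.setdefault(folded, LexiconEntry(display=m.text))
        entry.total += 1
        if m.cls is not None:
            entry.class_counts[m.cls] += 1
            entry.last_seen[m.cls] = i
        casing_counts.setdefault(folded, Counter())[m.text] += 1
        casing_first.setdefault(folded, {}).setdefault(m.text, i)
    for folded, entry in lex.entries.items():
        entry.display = min(
            casing_counts[folded],
            key=lambda c: (-casing_counts[folded][c], casing_first[folded][c]),
        )
    return lex


@dataclass
class RecommendationSet:
    """Automatic suggestions awaiting curator review."""

    suggestions: list[Mention] = field(default_factory=list)
    source_set: Optional[AnnotationSet] = None

    def __len__(self) -> int:
        return len(self.suggestions)


def _is_word_char(ch: str) -> bool:
    cat = unicodedata.category(ch)
    return cat[0] in ("L", "N") or ch == "_"


def find_occurrences(text: str, folded_forms: Iterable[str]) -> list[tuple[int, int, str]]:
    """All spans (start, end, folded_form) whose case-folded slice equals a form.

    Scanning folds the text one code point at a time, which is exact because
    ``str.casefold`` maps each code point independently; a raw slice can only
    fold to something at least as long as itself, so candidate spans are
    bounded by the longest folded form.
    """
    forms = set(folded_forms)
    if not forms:
        return []
    max_len = max(len(f) for f in forms)
    n = len(text)
    out = []
    for i in range(n):
        folded = ""
        j = i
        while j < n and len(folded) < max_len:
            folded += text[j].casefold()
            j += 1
            if folded in forms:
                out.append((i, j, folded))
    return out


def suggest_annotations(
    corpus: Corpus,
    aset: AnnotationSet,
    lex: Lexicon,
    boundary: str = "word",
) -> RecommendationSet:
    """Scan the corpus for unlabelled occurrences of lexicon forms.

    Occurrences overlapping an existing annotation are skipped (nesting is
    never allowed); competing occurrences are resolved greedily — longest
    span first, then leftmost.  With ``boundary="word"`` a match must abut
    non-word characters or the text edges, so forms do not fire inside longer
    words; ``boundary="none"`` suggests every non-overlapping occurrence.
    The suggested class is the lexicon entry's majority class.
    """
    if boundary not in ("word", "none"):
        raise ValueError(f"boundary must be 'word' or 'none', got {boundary!r}")
    suggestions: list[Mention] = []
    for doc in corpus:
        for section in ("T", "A"):
            text = doc.section_text(section)
            if not text:
                continue
            existing = aset.by_section(doc.doc_id, section)
            occurrences = find_occurrences(text, lex.entries.keys())
            if boundary == "word":
                occurrences = [
                    (s, e, f) for s, e, f in occurrences
                    if (s == 0 or not _is_word_char(text[s - 1]))
                    and (e == len(text) or not _is_word_char(text[e]))
                ]
            # greedy resolution: longest span first, then leftmost
            occurrences.sort(key=lambda o: (-(o[1] - o[0]), o[0]))
            taken: list[tuple[int, int]] = [(m.start, m.end) for m in existing]
            for s, e, folded in occurrences:
                if any(s < te and ts < e for ts, te in taken):
                    continue
                taken.append((s, e))
                suggestions.append(
                    Mention(
                        doc_id=doc.doc_id, section=section, start=s, end=e,
                        text=text[s:e], cls=lex.majority_class(folded),
                        provenance="automatic",
                    )
                )
    suggestions.sort(key=lambda m: (m.doc_id, m.section, m.start))
    return RecommendationSet(suggestions=suggestions, source_set=aset)


@dataclass(frozen=True)
class Edit:
    """A curator's change to one suggestion: a new span and/or a new class."""

    target: Mention
    start: Optional[int] = None
    end: Optional[int] = None
    cls: Optional[str] = None


def revise(
    recs: RecommendationSet,
    corpus: Corpus,
    removals: Iterable[Mention] = (),
    edits: Iterable[Edit] = (),
) -> RecommendationSet:
    """Apply curator removals and edits, re-validating all invariants."""
    current = list(recs.suggestions)
    for ref in removals:
        if ref not in current:
            raise InvariantError(f"removal target not among suggestions: {ref}")
        current.remove(ref)
    for ed in edits:
        if ed.target not in current:
            raise InvariantError(f"edit target not among suggestions: {ed.target}")
        idx = current.index(ed.target)
        m = ed.target
        start = ed.start if ed.start is not None else m.start
        end = ed.end if ed.end is not None else m.end
        cls = ed.cls if ed.cls is not None else m.cls
        text = corpus.section_text(m.doc_id, m.section)
        if not (0 <= start < end <= len(text)):
            raise InvariantError(f"edited span [{start},{end}) outside section")
        new = m.replace(start=start, end=end, cls=cls, text=text[start:end])
        others = [x for i, x in enumerate(current) if i != idx]
        manual = recs.source_set.mentions if recs.source_set else []
        for other in list(others) + list(manual):
            if new.overlaps(other):
                raise InvariantError(
                    f"edit rejected: [{start},{end}) would overlap "
                    f"[{other.start},{other.end}) {other.text!r}"
                )
        current[idx] = new
    return RecommendationSet(suggestions=current, source_set=recs.source_set)


def finalize_annotations(
    aset: AnnotationSet, recs: RecommendationSet
) -> AnnotationSet:
    """Implicitly accept remaining suggestions into the annotation set.

    Former suggestions carry provenance ``accepted``; the merged set must
    satisfy every annotation-set invariant (stale recommendations that now
    overlap raise).
    """
    accepted = [m.replace(provenance="accepted") for m in recs.suggestions]
    return aset.replace_mentions(list(aset.mentions) + accepted)


def batch_retype(
    aset: AnnotationSet, term: str, from_class: Optional[str], to_class: Optional[str]
) -> tuple[AnnotationSet, int]:
    """Retype every mention of ``term`` (case-insensitive) from one class to
    another; returns the new set and the number of changes."""
    if aset.class_inventory and to_class is not None and to_class not in aset.class_inventory:
        raise InvariantError(f"class {to_class!r} not in inventory")
    folded = term.casefold()
    changed = 0
    out = []
    for m in aset.mentions:
        if m.text.casefold() == folded and m.cls == from_class:
            out.append(m.replace(cls=to_class))
            changed += 1
        else:
            out.append(m)
    return aset.replace_mentions(out), changed


def delete_term(
    aset: AnnotationSet, term: str, cls: Optional[str] = None
) -> tuple[AnnotationSet, int]:
    """Delete all mentions of ``term`` (case-insensitive), optionally
    restricted to one class; returns the new set and the removal count."""
    folded = term.casefold()
    kept, removed = [], 0
    for m in aset.mentions:
        if m.text.casefold() == folded and (cls is None or m.cls == cls):
            removed += 1
        else:
            kept.append(m)
    return aset.replace_mentions(kept), removed


def review_listing(recs: RecommendationSet) -> str:
    """Plain-text listing of suggested terms to review, indexed by document."""
    lines = []
    by_doc: dict[str, list[Mention]] = {}
    for m in recs.suggestions:
        by_doc.setdefault(m.doc_id, []).append(m)
    for doc_id in sorted(by_doc):
        lines.append(doc_id)
        for m in sorted(by_doc[doc_id], key=lambda m: (m.section, m.start)):
            lines.append(
                f"  {m.section}:{m.start}:{m.end}\t{m.text}\t{m.cls or ''}"
            )
    return "\n".join(lines) + ("\n" if lines else "")
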