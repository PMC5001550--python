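"""Readers and writers for the stand-off TSV dialects and inline-HTML export.

Three headerless, UTF-8, tab-separated dialects are used throughout:

* documents:   ``doc_id \\t title \\t abstract``
* gold:        ``doc_id \\t section(T|A) \\t start \\t end \\t text \\t class``
  (stand-off export appends ``\\t provenance``)
* predictions: ``doc_id \\t section:start:end \\t rank \\t confidence``
  (extended dialect appends ``\\t text \\t class``)

Lines may end in ``\\n`` or ``\\r\\n``; empty lines are ignored.  Offsets are
0-based half-open code-point offsets into the raw section text.  The concrete
dialect is deliberately isolated in this module so that a format swap touches
nothing else.
"""

from __future__ import annotations

import html
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import FormatError
from .types import (
    MAX_RUNS_PER_TEAM,
    AnnotationSet,
    Corpus,
    Document,
    Mention,
    PredictionRun,
    ValidationReport,
)


def _iter_lines(path: str | Path):
    """Yield (1-based line number, stripped line) for non-empty lines."""
    try:
        with open(path, encoding="utf-8", newline="") as fh:
            raw = fh.read()
    except UnicodeDecodeError as exc:
        raise FormatError(f"not valid UTF-8: {exc}", path=str(path)) from exc
    for i, line in enumerate(raw.split("\n"), start=1):
        line = line.rstrip("\r")
        if line:
            yield i, line


def read_documents(path: str | Path) -> Corpus:
    """Load a documents TSV into a :class:`Corpus`, preserving input order.

    Raises :class:`FormatError` on a wrong column count, duplicate ``doc_id``
    (naming both offending lines) or non-UTF-8 input.
    """
    corpus = Corpus()
    first_line: dict[str, int] = {}
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(
                f"expected 3 tab-separated fields, got {len(fields)}",
                path=str(path), line=lineno,
            )
        doc_id, title, abstract = fields
        if doc_id in first_line:
            raise FormatError(
                f"duplicate doc_id {doc_id!r} (first seen on line {first_line[doc_id]})",
                path=str(path), line=lineno,
            )
        first_line[doc_id] = lineno
        try:
            corpus.add(Document(doc_id=doc_id, title=title, abstract=abstract))
        except Exception as exc:
            raise FormatError(str(exc), path=str(path), line=lineno) from exc
    return corpus


def write_documents(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for doc in corpus:
            fh.write(f"{doc.doc_id}\t{doc.title}\t{doc.abstract}\n")


def _check_span(doc, section: str, start: int, end: int):
    text = doc.section_text(section)
    if not (0 <= start < end <= len(text)):
        raise ValueError(
            f"span [{start},{end}) outside section {section!r} of "
            f"{doc.doc_id} (length {len(text)})"
        )
    return text[start:end]


def read_gold_annotations(
    path: str | Path,
    corpus: Corpus,
    inventory: Sequence[str] = (),
    task: str = "custom",
    lenient: bool = False,
    report: Optional[ValidationReport] = None,
) -> AnnotationSet:
    """Load and validate a gold TSV against its corpus.

    Every mention is checked for slice fidelity (the stored surface text must
    equal the addressed code-point slice — a mismatch signals an offset
    convention error) and for the no-overlap rule.  Nesting is always an
    error; with ``lenient=True`` a *partial* overlap demotes the later line to
    a warning and the mention is dropped.  ``report``, when given, collects
    warnings.
    """
    inventory = tuple(inventory)
    mentions: list[Mention] = []
    accepted: dict[tuple[str, str], list[tuple[int, Mention]]] = {}
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if len(fields) not in (6, 7):
            raise FormatError(
                f"expected 6 or 7 fields, got {len(fields)}",
                path=str(path), line=lineno,
            )
        doc_id, section, start_s, end_s, text, cls = fields[:6]
        provenance = fields[6] if len(fields) == 7 else "manual"
        if doc_id not in corpus:
            raise FormatError(f"unknown doc_id {doc_id!r}", path=str(path), line=lineno)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(
                f"non-integer offsets {start_s!r}, {end_s!r}",
                path=str(path), line=lineno,
            ) from None
        try:
            slice_text = _check_span(corpus[doc_id], section, start, end)
        except ValueError as exc:
            raise FormatError(str(exc), path=str(path), line=lineno) from exc
        if slice_text != text:
            raise FormatError(
                f"surface text {text!r} does not equal document slice "
                f"{slice_text!r} (offset convention error?)",
                path=str(path), line=lineno,
            )
        if inventory and cls and cls not in inventory:
            raise FormatError(
                f"unknown class {cls!r} for task {task}", path=str(path), line=lineno
            )
        m = Mention(
            doc_id=doc_id, section=section, start=start, end=end,
            text=text, cls=cls or None, provenance=provenance,
        )
        key = (doc_id, section)
        clash = None
        for prev_line, prev in accepted.get(key, ()):
            if m.overlaps(prev):
                clash = (prev_line, prev)
                break
        if clash is not None:
            prev_line, prev = clash
            nested = (prev.start <= m.start and m.end <= prev.end) or (
                m.start <= prev.start and prev.end <= m.end
            )
            msg = (
                f"mention [{start},{end}) {text!r} "
                f"{'nested within' if nested else 'overlaps'} "
                f"[{prev.start},{prev.end}) {prev.text!r} from line {prev_line}"
            )
            if lenient and not nested:
                if report is not None:
                    report.add_warning(lineno, "overlap", msg)
                continue
            raise FormatError(msg, path=str(path), line=lineno)
        accepted.setdefault(key, []).append((lineno, m))
        mentions.append(m)
    return AnnotationSet(task=task, class_inventory=inventory, mentions=mentions)


def export_standoff(aset: AnnotationSet, path: str | Path) -> None:
    """Write the gold TSV dialect with a seventh provenance column.

    Reading the export back reproduces the mention multiset exactly.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in sorted(
            aset.mentions, key=lambda m: (m.doc_id, m.section, m.start, m.end)
        ):
            fh.write(
                f"{m.doc_id}\t{m.section}\t{m.start}\t{m.end}\t{m.text}\t"
                f"{m.cls or ''}\t{m.provenance}\n"
            )


def _parse_prediction_fields(fields: list[str], corpus: Corpus, lineno: int, path: str):
    """Parse one ranked/extended prediction line; raises FormatError."""
    if len(fields) not in (4, 6):
        raise FormatError(
            f"expected 4 (ranked) or 6 (extended) fields, got {len(fields)}",
            path=path, line=lineno,
        )
    doc_id, span, rank_s, conf_s = fields[:4]
    parts = span.rsplit(":", 2)
    if len(parts) != 3 or parts[0] not in ("T", "A"):
        raise FormatError(
            f"malformed span triple {span!r} (expected section:start:end)",
            path=path, line=lineno,
        )
    section = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError:
        raise FormatError(
            f"non-integer offsets in span triple {span!r}", path=path, line=lineno
        ) from None
    try:
        rank = int(rank_s)
        if rank < 1:
            raise ValueError
    except ValueError:
        raise FormatError(
            f"rank must be a positive integer, got {rank_s!r}", path=path, line=lineno
        ) from None
    try:
        confidence = float(conf_s)
    except ValueError:
        raise FormatError(
            f"confidence must be a real number, got {conf_s!r}", path=path, line=lineno
        ) from None
    if not (0.0 <= confidence <= 1.0):
        raise FormatError(
            f"confidence {confidence} outside [0, 1]", path=path, line=lineno
        )
    if doc_id not in corpus:
        raise FormatError(f"unknown doc_id {doc_id!r}", path=path, line=lineno)
    try:
        slice_text = _check_span(corpus[doc_id], section, start, end)
    except ValueError as exc:
        raise FormatError(str(exc), path=path, line=lineno) from exc
    text, cls = (fields[4], fields[5] or None) if len(fields) == 6 else (None, None)
    if text is not None and text != slice_text:
        raise FormatError(
            f"surface text {text!r} does not equal document slice {slice_text!r}",
            path=path, line=lineno,
        )
    return Mention(
        doc_id=doc_id, section=section, start=start, end=end,
        text=slice_text, cls=cls, provenance="predicted",
        confidence=confidence, rank=rank,
    )


def read_prediction_run(
    path: str | Path,
    corpus: Corpus,
    team_id: str,
    run_id: int,
    strict: bool = True,
    report: Optional[ValidationReport] = None,
) -> PredictionRun:
    """Load a prediction TSV (ranked or extended dialect).

    Surface text is filled from the document slice when absent.  Exact span
    duplicates are collapsed, keeping the first occurrence, with a warning.
    Unknown doc_ids raise in strict mode; in lenient mode the line is skipped
    with a warning (silent skipping hides scoring bugs, hence strict default).
    """
    mentions: list[Mention] = []
    seen: dict[tuple, int] = {}
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        try:
            m = _parse_prediction_fields(fields, corpus, lineno, str(path))
        except FormatError as exc:
            if not strict and "unknown doc_id" in str(exc):
                if report is not None:
                    report.add_warning(lineno, "unknown-doc", str(exc))
                continue
            raise
        if m.span_key in seen:
            if report is not None:
                report.add_warning(
                    lineno, "duplicate",
                    f"duplicate span {m.span_key} (first on line {seen[m.span_key]})",
                )
            continue
        seen[m.span_key] = lineno
        mentions.append(m)
    return PredictionRun(team_id=team_id, run_id=run_id, mentions=mentions)


def write_predictions(run: PredictionRun, path: str | Path, extended: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in sorted(run.mentions, key=lambda m: (m.rank or 0, m.doc_id, m.section, m.start)):
            conf = m.confidence if m.confidence is not None else 1.0
            line = f"{m.doc_id}\t{m.section}:{m.start}:{m.end}\t{m.rank or 1}\t{conf:g}"
            if extended:
                line += f"\t{m.text}\t{m.cls or ''}"
            fh.write(line + "\n")


def validate_submission(
    paths: Sequence[str | Path], corpus: Corpus
) -> ValidationReport:
    """Structurally validate 1–5 run files as one submission.

    Content problems are collected into the report, never raised; an
    unreadable file produces an error entry and validation continues.  More
    than five run files violates the per-task run cap.
    """
    out = ValidationReport()
    if len(paths) > MAX_RUNS_PER_TEAM:
        out.add_error(
            0, "run-limit",
            f"run limit exceeded: {len(paths)} files, maximum {MAX_RUNS_PER_TEAM} runs per task",
        )
    if not paths:
        out.add_error(0, "no-runs", "submission contains no run files")
    for path in paths:
        seen: dict[tuple, int] = {}
        try:
            lines = list(_iter_lines(path))
        except (OSError, FormatError) as exc:
            out.add_error(0, "unreadable", f"{path}: {exc}")
            continue
        for lineno, line in lines:
            try:
                m = _parse_prediction_fields(line.split("\t"), corpus, lineno, str(path))
            except FormatError as exc:
                out.add_error(lineno, "format", str(exc))
                continue
            if m.span_key in seen:
                out.add_warning(
                    lineno, "duplicate",
                    f"{path}:{lineno}: duplicate span {m.span_key} "
                    f"(first on line {seen[m.span_key]})",
                )
            else:
                seen[m.span_key] = lineno
    return out


# ---------------------------------------------------------------------------
# inline-HTML export


def _render_section(text: str, mentions: list[Mention]) -> str:
    mentions = sorted(mentions, key=lambda m: m.start)
    for a, b in zip(mentions, mentions[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping mentions cannot be serialised inline: "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )
    parts: list[str] = []
    pos = 0
    for m in mentions:
        parts.append(html.escape(text[pos:m.start]))
        tokens = ["mention"]
        if m.cls:
            tokens.append(m.cls)
        if m.provenance == "automatic":
            tokens.append("auto")  # visual cue distinguishing recommendations
        parts.append(
            f'<span class="{html.escape(" ".join(tokens))}"'
            f' data-provenance="{m.provenance}"'
            f' data-start="{m.start}" data-end="{m.end}">'
            f"{html.escape(m.text)}</span>"
        )
        pos = m.end
    parts.append(html.escape(text[pos:]))
    return "".join(parts)


def export_inline_html(corpus: Corpus, aset: AnnotationSet, outdir: str | Path) -> list[Path]:
    """Write one UTF-8 HTML file per document with mentions marked up inline.

    Annotation classes become HTML class tokens; provenance and offsets are
    carried in data attributes; automatic recommendations get an extra
    ``auto`` class token so they render distinguishably.  Stripping all tags
    and decoding entities recovers the section text exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_doc = aset.by_doc()
    written = []
    for doc in corpus:
        ms = by_doc.get(doc.doc_id, [])
        body = []
        for section in ("T", "A"):
            sec_ms = [m for m in ms if m.section == section]
            rendered = _render_section(doc.section_text(section), sec_ms)
            body.append(f'<div class="section" data-section="{section}">{rendered}</div>')
        doc_html = (
            "<!DOCTYPE html>\n"
            '<html><head><meta charset="utf-8"/>'
            f"<title>{html.escape(doc.doc_id)}</title></head>\n"
            "<body>\n" + "\n".join(body) + "\n</body></html>\n"
        )
        fname = outdir / (doc.doc_id.replace(os.sep, "_") + ".html")
        fname.write_text(doc_html, encoding="utf-8")
        written.append(fname)
    return written
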