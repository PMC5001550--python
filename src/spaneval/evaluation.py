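"""Exact-span matching and the prediction-analysis report.

A predicted mention is a true positive only when document, section, start and
end all equal a gold mention (and the class too, under class-strict matching).
Partial hits — predictions that overlap a gold span without matching it
exactly — receive no credit: they count as one false positive *and* leave the
gold mention a false negative.

Micro-averaged scores pool TP/FP/FN counts globally; macro-averaged scores
compute precision/recall/F per document and take the arithmetic mean over the
documents in scope (those with at least one gold annotation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ScopeError
from .types import AnnotationSet, Mention, PredictionRun


@dataclass(frozen=True)
class Scores:
    """Precision, recall and F-score (harmonic mean of the two).

    Zero-denominator conventions: precision is 1 when nothing was predicted
    and nothing was there to find (TP+FP=0 and FN=0), else 0 when TP+FP=0;
    recall symmetrically; F is 0 when precision+recall is 0.
    """

    precision: float
    recall: float
    fscore: float
    flavor: str = "micro"
    n_documents: Optional[int] = None


@dataclass
class MatchResult:
    """The TP/FP/FN partition of a gold set against one prediction run."""

    tp: list[tuple[Mention, Mention]] = field(default_factory=list)
    fp: list[Mention] = field(default_factory=list)
    fn: list[Mention] = field(default_factory=list)
    per_doc: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.tp), len(self.fp), len(self.fn))


def match_run(
    gold: AnnotationSet, run: PredictionRun, class_strict: bool = False
) -> MatchResult:
    """Partition gold and predicted mentions into TP pairs, FPs and FNs.

    Each gold mention matches at most one prediction and vice versa.  With
    ``class_strict`` a span-identical prediction of the wrong class is a
    false positive and the gold mention stays a false negative.
    """
    def key(m: Mention):
        return m.span_key + ((m.cls,) if class_strict else ())

    gold_index: dict[tuple, Mention] = {key(g): g for g in gold.mentions}
    matched: set[tuple] = set()
    result = MatchResult()
    preds = sorted(
        run.mentions,
        key=lambda m: (m.rank if m.rank is not None else 1_000_000,
                       -(m.confidence if m.confidence is not None else 0.0),
                       m.doc_id, m.section, m.start, m.end),
    )
    for p in preds:
        k = key(p)
        if k in gold_index and k not in matched:
            matched.add(k)
            result.tp.append((gold_index[k], p))
        else:
            result.fp.append(p)
    for g in gold.mentions:
        if key(g) not in matched:
            result.fn.append(g)

    per_doc: dict[str, list[int]] = {}
    for g, _ in result.tp:
        per_doc.setdefault(g.doc_id, [0, 0, 0])[0] += 1
    for p in result.fp:
        per_doc.setdefault(p.doc_id, [0, 0, 0])[1] += 1
    for g in result.fn:
        per_doc.setdefault(g.doc_id, [0, 0, 0])[2] += 1
    result.per_doc = {d: tuple(v) for d, v in sorted(per_doc.items())}
    return result


def scores_from_counts(tp: int, fp: int, fn: int, flavor: str = "micro") -> Scores:
    if tp + fp == 0:
        precision = 1.0 if fn == 0 else 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 1.0 if fp == 0 else 0.0
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        fscore = 0.0
    else:
        fscore = 2 * precision * recall / (precision + recall)
    return Scores(precision=precision, recall=recall, fscore=fscore, flavor=flavor)


def micro_scores(m: MatchResult) -> Scores:
    """Precision/recall/F from globally pooled TP, FP and FN counts."""
    return scores_from_counts(*m.counts, flavor="micro")


def macro_scores(
    gold: AnnotationSet, run: PredictionRun, class_strict: bool = False
) -> Scores:
    """Arithmetic mean of per-document precision/recall/F.

    Scope is the set of documents carrying at least one gold annotation;
    predictions falling in out-of-scope documents are ignored here (they
    still count as micro false positives).  Raises :class:`ScopeError` when
    no document is in scope.
    """
    m = match_run(gold, run, class_strict=class_strict)
    in_scope = {g.doc_id for g in gold.mentions}
    if not in_scope:
        raise ScopeError("macro undefined on empty scope (no annotated documents)")
    ps, rs, fs = [], [], []
    for doc_id in sorted(in_scope):
        tp, fp, fn = m.per_doc.get(doc_id, (0, 0, 0))
        s = scores_from_counts(tp, fp, fn)
        ps.append(s.precision)
        rs.append(s.recall)
        fs.append(s.fscore)
    n = len(in_scope)
    return Scores(
        precision=sum(ps) / n, recall=sum(rs) / n, fscore=sum(fs) / n,
        flavor="macro", n_documents=n,
    )


def class_distribution(
    m: MatchResult, gold: AnnotationSet
) -> dict[str, tuple[int, int]]:
    """Per-class (TP, FN) counts; each gold mention contributes exactly once.

    Rows appear in inventory order when the set declares an inventory,
    followed by any remaining labels alphabetically.
    """
    tally: dict[str, list[int]] = {}

    def label(g: Mention) -> str:
        return g.cls if g.cls is not None else "(none)"

    for g, _ in m.tp:
        tally.setdefault(label(g), [0, 0])[0] += 1
    for g in m.fn:
        tally.setdefault(label(g), [0, 0])[1] += 1
    order = [c for c in gold.class_inventory if c in tally]
    order += sorted(set(tally) - set(order))
    return {c: tuple(tally[c]) for c in order}


def _group_terms(mentions: Iterable[Mention]) -> list[tuple[str, int]]:
    """Case-fold-grouped term counts with a deterministic display form.

    Ranked by count descending, ties broken lexicographically on the folded
    form; the display form is the most frequent original casing, first-seen
    winning ties.
    """
    counts: Counter[str] = Counter()
    casings: dict[str, Counter[str]] = {}
    first_seen: dict[str, dict[str, int]] = {}
    for i, m in enumerate(mentions):
        folded = m.text.casefold()
        counts[folded] += 1
        casings.setdefault(folded, Counter())[m.text] += 1
        first_seen.setdefault(folded, {}).setdefault(m.text, i)
    out = []
    for folded in sorted(counts, key=lambda t: (-counts[t], t)):
        display = min(
            casings[folded],
            key=lambda c: (-casings[folded][c], first_seen[folded][c]),
        )
        out.append((display, counts[folded]))
    return out


def top_terms(m: MatchResult, direction: str, k: int) -> list[tuple[str, int]]:
    """The k most frequent missed (``fn``) or spurious (``fp``) surface terms."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction == "fn":
        mentions: Iterable[Mention] = m.fn
    elif direction == "fp":
        mentions = m.fp
    else:
        raise ValueError(f"direction must be 'fn' or 'fp', got {direction!r}")
    return _group_terms(mentions)[:k]


def top_documents(m: MatchResult, direction: str, k: int) -> list[tuple[str, int]]:
    """The k documents with the most FN or FP mismatches (zero counts hidden)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = {"fn": 2, "fp": 1}.get(direction)
    if idx is None:
        raise ValueError(f"direction must be 'fn' or 'fp', got {direction!r}")
    ranked = sorted(
        ((d, c[idx]) for d, c in m.per_doc.items() if c[idx] > 0),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]


def cross_run_report(
    gold: AnnotationSet, runs: list[PredictionRun], k: int = 10
) -> dict[str, list[tuple[str, float]]]:
    """Mismatches common across several runs: average FN/FP per run.

    For each document and each (case-folded) term, the total mismatch count
    across all runs is divided by the number of runs.  Ranking uses the
    unrounded average; rounding, if any, is a display concern.  Returns four
    ranked lists: ``top_fn_documents``, ``top_fp_documents``,
    ``top_fn_terms``, ``top_fp_terms``.
    """
    if not runs:
        raise ScopeError("cross_run_report requires at least one run")
    n = len(runs)
    doc_fn: Counter[str] = Counter()
    doc_fp: Counter[str] = Counter()
    fn_mentions: list[Mention] = []
    fp_mentions: list[Mention] = []
    for run in runs:
        m = match_run(gold, run)
        for d, (_, fp_c, fn_c) in m.per_doc.items():
            doc_fn[d] += fn_c
            doc_fp[d] += fp_c
        fn_mentions.extend(m.fn)
        fp_mentions.extend(m.fp)

    def rank_docs(counter: Counter[str]) -> list[tuple[str, float]]:
        ranked = sorted(
            ((d, c / n) for d, c in counter.items() if c > 0),
            key=lambda t: (-t[1], t[0]),
        )
        return ranked[:k]

    def rank_terms(mentions: list[Mention]) -> list[tuple[str, float]]:
        return [(t, c / n) for t, c in _group_terms(mentions)[:k]]

    return {
        "top_fn_documents": rank_docs(doc_fn),
        "top_fp_documents": rank_docs(doc_fp),
        "top_fn_terms": rank_terms(fn_mentions),
        "top_fp_terms": rank_terms(fp_mentions),
    }


@dataclass
class ErrorReport:
    """The full prediction-analysis report for one run."""

    scores_micro: Scores
    scores_macro: Scores
    class_distribution: dict[str, tuple[int, int]]
    top_fn_terms: list[tuple[str, int]]
    top_fp_terms: list[tuple[str, int]]
    top_fn_documents: list[tuple[str, int]]
    top_fp_documents: list[tuple[str, int]]
    per_doc: dict[str, tuple[int, int, int]]

    def to_dict(self) -> dict:
        def scores(s: Scores) -> dict:
            d = {"precision": s.precision, "recall": s.recall, "fscore": s.fscore,
                 "flavor": s.flavor}
            if s.n_documents is not None:
                d["n_documents"] = s.n_documents
            return d

        return {
            "scores_micro": scores(self.scores_micro),
            "scores_macro": scores(self.scores_macro),
            "class_distribution": {
                c: {"tp": tp, "fn": fn} for c, (tp, fn) in self.class_distribution.items()
            },
            "top_fn_terms": [[t, c] for t, c in self.top_fn_terms],
            "top_fp_terms": [[t, c] for t, c in self.top_fp_terms],
            "top_fn_documents": [[d, c] for d, c in self.top_fn_documents],
            "top_fp_documents": [[d, c] for d, c in self.top_fp_documents],
            "per_document": {
                d: {"tp": tp, "fp": fp, "fn": fn}
                for d, (tp, fp, fn) in self.per_doc.items()
            },
        }

    def render_text(self) -> str:
        lines = []
        for s in (self.scores_micro, self.scores_macro):
            extra = f" over {s.n_documents} documents" if s.n_documents else ""
            lines.append(
                f"{s.flavor:>5}: P={s.precision:.4f} R={s.recall:.4f} "
                f"F={s.fscore:.4f}{extra}"
            )
        lines.append("")
        lines.append("TP/FN by annotation class:")
        for c, (tp, fn) in self.class_distribution.items():
            lines.append(f"  {c:<16} TP={tp:<6} FN={fn}")
        for title, rows in (
            ("Top false negatives (terms)", self.top_fn_terms),
            ("Top false positives (terms)", self.top_fp_terms),
            ("Top false negatives (documents)", self.top_fn_documents),
            ("Top false positives (documents)", self.top_fp_documents),
        ):
            lines.append("")
            lines.append(title + ":")
            for name, count in rows:
                lines.append(f"  {name:<24} {count}")
        return "\n".join(lines) + "\n"


def error_report(
    gold: AnnotationSet,
    run: PredictionRun,
    class_strict: bool = False,
    k: int = 10,
) -> ErrorReport:
    """Compute the complete analysis report: scores, class table, mismatch lists."""
    m = match_run(gold, run, class_strict=class_strict)
    return ErrorReport(
        scores_micro=micro_scores(m),
        scores_macro=macro_scores(gold, run, class_strict=class_strict),
        class_distribution=class_distribution(m, gold),
        top_fn_terms=top_terms(m, "fn", k) if m.fn else [],
        top_fp_terms=top_terms(m, "fp", k) if m.fp else [],
        top_fn_documents=top_documents(m, "fn", k),
        top_fp_documents=top_documents(m, "fp", k),
        per_doc=m.per_doc,
    )
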