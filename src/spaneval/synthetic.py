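"""Deterministic synthetic corpora, gold standards and degraded predictions.

Every other module is testable without downloading anything: documents are
assembled from filler tokens with entity surface forms embedded at recorded
offsets, and prediction runs are derived from the gold standard by applying
known error rates — a drop probability (false negatives), a boundary-shift
probability (partial hits, which exact-span scoring counts as one FP plus one
FN) and a Poisson rate of spurious spans per document (false positives).
Closed-form expected counts make the generator self-checking.

The filler vocabulary deliberately mixes ASCII with multi-byte code points
(Greek letters, µ) so that any confusion between byte and code-point offsets
surfaces immediately.  No attempt is made to mimic real patent language,
chemical-name morphology or realistic class priors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InvariantError
from .evaluation import scores_from_counts
from .io import export_standoff, write_documents, write_predictions
from .types import AnnotationSet, Corpus, Document, Mention, PredictionRun

DEFAULT_VOCAB: dict[str, list[str]] = {
    "SYSTEMATIC": ["2-acetoxybenzoic acid", "N-methylpyridinium", "1,2-diol"],
    "TRIVIAL": ["aspirin", "caffeine", "Docetaxel", "ibuprofen"],
    "FAMILY": ["alkyl", "ester", "opioid", "aromatic amine"],
    "FORMULA": ["C9H8O4", "NaCl", "H2SO4"],
    "ABBREVIATIONS": ["ASA", "DMSO", "EtOH"],
    "IDENTIFIERS": ["CHEBI:15365", "CAS-50-78-2"],
    "MULTIPLE": ["sodium and potassium salts"],
    "NO CLASS": ["active agent"],
}

DEFAULT_FILLER: list[str] = [
    "the", "compound", "was", "tested", "in", "vitro", "with", "good",
    "yield", "and", "purity", "under", "reflux", "conditions", "for",
    "two", "hours", "giving", "a", "white", "solid", "product", "that",
    "showed", "activity", "against", "several", "targets", "at", "low",
    "doses", "per", "kilogram", "body", "weight",
    # Unicode salt: multi-byte code points ahead of mention offsets
    "µM", "α-substituted", "β-lactam", "Δ9", "50 µg",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic corpus."""

    n_docs: int = 50
    vocab: dict = field(default_factory=lambda: dict(DEFAULT_VOCAB))
    filler_words: list = field(default_factory=lambda: list(DEFAULT_FILLER))
    mentions_per_doc: tuple[int, int] = (2, 6)
    title_mention_prob: float = 0.2
    abstract_tokens: tuple[int, int] = (25, 45)
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 1:
            raise InvariantError("n_docs must be >= 1")
        if not self.vocab or not any(self.vocab.values()):
            raise InvariantError("vocab must contain at least one surface form")
        lo, hi = self.mentions_per_doc
        if not (0 <= lo <= hi):
            raise InvariantError("mentions_per_doc range invalid")
        for cls, forms in self.vocab.items():
            for form in forms:
                if not form or "\t" in form or "\n" in form:
                    raise InvariantError(
                        f"vocab form {form!r} (class {cls}) contains tab/newline or is empty"
                    )


@dataclass(frozen=True)
class DegradeSpec:
    """Known error rates for deriving a prediction run from the gold standard.

    ``fn_rate``: probability a gold mention is dropped.  ``fp_rate``: expected
    spurious predictions per document (Poisson).  ``shift_rate``: probability
    a kept mention's boundary is perturbed by one code point, producing a
    partial hit that is guaranteed not to equal any gold span.
    """

    fn_rate: float = 0.0
    fp_rate: float = 0.0
    shift_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.fn_rate <= 1.0):
            raise InvariantError("fn_rate must be in [0, 1]")
        if not (0.0 <= self.shift_rate <= 1.0):
            raise InvariantError("shift_rate must be in [0, 1]")
        if self.fp_rate < 0.0:
            raise InvariantError("fp_rate must be >= 0")


def _build_section(
    rng: np.random.Generator,
    filler: list[str],
    n_tokens: int,
    mention_forms: list[tuple[str, str]],  # (form, class)
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Assemble space-joined tokens with mention forms at random slots.

    Returns the text and (start, end, text, class) for each embedded mention.
    """
    tokens = [filler[rng.integers(0, len(filler))] for _ in range(n_tokens)]
    slots = sorted(
        int(s) for s in rng.choice(n_tokens + 1, size=len(mention_forms), replace=False)
    )
    mention_at: dict[int, tuple[str, str]] = {}
    for slot, fc in zip(slots, mention_forms):
        mention_at[slot] = fc
    out_tokens: list[str] = []
    spans: list[tuple[int, int, str, str]] = []
    pos = 0
    for i in range(n_tokens + 1):
        if i in mention_at:
            form, cls = mention_at[i]
            if out_tokens:
                pos += 1  # joining space
            spans.append((pos, pos + len(form), form, cls))
            out_tokens.append(form)
            pos += len(form)
        if i < n_tokens:
            if out_tokens:
                pos += 1
            out_tokens.append(tokens[i])
            pos += len(tokens[i])
    return " ".join(out_tokens), spans


def generate_corpus(spec: SynthSpec) -> tuple[Corpus, AnnotationSet]:
    """Generate a corpus and its gold standard; identical seeds give
    bit-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.vocab)
    corpus = Corpus()
    mentions: list[Mention] = []
    lo, hi = spec.mentions_per_doc
    for d in range(spec.n_docs):
        doc_id = f"SYN{d:05d}"
        k = int(rng.integers(lo, hi + 1))
        picks: list[tuple[str, str]] = []
        for _ in range(k):
            cls = classes[rng.integers(0, len(classes))]
            forms = spec.vocab[cls]
            picks.append((forms[rng.integers(0, len(forms))], cls))
        in_title = [
            bool(rng.random() < spec.title_mention_prob) for _ in range(k)
        ]
        title_picks = [p for p, t in zip(picks, in_title) if t]
        abstract_picks = [p for p, t in zip(picks, in_title) if not t]
        n_title_tokens = max(3, len(title_picks))
        t_lo, t_hi = spec.abstract_tokens
        n_abs_tokens = int(rng.integers(t_lo, t_hi + 1))
        n_abs_tokens = max(n_abs_tokens, len(abstract_picks))
        title, t_spans = _build_section(
            rng, spec.filler_words, n_title_tokens, title_picks
        )
        abstract, a_spans = _build_section(
            rng, spec.filler_words, n_abs_tokens, abstract_picks
        )
        corpus.add(Document(doc_id=doc_id, title=title, abstract=abstract))
        for section, spans in (("T", t_spans), ("A", a_spans)):
            for start, end, text, cls in spans:
                mentions.append(
                    Mention(
                        doc_id=doc_id, section=section, start=start, end=end,
                        text=text, cls=cls, provenance="manual",
                    )
                )
    classes_inventory = tuple(sorted(spec.vocab))
    return corpus, AnnotationSet(
        task="custom", class_inventory=classes_inventory, mentions=mentions
    )


def _shift_span(
    rng: np.random.Generator,
    m: Mention,
    section_len: int,
    forbidden: set[tuple[str, str, int, int]],
) -> Optional[tuple[int, int]]:
    """A ±1 boundary perturbation that stays in bounds and avoids every
    forbidden span; widens to ±2, ±3 if needed; None if impossible."""
    for delta in (1, 2, 3):
        options = [
            (m.start - delta, m.end), (m.start + delta, m.end),
            (m.start, m.end - delta), (m.start, m.end + delta),
        ]
        options = [
            (s, e) for s, e in options
            if 0 <= s < e <= section_len
            and (m.doc_id, m.section, s, e) not in forbidden
        ]
        if options:
            return options[int(rng.integers(0, len(options)))]
    return None


def degrade_to_predictions(
    gold: AnnotationSet,
    corpus: Corpus,
    spec: DegradeSpec,
    team_id: str = "synthetic",
    run_id: int = 1,
) -> PredictionRun:
    """Derive a prediction run from the gold standard with known error rates."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gold_spans = {m.span_key for m in gold.mentions}
    taken: set[tuple[str, str, int, int]] = set()
    predicted: list[Mention] = []

    ordered = sorted(gold.mentions, key=lambda m: (m.doc_id, m.section, m.start, m.end))
    for m in ordered:
        if rng.random() < spec.fn_rate:
            continue
        start, end = m.start, m.end
        if rng.random() < spec.shift_rate:
            section_len = len(corpus.section_text(m.doc_id, m.section))
            shifted = _shift_span(rng, m, section_len, gold_spans | taken)
            if shifted is None:
                continue  # pathological: no legal perturbation; mention stays missed
            start, end = shifted
        key = (m.doc_id, m.section, start, end)
        if key in taken:
            continue
        taken.add(key)
        text = corpus.section_text(m.doc_id, m.section)[start:end]
        predicted.append(
            Mention(
                doc_id=m.doc_id, section=m.section, start=start, end=end,
                text=text, cls=m.cls, provenance="predicted",
                confidence=round(float(rng.uniform(0.5, 1.0)), 6),
            )
        )

    if spec.fp_rate > 0:
        for doc in corpus:
            n_spurious = int(rng.poisson(spec.fp_rate))
            text = doc.abstract if doc.abstract else doc.title
            section = "A" if doc.abstract else "T"
            for _ in range(n_spurious):
                for _attempt in range(20):
                    length = int(rng.integers(3, 9))
                    if length >= len(text):
                        length = max(1, len(text) - 1)
                    start = int(rng.integers(0, len(text) - length + 1))
                    key = (doc.doc_id, section, start, start + length)
                    if key not in gold_spans and key not in taken:
                        taken.add(key)
                        predicted.append(
                            Mention(
                                doc_id=doc.doc_id, section=section,
                                start=start, end=start + length,
                                text=text[start:start + length],
                                provenance="predicted",
                                confidence=round(float(rng.uniform(0.0, 0.5)), 6) or 0.01,
                            )
                        )
                        break

    # per-document ranks by descending confidence
    by_doc: dict[str, list[Mention]] = {}
    for m in predicted:
        by_doc.setdefault(m.doc_id, []).append(m)
    ranked: list[Mention] = []
    for doc_id in sorted(by_doc):
        ms = sorted(
            by_doc[doc_id],
            key=lambda m: (-(m.confidence or 0.0), m.section, m.start, m.end),
        )
        for r, m in enumerate(ms, start=1):
            ranked.append(m.replace(rank=r))
    return PredictionRun(team_id=team_id, run_id=run_id, mentions=ranked)


@dataclass(frozen=True)
class ExpectedCounts:
    tp: float
    fp: float
    fn: float
    precision: float
    recall: float


def expected_counts(
    gold_size: int, spec: DegradeSpec, n_docs: int
) -> ExpectedCounts:
    """Closed-form expectations for the degradation model.

    TP = G(1-fn)(1-shift); a shifted survivor contributes one FP and leaves
    its gold mention as an FN; spurious spans add n_docs*fp_rate FPs.
    """
    tp = gold_size * (1.0 - spec.fn_rate) * (1.0 - spec.shift_rate)
    fn = gold_size - tp
    fp = gold_size * (1.0 - spec.fn_rate) * spec.shift_rate + n_docs * spec.fp_rate
    s = scores_from_counts(tp, fp, fn)
    return ExpectedCounts(tp=tp, fp=fp, fn=fn, precision=s.precision, recall=s.recall)


def write_fixture_set(
    outdir: str | Path,
    spec: SynthSpec,
    degrade_specs: Optional[dict[str, DegradeSpec]] = None,
) -> dict:
    """Write documents/gold/prediction TSVs plus a manifest recording the specs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus, gold = generate_corpus(spec)
    write_documents(corpus, outdir / "documents.tsv")
    export_standoff(gold, outdir / "gold.tsv")
    manifest: dict = {
        "corpus": {
            "n_docs": spec.n_docs,
            "mentions_per_doc": list(spec.mentions_per_doc),
            "seed": spec.seed,
            "n_gold_mentions": len(gold),
        },
        "runs": {},
    }
    for name, dspec in (degrade_specs or {}).items():
        run = degrade_to_predictions(gold, corpus, dspec, team_id=name)
        write_predictions(run, outdir / f"pred_{name}.tsv")
        manifest["runs"][name] = {
            "fn_rate": dspec.fn_rate, "fp_rate": dspec.fp_rate,
            "shift_rate": dspec.shift_rate, "seed": dspec.seed,
            "n_predictions": len(run),
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
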