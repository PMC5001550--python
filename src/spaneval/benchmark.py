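"""Run ranking, bootstrap F-score variability and significance grouping.

Variability of a team's micro-averaged F-score is estimated by a document-level
bootstrap: the sampling frame is every document that carries at least one gold
annotation; each bootstrap sample draws that many documents *with replacement*
(a document drawn twice contributes its TP/FP/FN counts twice) and the pooled
micro F is computed on the sample.  One shared RNG stream generates the draws,
so every team is scored on identical document multisets — differences between
teams are then differences between systems, not between samples.  The default
of 2500 samples and the two-standard-deviation grouping follow common shared-
task practice.

Grouping uses an adjacent-chain rule: consecutive ranked teams fall in the
same group when their F difference is within ``k_sd`` times the larger of
their two bootstrap SDs; groups are maximal such chains.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError, ScopeError
from .evaluation import Scores, match_run, micro_scores
from .types import AnnotationSet, PredictionRun

DEFAULT_N_SAMPLES = 2500


@dataclass
class BootstrapResult:
    team_id: str
    run_id: int
    observed_f: float
    samples: np.ndarray
    sd: float
    rank: Optional[int] = None
    group: Optional[int] = None


def best_run_per_team(
    gold: AnnotationSet, runs: Sequence[PredictionRun]
) -> dict[str, PredictionRun]:
    """Select each team's top-scoring run by micro F; ties go to the lower run_id."""
    if not runs:
        raise ScopeError("no runs supplied")
    best: dict[str, tuple[float, int, PredictionRun]] = {}
    for run in runs:
        f = micro_scores(match_run(gold, run)).fscore
        cur = best.get(run.team_id)
        if cur is None or f > cur[0] or (f == cur[0] and run.run_id < cur[1]):
            best[run.team_id] = (f, run.run_id, run)
    return {team: run for team, (_, _, run) in sorted(best.items())}


def _per_doc_count_arrays(
    gold: AnnotationSet, run: PredictionRun, frame: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = match_run(gold, run)
    pos = {d: i for i, d in enumerate(frame)}
    tp = np.zeros(len(frame), dtype=np.int64)
    fp = np.zeros(len(frame), dtype=np.int64)
    fn = np.zeros(len(frame), dtype=np.int64)
    for d, (tp_c, fp_c, fn_c) in m.per_doc.items():
        if d in pos:  # predictions in unannotated documents fall outside the frame
            tp[pos[d]], fp[pos[d]], fn[pos[d]] = tp_c, fp_c, fn_c
    return tp, fp, fn


def _sample_fscores(
    tp: np.ndarray, fp: np.ndarray, fn: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Pooled micro F for each row of draw indices ``idx`` (n_samples × n_docs)."""
    tp_s = tp[idx].sum(axis=1).astype(float)
    fp_s = fp[idx].sum(axis=1).astype(float)
    fn_s = fn[idx].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp_s + fp_s > 0, tp_s / np.maximum(tp_s + fp_s, 1), 0.0)
        p = np.where((tp_s + fp_s == 0) & (fn_s == 0), 1.0, p)
        r = np.where(tp_s + fn_s > 0, tp_s / np.maximum(tp_s + fn_s, 1), 0.0)
        r = np.where((tp_s + fn_s == 0) & (fp_s == 0), 1.0, r)
        f = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-300), 0.0)
    return f


def annotated_documents(gold: AnnotationSet) -> list[str]:
    """The bootstrap sampling frame: sorted ids of documents with >=1 annotation."""
    return sorted({m.doc_id for m in gold.mentions})


def bootstrap_fscores(
    gold: AnnotationSet,
    runs: dict[str, PredictionRun],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    k_sd: float = 2.0,
) -> list[BootstrapResult]:
    """Bootstrap each team's micro F over annotated documents; rank and group.

    Returns results ordered by observed F descending (rank 1 first), each
    carrying the full sample vector, its sample standard deviation (n-1
    denominator) and a significance group label.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    frame = annotated_documents(gold)
    if not frame:
        raise ScopeError("bootstrap requires at least one annotated document")
    rng = np.random.default_rng(seed)
    n = len(frame)
    idx = rng.integers(0, n, size=(n_samples, n))

    results = []
    for team in sorted(runs):
        run = runs[team]
        tp, fp, fn = _per_doc_count_arrays(gold, run, frame)
        samples = _sample_fscores(tp, fp, fn, idx)
        observed = micro_scores(match_run(gold, run)).fscore
        # a constant sample vector has sd exactly 0; don't let the mean's
        # last-bit rounding manufacture a spurious 1e-16
        sd = 0.0 if samples.max() == samples.min() else float(samples.std(ddof=1))
        results.append(
            BootstrapResult(
                team_id=team,
                run_id=run.run_id,
                observed_f=observed,
                samples=samples,
                sd=sd,
            )
        )
    results.sort(key=lambda r: (-r.observed_f, r.team_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return group_by_significance(results, k_sd=k_sd)


def group_by_significance(
    results: list[BootstrapResult], k_sd: float = 2.0
) -> list[BootstrapResult]:
    """Assign group labels along the ranking by the adjacent-chain rule.

    Consecutive teams i, i+1 share a group iff
    ``|F_i - F_{i+1}| <= k_sd * max(sd_i, sd_{i+1})``; group numbers start at
    1 and are non-decreasing down the ranking.  ``k_sd=0`` separates every
    distinct F; ``k_sd=inf`` yields a single group.
    """
    if any(
        a.observed_f < b.observed_f for a, b in zip(results, results[1:])
    ):
        raise ScopeError("results must be ranked by observed F descending")
    group = 1
    for i, r in enumerate(results):
        if i > 0:
            prev = results[i - 1]
            gap = abs(prev.observed_f - r.observed_f)
            # 1e-12 guards the <= against float subtraction noise
            if not (math.isinf(k_sd) or gap <= k_sd * max(prev.sd, r.sd) + 1e-12):
                group += 1
        r.group = group
    return results


# ---------------------------------------------------------------------------
# leaderboards and post-challenge placement


@dataclass(frozen=True)
class LeaderboardEntry:
    team_id: str
    precision: float
    recall: float
    fscore: float
    sd: float


@dataclass
class Leaderboard:
    """Published best-run-per-team scores, sorted by F descending."""

    entries: list[LeaderboardEntry] = field(default_factory=list)
    task: str = "custom"
    corpus_fingerprint: str = ""
    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = 0

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries, key=lambda e: (-e.fscore, e.team_id)
        )


def corpus_fingerprint(gold: AnnotationSet) -> str:
    """Stable hash of the gold annotation content, used to refuse comparing
    scores computed against different gold standards."""
    h = hashlib.sha256()
    for m in sorted(gold.mentions, key=lambda m: (m.doc_id, m.section, m.start, m.end)):
        h.update(
            f"{m.doc_id}\t{m.section}\t{m.start}\t{m.end}\t{m.text}\t{m.cls or ''}\n".encode()
        )
    return h.hexdigest()[:16]


def build_leaderboard(
    gold: AnnotationSet,
    runs: Sequence[PredictionRun],
    task: str = "custom",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> tuple[Leaderboard, list[BootstrapResult]]:
    """Best run per team -> bootstrap -> published leaderboard."""
    best = best_run_per_team(gold, runs)
    boots = bootstrap_fscores(gold, best, n_samples=n_samples, seed=seed)
    entries = []
    for b in boots:
        s = micro_scores(match_run(gold, best[b.team_id]))
        entries.append(
            LeaderboardEntry(
                team_id=b.team_id, precision=s.precision, recall=s.recall,
                fscore=s.fscore, sd=b.sd,
            )
        )
    board = Leaderboard(
        entries=entries, task=task, corpus_fingerprint=corpus_fingerprint(gold),
        n_samples=n_samples, seed=seed,
    )
    return board, boots


def write_leaderboard(board: Leaderboard, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# task={board.task} corpus={board.corpus_fingerprint} "
            f"n_samples={board.n_samples} seed={board.seed}\n"
        )
        for e in board.entries:
            fh.write(
                f"{e.team_id}\t{e.precision:.6f}\t{e.recall:.6f}\t"
                f"{e.fscore:.6f}\t{e.sd:.6f}\n"
            )


def read_leaderboard(path: str | Path) -> Leaderboard:
    entries = []
    meta = {"task": "custom", "corpus": "", "n_samples": DEFAULT_N_SAMPLES, "seed": 0}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k in meta:
                            meta[k] = type(meta[k])(v)
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"expected 5 fields, got {len(fields)}", path=str(path), line=lineno
                )
            entries.append(
                LeaderboardEntry(
                    team_id=fields[0],
                    precision=float(fields[1]),
                    recall=float(fields[2]),
                    fscore=float(fields[3]),
                    sd=float(fields[4]),
                )
            )
    return Leaderboard(
        entries=entries, task=meta["task"], corpus_fingerprint=meta["corpus"],
        n_samples=meta["n_samples"], seed=meta["seed"],
    )


@dataclass
class Placement:
    """A new system's position among stored challenge results."""

    scores: Scores
    sd: float
    rank: int
    board: Leaderboard
    neighbor_context: dict[str, Optional[dict]]


def place_new_run(
    board: Leaderboard,
    gold: AnnotationSet,
    run: PredictionRun,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    k_sd: float = 2.0,
) -> Placement:
    """Score a new run and insert it into a stored leaderboard.

    Stored entries are taken at face value (the original submissions are not
    recomputed); the new run's micro P/R/F and bootstrap SD are computed
    against the gold standard, which must fingerprint-match the board.  On an
    exact F tie the new run is placed immediately after the stored entry.
    """
    fp = corpus_fingerprint(gold)
    if board.corpus_fingerprint and board.corpus_fingerprint != fp:
        raise ScopeError(
            f"corpus fingerprint mismatch: board={board.corpus_fingerprint} "
            f"gold={fp}; scores are not comparable"
        )
    scores = micro_scores(match_run(gold, run))
    boots = bootstrap_fscores(
        gold, {run.team_id: run}, n_samples=n_samples, seed=seed
    )
    sd = boots[0].sd
    new_entry = LeaderboardEntry(
        team_id=run.team_id, precision=scores.precision, recall=scores.recall,
        fscore=scores.fscore, sd=sd,
    )
    pos = sum(1 for e in board.entries if e.fscore >= new_entry.fscore)
    entries = list(board.entries)
    entries.insert(pos, new_entry)
    new_board = Leaderboard(
        entries=[], task=board.task, corpus_fingerprint=board.corpus_fingerprint or fp,
        n_samples=n_samples, seed=seed,
    )
    new_board.entries = entries  # preserve stable insertion order on ties

    def relation(other: Optional[LeaderboardEntry]) -> Optional[dict]:
        if other is None:
            return None
        gap = abs(other.fscore - new_entry.fscore)
        threshold = k_sd * max(other.sd, sd)
        return {
            "team_id": other.team_id,
            "fscore": other.fscore,
            "gap": gap,
            "significant": gap > threshold,
        }

    context = {
        "above": relation(entries[pos - 1] if pos > 0 else None),
        "below": relation(entries[pos + 1] if pos + 1 < len(entries) else None),
    }
    return Placement(
        scores=scores, sd=sd, rank=pos + 1, board=new_board, neighbor_context=context
    )
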