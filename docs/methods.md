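# Methods

## Data model and offset conventions

A corpus is a list of documents, each a `(doc_id, title, abstract)` triple.
Annotations are stand-off mentions `(doc_id, section, start, end, text,
class, provenance)` with `section ∈ {T, A}`. Offsets are 0-based, half-open
`[start, end)`, counted in Unicode **code points** of the raw section text —
no normalisation is ever applied before offsets are taken. Whether
challenge-era submissions counted bytes or code points in multi-byte text is
ambiguous in the wild; code points are the only convention that makes
`text == section[start:end]` checkable in Python, so the readers enforce
exactly that slice equality and reject anything else as an offset-convention
error. Title and abstract are addressed independently; a span never crosses
the boundary.

Gold sets forbid **all** overlaps between mentions, not just strict nesting.
Annotation classes are exclusive (one class per span), and inline-HTML
serialisation requires a properly nested span structure; banning partial
overlaps outright gives both. A `lenient` reading mode demotes partial
overlaps (never nesting) to warnings and drops the later line. Prediction
runs, by contrast, may contain mutually overlapping spans — systems emit what
they emit — and only exact span duplicates are collapsed at load time, with a
warning. Unknown document ids in predictions are an error by default because
silently skipping them hides scoring bugs; a lenient flag downgrades them to
warnings.

## Matching and scores

A predicted span is a true positive iff document, section, start and end all
equal a gold mention; under class-strict matching the class must match too
(class-agnostic is the default, since mention-level task scoring treats
classes only as an analysis dimension). Partial overlaps receive no credit:
the prediction is a false positive and the gold mention remains a false
negative. Each gold mention matches at most one prediction and vice versa.

Precision, recall and F (harmonic mean) use these zero-denominator
conventions, chosen so that the degenerate cases order sensibly: if nothing
was predicted and nothing was annotated, precision = recall = 1 (perfect
agreement); if nothing was predicted but gold is non-empty, precision = 0;
symmetrically for recall; F = 0 whenever P + R = 0, hence F = 0 iff TP = 0 on
non-degenerate input.

Macro averages are taken over documents with at least one gold annotation.
Per-document recall is undefined on unannotated documents, and letting
0-gold/0-pred documents contribute perfect scores would inflate the mean, so
they are excluded; predictions falling in excluded documents still count as
micro false positives. `n_documents` is reported with every macro score.

Mismatch analytics group surface strings by full Unicode case folding
(`str.casefold`) with no stemming or whitespace normalisation — exact,
case-insensitive equality is the only string normalisation used anywhere in
the package. Ranked lists sort by count descending with lexicographic
tie-breaks; the display form of a folded group is its most frequent original
casing (first seen wins ties). Cross-run averages divide the total mismatch
count by the number of runs and rank on the unrounded value; rounding is
left to display code.

## Bootstrap benchmarking

The sampling frame is the set of documents carrying at least one gold
annotation. Each of `n_samples` (default 2500) bootstrap samples draws
`len(frame)` documents with replacement; a document drawn twice contributes
its TP/FP/FN counts twice (standard multiset bootstrap). Micro F is pooled
per sample. One RNG stream (`numpy.random.default_rng(seed)`) generates the
draw indices once, and every team is scored on those same index rows — the
shared-sample design means between-team differences are never sampling
noise. The SD is the sample standard deviation (n−1 denominator, the
conventional estimator); a constant sample vector reports exactly 0.0 rather
than the last-bit rounding of a mean.

Teams are ranked by observed (full-corpus) micro F, descending, ties broken
by team id. Significance grouping uses an adjacent-chain rule: consecutive
ranked teams share a group iff `|F_i − F_{i+1}| ≤ k_sd · max(sd_i, sd_{i+1})`
with `k_sd = 2` by default; groups are maximal chains, numbered from the top.
"Grouped at two SD" admits several constructions (compare to the group's
best, pairwise closure, neighbour chain); the neighbour chain with the larger
of the two SDs was chosen because it is deterministic, order-independent and
produces contiguous groups along the displayed ranking. A 1e-12 epsilon
guards the comparison against float subtraction noise. `k_sd = 0` separates
every distinct F; `k_sd = ∞` merges everything.

Leaderboards store `(team, P, R, F, SD)` plus a metadata line with the task
label and a fingerprint (SHA-256 prefix of the canonicalised gold TSV).
Post-hoc placement of a new run recomputes nothing for stored entries — the
original submissions are not available — and refuses to compare across
fingerprint mismatches. A new run tying a stored F is inserted immediately
after it.

## Annotation propagation

The lexicon maps each case-folded surface form of the manual set to its
class frequencies, total count and display casing. Document text is scanned
by folding one code point at a time; since `str.casefold` maps each code
point independently and never shortens, any raw window longer than the
longest folded form cannot match, which bounds the scan. A candidate
occurrence is suggested when it does not overlap an existing annotation or a
previously accepted candidate; competing candidates are resolved greedily,
longest span first, then leftmost — deterministic and independent of lexicon
insertion order. The suggested class is the entry's majority class, ties
going to the class whose most recent contributing annotation came last
(exclusive classes force a single choice; the data provides no better
signal).

Guidelines permit partial-word annotations, but propagating "acid" into
"acidic" is mostly noise, so the default requires matches to abut non-word
characters or text edges (`boundary="word"`); `boundary="none"` implements
the unrestricted behaviour and is what the brute-force oracle in the tests
verifies exhaustively. Propagation → acceptance → propagation is a fixed
point: accepted suggestions block exactly the occurrences that produced
them.

Curator batch operations (retype by term+class, delete by term with optional
class restriction) use the same case folding and report change counts.

## Synthetic fixtures

The generator assembles documents from whitespace-joined filler tokens with
entity forms embedded as whole tokens at recorded offsets, so the gold set
satisfies every invariant by construction and slice fidelity is exact. The
filler mixes ASCII with Greek letters and µ so byte/code-point confusions
fail loudly. Defaults — 50 documents, 2–6 mentions per document drawn from
an eight-class vocabulary, a 20% chance a mention lands in the title —
produce corpora small enough for sub-second tests yet dense enough that
every class and both sections are exercised; the acceptance benchmark scales
to 250 documents × 4 mentions = 1000 gold mentions, the size at which a 20%
drop rate pins recall to 0.8 within ±3·√(0.2·0.8/1000) ≈ ±0.038.

Degradation applies, per gold mention, an independent drop (probability
`fn_rate`), then a ±1 boundary shift (probability `shift_rate`) that is
re-rolled — widening to ±2, ±3 if needed — until the span differs from every
gold span and every span already predicted, and finally adds
Poisson(`fp_rate`) spurious spans per document that avoid exact collisions
with gold. Expected counts follow in closed form: `TP = G(1−fn)(1−shift)`,
`FN = G − TP`, `FP = G(1−fn)·shift + n_docs·fp_rate`. All randomness flows
through one seeded `numpy` generator, so fixtures are bit-reproducible
across platforms.

What the generator does **not** emulate: real patent prose, chemical-name
morphology, class priors, inter-annotator disagreement, or systems whose
errors correlate with document content. Passing tests therefore demonstrate
that the *scoring machinery* is correct and self-consistent, not that any
particular NER system performs at some level on real patents.

## Numerical and degenerate-input choices

- Scores are plain double arithmetic; test oracles compare at 1e-12.
- `macro_scores`, `bootstrap_fscores` and `cross_run_report` raise a scope
  error on empty input rather than returning NaN.
- Matching iterates predictions in (rank, −confidence, position) order, so
  the better-ranked prediction wins any residual ambiguity deterministically.
- Bootstrap at `n_samples < 2` is rejected (no SD estimable).
- TSV files are headerless UTF-8, `\n` or `\r\n`, empty lines ignored; the
  concrete dialect lives entirely in `spaneval.io` so a format swap touches
  one module.

## Known limitations

- No partial-credit or overlap-based scoring, no confidence-threshold sweeps
  or PR curves: the toolkit evaluates fixed submissions only.
- No paired permutation tests or bootstrap confidence intervals beyond the
  SD; the two-SD chain grouping is a documented stand-in for an
  underspecified convention, and `k_sd` is configurable.
- Stored leaderboard entries are trusted as published; their SDs may have
  been computed with a different seed than a newly placed run's.
- The propagation matcher is exact (folded) string matching only — no fuzzy
  matching, no tokeniser-aware boundaries beyond the word/none switch.
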