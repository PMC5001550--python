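# spaneval

Exact-span evaluation, benchmarking and semi-automatic curation support for
named-entity annotations over title/abstract document collections — the kind
of stand-off chemical and gene/protein mention corpora used in patent-mining
shared tasks (CEMP-style chemical mentions, GPRO-style gene/protein objects).

The package is a batch toolkit for three jobs:

1. **Gold-standard management** — read/validate/write stand-off TSV
   annotations, export inline HTML with highlighted spans, and speed up
   curation by propagating manual annotations to unlabelled exact
   case-insensitive matches, which a curator then revises and implicitly
   accepts.
2. **Prediction analysis** — exact-span matching of a system's predictions
   against the gold standard (no credit for partial overlaps: a partial hit
   counts as one false positive *and* one false negative), micro/macro
   precision–recall–F, per-class TP/FN distributions, and ranked lists of the
   most frequent mismatch terms and the most-mismatched documents, per run or
   averaged across runs.
3. **Benchmarking** — best-run-per-team selection by micro F, document-level
   bootstrap resampling (2500 samples by default) to estimate each team's
   F-score standard deviation, grouping of ranked teams by statistically
   significant difference at two SD, and placement of a new system into a
   stored leaderboard after the fact.

## The statistics

With pooled counts of true positives (TP), false positives (FP) and false
negatives (FN):

```
P = TP / (TP + FP)        R = TP / (TP + FN)        F = 2PR / (P + R)
```

*Micro* averages pool TP/FP/FN globally; *macro* averages compute P/R/F per
document and take the arithmetic mean over documents that carry at least one
gold annotation. A prediction is a TP only when document, section (title vs
abstract), start and end offsets all match a gold mention exactly
(optionally the class too). Offsets are 0-based, half-open, in Unicode code
points.

Bootstrap SDs come from resampling the annotated documents with replacement:
every team is scored on the same 2500 resampled document multisets (one
shared RNG stream), the micro F is pooled per sample, and the sample standard
deviation (n−1) summarises each team's variability. Ranked teams whose
F-score gap is within `2·max(SD_i, SD_j)` of their neighbour chain into one
significance group.

## Worked example

Everything is testable without any corpus download: the `synthetic` module
generates a seeded corpus with known error rates.

```python
from spaneval import (SynthSpec, DegradeSpec, generate_corpus,
                      degrade_to_predictions, error_report, bootstrap_fscores)

corpus, gold = generate_corpus(SynthSpec(n_docs=50, seed=7))
run = degrade_to_predictions(
    gold, corpus, DegradeSpec(fn_rate=0.2, fp_rate=0.5, shift_rate=0.1, seed=8))

report = error_report(gold, run, k=3)
print(report.render_text())

boots = bootstrap_fscores(gold, {"demo": run}, n_samples=2500, seed=9)
b = boots[0]
print(f"observed F = {b.observed_f:.4f}, bootstrap SD = {b.sd:.4f} "
      f"(rank {b.rank}, group {b.group})")
```

prints

```
micro: P=0.8391 R=0.7192 F=0.7745
macro: P=0.8290 R=0.7263 F=0.7565 over 50 documents

TP/FN by annotation class:
  ABBREVIATIONS    TP=18     FN=6
  FAMILY           TP=18     FN=5
  ...

Top false negatives (terms):
  sodium and potassium salts 9
  active agent             8
  CAS-50-78-2              4

Top false positives (terms):
   1,2-diol                2
  Docetaxel                2
  odium and potassium salts 2
...
observed F = 0.7745, bootstrap SD = 0.0296 (rank 1, group 1)
```

The run was degraded with a 20% drop rate, so recall lands near 0.8; the
boundary-shifted survivors (10%) show up twice — as clipped false-positive
terms like `odium and potassium salts` *and* as false negatives — which is
exactly how exact-span scoring treats partial hits.

The same workflow is available from the shell:

```
spaneval synth --outdir fix --n-docs 50 --seed 7
spaneval validate --docs fix/documents.tsv fix/pred_degraded.tsv
spaneval evaluate --docs fix/documents.tsv --gold fix/gold.tsv \
                  --pred fix/pred_degraded.tsv --out report.json
spaneval bench --docs fix/documents.tsv --gold fix/gold.tsv \
               --pred team1:1:fix/pred_degraded.tsv --seed 7 --out board.tsv
spaneval rank  --board board.tsv --docs fix/documents.tsv \
               --gold fix/gold.tsv --pred fix/pred_degraded.tsv --seed 7
```

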