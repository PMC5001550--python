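"""Shared fixtures: a small hand-built corpus and seeded synthetic fixtures."""

import pytest

from spaneval import (
    AnnotationSet,
    Corpus,
    DegradeSpec,
    Document,
    Mention,
    PredictionRun,
    SynthSpec,
    degrade_to_predictions,
    generate_corpus,
)


@pytest.fixture
def tiny_corpus() -> Corpus:
    return Corpus([
        Document("D1", "Aspirin salts", "We tested aspirin in µM doses."),
        Document("D2", "Ester screening", "An alkyl ester and an Aspirin salt."),
        Document("D3", "Control study", "No chemicals were mentioned here."),
    ])


def gold_mention(doc_id, section, start, end, text, cls="TRIVIAL", **kw):
    return Mention(doc_id=doc_id, section=section, start=start, end=end,
                   text=text, cls=cls, **kw)


@pytest.fixture
def tiny_gold(tiny_corpus) -> AnnotationSet:
    # offsets verified against the fixture texts
    mentions = [
        gold_mention("D1", "T", 0, 7, "Aspirin"),
        gold_mention("D1", "A", 10, 17, "aspirin"),
        gold_mention("D2", "A", 3, 8, "alkyl", cls="FAMILY"),
        gold_mention("D2", "A", 9, 14, "ester", cls="FAMILY"),
        gold_mention("D2", "A", 22, 29, "Aspirin"),
    ]
    return AnnotationSet(task="CEMP",
                         class_inventory=("SYSTEMATIC", "TRIVIAL", "FAMILY",
                                          "FORMULA", "ABBREVIATIONS",
                                          "IDENTIFIERS", "MULTIPLE", "NO CLASS"),
                         mentions=mentions)


def make_run(mentions, team="t1", run_id=1) -> PredictionRun:
    return PredictionRun(team_id=team, run_id=run_id, mentions=[
        m.replace(provenance="predicted") for m in mentions
    ])


@pytest.fixture
def synth_small():
    spec = SynthSpec(n_docs=30, seed=11)
    corpus, gold = generate_corpus(spec)
    return spec, corpus, gold


@pytest.fixture
def synth_degraded(synth_small):
    spec, corpus, gold = synth_small
    dspec = DegradeSpec(fn_rate=0.2, fp_rate=0.5, shift_rate=0.1, seed=13)
    run = degrade_to_predictions(gold, corpus, dspec)
    return corpus, gold, dspec, run
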