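import math

import pytest
from hypothesis import given, settings, strategies as st

from spaneval import (
    AnnotationSet,
    Corpus,
    Document,
    Mention,
    PredictionRun,
    ScopeError,
    class_distribution,
    cross_run_report,
    error_report,
    macro_scores,
    match_run,
    micro_scores,
    scores_from_counts,
    top_documents,
    top_terms,
)

from conftest import gold_mention, make_run


def oracle_prf(tp, fp, fn):
    """Directly coded precision/recall/F definitions, used as the oracle."""
    p = 1.0 if (tp + fp == 0 and fn == 0) else (0.0 if tp + fp == 0 else tp / (tp + fp))
    r = 1.0 if (tp + fn == 0 and fp == 0) else (0.0 if tp + fn == 0 else tp / (tp + fn))
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f


class TestMatchRun:
    def test_identity_is_one_tp(self, tiny_gold):
        g = tiny_gold.mentions[1]  # (D1, A, 10, 17)
        run = make_run([g])
        m = match_run(tiny_gold.replace_mentions([g]), run)
        assert m.counts == (1, 0, 0)

    def test_partial_hit_scores_fp_plus_fn(self, tiny_gold):
        g = tiny_gold.mentions[1]
        run = make_run([g.replace(end=16, text=g.text[:-1])])
        m = match_run(tiny_gold.replace_mentions([g]), run)
        assert m.counts == (0, 1, 1)

    def test_wrong_section_is_no_match(self):
        gold = AnnotationSet(mentions=[gold_mention("D1", "T", 0, 4, "Aspi")])
        run = make_run([gold_mention("D1", "A", 0, 4, "We t")])
        assert match_run(gold, run).counts == (0, 1, 1)

    def test_class_strict_demotes_wrong_class(self, tiny_gold):
        g = tiny_gold.mentions[1]  # TRIVIAL
        run = make_run([g.replace(cls="FORMULA")])
        gold = tiny_gold.replace_mentions([g])
        assert match_run(gold, run, class_strict=False).counts == (1, 0, 0)
        assert match_run(gold, run, class_strict=True).counts == (0, 1, 1)

    def test_per_doc_counts_sum_to_global(self, tiny_gold):
        run = make_run(tiny_gold.mentions[:3])
        m = match_run(tiny_gold, run)
        sums = [sum(c[i] for c in m.per_doc.values()) for i in range(3)]
        assert tuple(sums) == m.counts

    def test_empty_inputs_give_empty_partitions(self):
        gold = AnnotationSet()
        m = match_run(gold, PredictionRun(team_id="t", run_id=1))
        assert m.counts == (0, 0, 0)


class TestMicroScores:
    def test_eight_two_two_gives_point_eight(self):
        s = scores_from_counts(8, 2, 2)
        assert (s.precision, s.recall) == (0.8, 0.8)
        assert s.fscore == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("tp,fp,fn,expect", [
        (0, 5, 5, (0.0, 0.0, 0.0)),
        (3, 0, 0, (1.0, 1.0, 1.0)),
        (0, 0, 0, (1.0, 1.0, 1.0)),   # empty vs empty is perfect agreement
        (0, 0, 4, (0.0, 0.0, 0.0)),   # predicted nothing, missed everything
        (0, 4, 0, (0.0, 0.0, 0.0)),   # nothing to find, predicted junk
    ])
    def test_zero_denominator_conventions(self, tp, fp, fn, expect):
        s = scores_from_counts(tp, fp, fn)
        assert (s.precision, s.recall, s.fscore) == expect

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_matches_directly_coded_oracle(self, tp, fp, fn):
        s = scores_from_counts(tp, fp, fn)
        p, r, f = oracle_prf(tp, fp, fn)
        assert math.isclose(s.precision, p, abs_tol=1e-12)
        assert math.isclose(s.recall, r, abs_tol=1e-12)
        assert math.isclose(s.fscore, f, abs_tol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_f_bounded_by_p_and_r_and_zero_iff_no_tp(self, tp, fp, fn):
        s = scores_from_counts(tp, fp, fn)
        assert min(s.precision, s.recall) - 1e-12 <= s.fscore <= max(s.precision, s.recall) + 1e-12
        if tp == 0 and (fp or fn):
            assert s.fscore == 0.0


def random_eval_case(rng, n_docs=6):
    """A random corpus + gold + run; returns (gold, run)."""
    docs, gold_ms, pred_ms = [], [], []
    for d in range(n_docs):
        doc_id = f"D{d}"
        text = " ".join("tok%d" % i for i in range(rng.integers(5, 15)))
        docs.append(Document(doc_id, "title here", text))
        pos = 0
        while pos + 4 < len(text):
            length = int(rng.integers(2, 5))
            span = (pos, min(pos + length, len(text)))
            mention = Mention(doc_id=doc_id, section="A", start=span[0], end=span[1],
                              text=text[span[0]:span[1]], cls="TRIVIAL")
            roll = rng.random()
            if roll < 0.35:
                gold_ms.append(mention)
                if rng.random() < 0.6:
                    pred_ms.append(mention.replace(provenance="predicted"))
            elif roll < 0.55:
                pred_ms.append(mention.replace(provenance="predicted"))
            pos = span[1] + int(rng.integers(1, 4))
    gold = AnnotationSet(mentions=gold_ms)
    run = PredictionRun(team_id="t", run_id=1, mentions=pred_ms)
    return gold, run


class TestConservationAndMacro:
    def test_conservation_on_random_fixtures(self):
        import numpy as np
        rng = np.random.default_rng(42)
        for _ in range(25):
            gold, run = random_eval_case(rng)
            m = match_run(gold, run)
            assert len(m.tp) + len(m.fn) == len(gold)
            assert len(m.tp) + len(m.fp) == len(run)

    def test_macro_is_mean_of_per_doc_f(self):
        gold = AnnotationSet(mentions=[
            gold_mention("D1", "A", 10, 17, "aspirin"),
            gold_mention("D2", "A", 3, 8, "alkyl"),
        ])
        run = make_run([gold.mentions[0]])  # D1 perfect, D2 fully missed
        s = macro_scores(gold, run)
        assert s.fscore == pytest.approx(0.5)
        assert s.n_documents == 2

    def test_single_doc_macro_equals_micro_equals_one(self, tiny_gold):
        only_d1 = tiny_gold.replace_mentions(
            [m for m in tiny_gold.mentions if m.doc_id == "D1"]
        )
        run = make_run(only_d1.mentions)
        assert macro_scores(only_d1, run).fscore == 1.0
        assert micro_scores(match_run(only_d1, run)).fscore == 1.0

    def test_macro_equals_micro_on_identical_per_doc_counts(self):
        # every document: 2 gold, 1 matched, 1 spurious prediction
        gold_ms, pred_ms = [], []
        for d in range(5):
            a = gold_mention(f"D{d}", "A", 0, 4, "aaaa")
            b = gold_mention(f"D{d}", "A", 6, 10, "bbbb")
            gold_ms += [a, b]
            pred_ms += [a.replace(provenance="predicted"),
                        gold_mention(f"D{d}", "A", 12, 16, "cccc",
                                     provenance="predicted")]
        gold = AnnotationSet(mentions=gold_ms)
        run = PredictionRun(team_id="t", run_id=1, mentions=pred_ms)
        micro = micro_scores(match_run(gold, run))
        macro = macro_scores(gold, run)
        assert macro.precision == pytest.approx(micro.precision, abs=1e-12)
        assert macro.recall == pytest.approx(micro.recall, abs=1e-12)
        assert macro.fscore == pytest.approx(micro.fscore, abs=1e-12)

    def test_macro_matches_brute_force_per_document_mean(self):
        import numpy as np
        rng = np.random.default_rng(7)
        for _ in range(10):
            gold, run = random_eval_case(rng)
            if not gold.mentions:
                continue
            s = macro_scores(gold, run)
            in_scope = sorted({g.doc_id for g in gold.mentions})
            fs = []
            for d in in_scope:
                g_spans = {m.span_key for m in gold.mentions if m.doc_id == d}
                p_spans = {m.span_key for m in run.mentions if m.doc_id == d}
                tp = len(g_spans & p_spans)
                fs.append(oracle_prf(tp, len(p_spans) - tp, len(g_spans) - tp)[2])
            assert s.fscore == pytest.approx(sum(fs) / len(fs), abs=1e-12)

    def test_macro_empty_scope_raises(self):
        with pytest.raises(ScopeError):
            macro_scores(AnnotationSet(), PredictionRun(team_id="t", run_id=1))

    def test_monotonicity_of_micro(self, tiny_gold):
        run0 = make_run(tiny_gold.mentions[:2])
        base = micro_scores(match_run(tiny_gold, run0))
        with_correct = make_run(tiny_gold.mentions[:3])
        s1 = micro_scores(match_run(tiny_gold, with_correct))
        assert s1.recall >= base.recall
        spurious = gold_mention("D3", "A", 0, 2, "No", provenance="predicted")
        with_spurious = make_run(tiny_gold.mentions[:2] + [spurious])
        s2 = micro_scores(match_run(tiny_gold, with_spurious))
        assert s2.precision <= base.precision


class TestDistributionAndTopLists:
    def test_class_distribution_counts(self):
        gold = AnnotationSet(mentions=[
            gold_mention("D1", "A", 0, 4, "aaaa", cls="TRIVIAL"),
            gold_mention("D1", "A", 6, 10, "bbbb", cls="TRIVIAL"),
            gold_mention("D2", "A", 0, 4, "cccc", cls="TRIVIAL"),
            gold_mention("D2", "A", 6, 10, "dddd", cls="FORMULA"),
        ])
        run = make_run(gold.mentions[:2])
        dist = class_distribution(match_run(gold, run), gold)
        assert dist == {"TRIVIAL": (2, 1), "FORMULA": (0, 1)}

    def test_rows_follow_inventory_order(self, tiny_gold):
        run = make_run([])
        dist = class_distribution(match_run(tiny_gold, run), tiny_gold)
        assert list(dist) == ["TRIVIAL", "FAMILY"]  # inventory order, present only

    def test_empty_gold_gives_empty_mapping(self):
        gold = AnnotationSet()
        assert class_distribution(match_run(gold, make_run([])), gold) == {}

    def test_top_terms_case_folds_and_ranks(self):
        gold = AnnotationSet(mentions=[
            gold_mention("D1", "A", 0, 5, "alkyl"),
            gold_mention("D2", "A", 0, 5, "Alkyl"),
            gold_mention("D3", "A", 0, 4, "acid"),
        ])
        m = match_run(gold, PredictionRun(team_id="t", run_id=1))
        assert top_terms(m, "fn", 5) == [("alkyl", 2), ("acid", 1)]

    def test_top_terms_tie_breaks_lexicographically(self):
        gold = AnnotationSet(mentions=[
            gold_mention("D1", "A", 0, 4, "acid"), gold_mention("D2", "A", 0, 4, "acid"),
            gold_mention("D3", "A", 0, 5, "ester"), gold_mention("D4", "A", 0, 5, "ester"),
        ])
        m = match_run(gold, PredictionRun(team_id="t", run_id=1))
        assert top_terms(m, "fn", 1) == [("acid", 2)]

    def test_top_documents_ranked_and_zero_suppressed(self, tiny_gold):
        run = make_run([m for m in tiny_gold.mentions if m.doc_id == "D1"])
        m = match_run(tiny_gold, run)  # D2 has 3 FNs, D1 none
        assert top_documents(m, "fn", 5) == [("D2", 3)]
        assert top_documents(m, "fp", 5) == []


class TestCrossRun:
    def test_averages_over_runs(self, tiny_gold):
        # run1 misses all of D2's 3 mentions + D1's title; run2 misses only D2's "alkyl"
        run1 = make_run([tiny_gold.mentions[1]], team="t", run_id=1)
        run2 = make_run(tiny_gold.mentions[:2] + tiny_gold.mentions[3:], team="t", run_id=2)
        rep = cross_run_report(tiny_gold, [run1, run2])
        docs = dict(rep["top_fn_documents"])
        assert docs["D2"] == pytest.approx((3 + 1) / 2)
        assert docs["D1"] == pytest.approx(0.5)

    def test_single_run_identity(self, tiny_gold):
        run = make_run([tiny_gold.mentions[1]])
        rep = cross_run_report(tiny_gold, [run])
        m = match_run(tiny_gold, run)
        assert rep["top_fn_documents"] == [(d, float(c)) for d, c in top_documents(m, "fn", 10)]

    def test_term_missed_by_every_run_outranks_partial(self, tiny_gold):
        # "Aspirin"/"aspirin" fold together; missed by both runs -> avg 1.5
        # "alkyl" missed by one of two runs -> avg 0.5
        miss_all = make_run([tiny_gold.mentions[3]], team="t", run_id=1)
        miss_some = make_run([tiny_gold.mentions[0], tiny_gold.mentions[1],
                              tiny_gold.mentions[2], tiny_gold.mentions[3]],
                             team="t", run_id=2)
        rep = cross_run_report(tiny_gold, [miss_all, miss_some])
        terms = {t.casefold(): c for t, c in rep["top_fn_terms"]}
        assert terms["aspirin"] > terms["alkyl"]

    def test_empty_run_list_raises(self, tiny_gold):
        with pytest.raises(ScopeError):
            cross_run_report(tiny_gold, [])


def test_error_report_is_complete(synth_degraded):
    corpus, gold, dspec, run = synth_degraded
    rep = error_report(gold, run)
    d = rep.to_dict()
    for key in ("scores_micro", "scores_macro", "class_distribution",
                "top_fn_terms", "top_fp_terms", "top_fn_documents",
                "top_fp_documents", "per_document"):
        assert key in d
    total_tp = sum(v["tp"] for v in d["class_distribution"].values())
    total_fn = sum(v["fn"] for v in d["class_distribution"].values())
    m = match_run(gold, run)
    assert (total_tp, total_fn) == (len(m.tp), len(m.fn))
    text = rep.render_text()
    assert "micro" in text and "macro" in text
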