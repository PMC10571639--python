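"""Fusion metrics, the SM promotion rule, and the corpus driver."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from vaxnorm.encoder import Candidate, CandidateList, build_index, char_ngram_backend, retrieve
from vaxnorm.ensemble import (
    METRICS,
    EnsembleConfig,
    apply_sm_rule,
    fuse,
    normalize_corpus,
    read_predictions_jsonl,
    weights_from_validation,
    write_predictions_jsonl,
)
from vaxnorm.fixtures import NoiseConfig, make_mentions
from vaxnorm.ontology import Concept, ConceptGraph


def _clist(mention, scored, backend="m"):
    """Build a CandidateList from [(concept_id, score), ...] (descending)."""
    return CandidateList(
        mention, [Candidate(cid, s, r) for r, (cid, s) in enumerate(scored, 1)], backend
    )


def _oracle_fuse(lists, weights, metric, k):
    """Independent enumeration of the weighted per-concept sums."""
    totals = {}
    for model, cl in lists.items():
        w = weights.get(model, 0.0)
        if w <= 0:
            continue
        top = cl.candidates[:k]
        for c in top:
            if metric == "score":
                s = c.score
            elif metric == "scale":
                lo, hi = min(x.score for x in top), max(x.score for x in top)
                s = 1.0 if hi == lo else (c.score - lo) / (hi - lo)
            else:
                s = k - c.rank + 1
            totals[c.concept_id] = totals.get(c.concept_id, 0.0) + w * s
    return sorted(totals.items(), key=lambda t: (-t[1], t[0]))


class TestFuse:
    @pytest.mark.parametrize("metric", METRICS)
    def test_single_model_reproduces_its_ordering(self, metric):
        cl = _clist("m1", [("C", 0.9), ("A", 0.5), ("B", 0.2)])
        cfg = EnsembleConfig({"m": 1.0}, metric=metric, k=10, sm_rule=False)
        out = fuse({"m": cl}, cfg)
        assert [c.concept_id for c in out.candidates] == ["C", "A", "B"]

    def test_zero_weight_model_is_ignored(self):
        cl1 = _clist("x", [("A", 0.9), ("B", 0.5)], "m1")
        cl2 = _clist("x", [("B", 0.9), ("A", 0.5)], "m2")
        cfg = EnsembleConfig({"m1": 1.0, "m2": 0.0}, metric="score", sm_rule=False)
        out = fuse({"m1": cl1, "m2": cl2}, cfg)
        solo = fuse({"m1": cl1}, EnsembleConfig({"m1": 1.0}, metric="score", sm_rule=False))
        assert [c.concept_id for c in out.candidates] == [c.concept_id for c in solo.candidates]

    def test_two_model_borda_totals_match_hand_computation(self):
        cl1 = _clist("x", [("A", 0.9), ("B", 0.8), ("C", 0.1)], "m1")
        cl2 = _clist("x", [("C", 0.7), ("A", 0.6), ("B", 0.5)], "m2")
        cfg = EnsembleConfig({"m1": 2.0, "m2": 1.0}, metric="rank", k=3, sm_rule=False)
        out = fuse({"m1": cl1, "m2": cl2}, cfg)
        # hand Borda (K=3): A: 2*3 + 1*2 = 8, B: 2*2 + 1*1 = 5, C: 2*1 + 1*3 = 5
        got = {c.concept_id: c.score for c in out.candidates}
        assert got == {"A": 8.0, "B": 5.0, "C": 5.0}
        assert [c.concept_id for c in out.candidates] == ["A", "B", "C"]  # tie → id order

    @pytest.mark.parametrize("metric", METRICS)
    def test_constructed_cases_match_enumeration_oracle(self, metric):
        rng = np.random.default_rng(42)
        ids = ["A", "B", "C", "D", "E"]
        for case in range(25):
            lists, weights = {}, {}
            for m in ("m1", "m2"):
                picked = sorted(rng.choice(len(ids), size=rng.integers(1, 5), replace=False))
                scores = sorted(rng.random(len(picked)), reverse=True)
                lists[m] = _clist("x", [(ids[i], float(s)) for i, s in zip(picked, scores)], m)
                weights[m] = float(rng.random() + 0.1)
            cfg = EnsembleConfig(weights, metric=metric, k=4, sm_rule=False)
            out = fuse(lists, cfg)
            expected = _oracle_fuse(lists, weights, metric, 4)
            assert [c.concept_id for c in out.candidates] == [cid for cid, _ in expected], case
            assert [c.score for c in out.candidates] == pytest.approx([s for _, s in expected])

    def test_model_map_iteration_order_is_irrelevant(self):
        cl1 = _clist("x", [("A", 0.9), ("B", 0.5)], "m1")
        cl2 = _clist("x", [("B", 0.9), ("C", 0.5)], "m2")
        cfg = EnsembleConfig({"m1": 0.7, "m2": 0.3}, metric="score", sm_rule=False)
        a = fuse({"m1": cl1, "m2": cl2}, cfg)
        b = fuse({"m2": cl2, "m1": cl1}, cfg)
        assert [(c.concept_id, c.score) for c in a.candidates] == [
            (c.concept_id, c.score) for c in b.candidates
        ]

    def test_scale_contributions_bounded(self):
        cl = _clist("x", [("A", 0.93), ("B", 0.41), ("C", 0.07)])
        cfg = EnsembleConfig({"m": 1.0}, metric="scale", sm_rule=False)
        out = fuse({"m": cl}, cfg)
        assert all(0.0 <= c.score <= 1.0 for c in out.candidates)
        assert out.candidates[0].score == 1.0 and out.candidates[-1].score == 0.0

    def test_mention_mismatch_and_bad_config(self):
        cl1 = _clist("x", [("A", 1.0)], "m1")
        cl2 = _clist("y", [("A", 1.0)], "m2")
        cfg = EnsembleConfig({"m1": 1.0, "m2": 1.0}, sm_rule=False)
        with pytest.raises(ValueError, match="different mentions"):
            fuse({"m1": cl1, "m2": cl2}, cfg)
        with pytest.raises(ValueError):
            EnsembleConfig({"m1": 0.0})
        with pytest.raises(ValueError):
            EnsembleConfig({"m1": -1.0})
        with pytest.raises(ValueError):
            EnsembleConfig({"m1": 1.0}, metric="median")


AIDSVAX = ConceptGraph(
    [
        Concept("V:1", "vaccine"),
        Concept("V:2", "AIDSVAX B/E", parent_ids=("V:1",)),
        Concept("V:3", "conjugate vaccine", parent_ids=("V:1",)),
        Concept("V:4", "meningococcal conjugate vaccine", parent_ids=("V:3",)),
    ]
)


class TestSmRule:
    def test_placebo_mention_promotes_the_vaccine_itself(self):
        pred = _clist("AIDSVAX B/E Placebo", [("V:3", 0.8), ("V:2", 0.6)])
        rp = fuse({"m": pred}, EnsembleConfig({"m": 1.0}, metric="score", sm_rule=False))
        out = apply_sm_rule(AIDSVAX, rp)
        assert out.candidates[0].concept_id == "V:2"
        assert out.sm_promoted.concept_id == "V:2"
        assert out.sm_promoted.name == "AIDSVAX B/E"
        # relative order of the others preserved
        assert [c.concept_id for c in out.candidates] == ["V:2", "V:3"]

    def test_no_vocabulary_substring_leaves_prediction_unchanged(self):
        rp = fuse(
            {"m": _clist("totally unrelated drug", [("V:3", 0.2)])},
            EnsembleConfig({"m": 1.0}, metric="score", sm_rule=False),
        )
        assert apply_sm_rule(AIDSVAX, rp) is rp

    def test_longest_matched_name_wins(self):
        mention = "Menveo meningococcal conjugate vaccine 0.5 mL"
        rp = fuse(
            {"m": _clist(mention, [("V:3", 0.9), ("V:4", 0.8)])},
            EnsembleConfig({"m": 1.0}, metric="score", sm_rule=False),
        )
        out = apply_sm_rule(AIDSVAX, rp)
        # brute-force scan over all names: the longest folded substring match
        matches = [
            (cid, name)
            for cid, name in AIDSVAX.iter_names()
            if name.casefold() in mention.casefold()
        ]
        longest = max(matches, key=lambda t: len(t[1]))
        assert longest == ("V:4", "meningococcal conjugate vaccine")
        assert out.candidates[0].concept_id == "V:4"

    def test_absent_concept_is_inserted_at_rank_1(self):
        rp = fuse(
            {"m": _clist("AIDSVAX B/E booster", [("V:3", 0.5)])},
            EnsembleConfig({"m": 1.0}, metric="score", sm_rule=False),
        )
        out = apply_sm_rule(AIDSVAX, rp)
        assert out.candidates[0].concept_id == "V:2"
        assert [c.rank for c in out.candidates] == [1, 2]

    def test_idempotent_on_full_fixture_corpus(self, fixture_graph, fixture_index, fixture_backend):
        entries, _ = make_mentions(fixture_graph, 60, NoiseConfig(seed=4))
        for e in entries:
            cl = retrieve(e.mention, fixture_index, fixture_backend, 10)
            rp = fuse({fixture_backend.name: cl},
                      EnsembleConfig({fixture_backend.name: 1.0}, metric="score", sm_rule=False))
            once = apply_sm_rule(fixture_graph, rp)
            twice = apply_sm_rule(fixture_graph, once)
            assert [(c.concept_id, c.rank) for c in once.candidates] == [
                (c.concept_id, c.rank) for c in twice.candidates
            ]
            assert once.sm_promoted == twice.sm_promoted


class TestWeightsFromValidation:
    def test_top_three_proportional(self):
        acc = {"a": 0.6, "b": 0.3, "c": 0.1, "d": 0.05}
        w = weights_from_validation(acc)
        assert set(w) == {"a", "b", "c"}
        assert w["a"] == pytest.approx(0.6)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_all_zero_falls_back_to_equal(self):
        w = weights_from_validation({"a": 0.0, "b": 0.0})
        assert w == {"a": 0.5, "b": 0.5}


class TestNormalizeCorpus:
    def test_empty_input(self, fixture_graph, fixture_index, fixture_backend):
        cfg = EnsembleConfig({fixture_backend.name: 1.0})
        assert normalize_corpus([], fixture_graph, {fixture_backend.name: fixture_index},
                                {fixture_backend.name: fixture_backend}, cfg) == []

    def test_composition_oracle(self, fixture_graph, fixture_index, fixture_backend):
        """Driver output equals retrieve → fuse → sm-rule composed by hand."""
        entries, _ = make_mentions(fixture_graph, 10, NoiseConfig(seed=6))
        name = fixture_backend.name
        cfg = EnsembleConfig({name: 1.0}, metric="scale", k=10, sm_rule=True)
        preds = normalize_corpus([(e.mention_id, e.mention) for e in entries], fixture_graph,
                                 {name: fixture_index}, {name: fixture_backend}, cfg)
        for e, p in zip(entries, preds):
            cl = retrieve(e.mention, fixture_index, fixture_backend, 10)
            manual = apply_sm_rule(fixture_graph, fuse({name: cl}, cfg))
            assert p.mention_id == e.mention_id
            assert [(c.concept_id, c.rank) for c in p.candidates] == [
                (c.concept_id, c.rank) for c in manual.candidates
            ]

    def test_sm_rule_disabled_sets_no_promotions(self, fixture_graph, fixture_index, fixture_backend):
        entries, _ = make_mentions(fixture_graph, 10, NoiseConfig(seed=6))
        cfg = EnsembleConfig({fixture_backend.name: 1.0}, sm_rule=False)
        preds = normalize_corpus([e.mention for e in entries], fixture_graph,
                                 {fixture_backend.name: fixture_index},
                                 {fixture_backend.name: fixture_backend}, cfg)
        assert all(p.sm_promoted is None for p in preds)


class TestPredictionsJsonl:
    def test_round_trip(self, tmp_path, fixture_graph, fixture_index, fixture_backend):
        entries, _ = make_mentions(fixture_graph, 5, NoiseConfig(seed=8))
        cfg = EnsembleConfig({fixture_backend.name: 1.0}, sm_rule=True)
        preds = normalize_corpus([(e.mention_id, e.mention) for e in entries], fixture_graph,
                                 {fixture_backend.name: fixture_index},
                                 {fixture_backend.name: fixture_backend}, cfg)
        path = tmp_path / "preds.jsonl"
        write_predictions_jsonl(preds, path)
        back = read_predictions_jsonl(path)
        assert len(back) == len(preds)
        for a, b in zip(preds, back):
            assert a.mention_id == b.mention_id and a.mention == b.mention
            assert [(c.concept_id, c.score, c.rank) for c in a.candidates] == [
                (c.concept_id, c.score, c.rank) for c in b.candidates
            ]
            assert a.sm_promoted == b.sm_promoted
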