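"""Line-sweep chaining against the quadratic oracle, plus edge semantics."""

import random

import pytest

from fragchain import (
    GapParams,
    brute_force_chain,
    chain_members,
    connect_decision,
    recompute_chain_score,
    report_chains,
    sweep_chain,
)
from tests.conftest import make_fragment, random_instance, random_params

TOL = 1e-9


def scores_match(a, b):
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        assert ra.frag.uid == rb.frag.uid
        assert ra.score == pytest.approx(rb.score, abs=TOL)


class TestSweepBasics:
    @pytest.mark.parametrize("model", ["linear", "sop"])
    def test_single_fragment(self, model):
        f = make_fragment(0, 0, 10, 0, 10, score=5)
        (rec,) = sweep_chain([f], GapParams(model, 1, 1))
        assert rec.score == 5 and rec.pred is None and rec.first is f

    @pytest.mark.parametrize("model", ["linear", "sop"])
    def test_abutting_fragments_add_without_gap_cost(self, model):
        frags = [
            make_fragment(0, 0, 10, 0, 10, score=3),
            make_fragment(1, 10, 20, 10, 20, score=4),
            make_fragment(2, 20, 30, 20, 30, score=5),
        ]
        recs = sweep_chain(frags, GapParams(model, 1, 1))
        assert recs[2].score == pytest.approx(12)
        assert [f.uid for f in chain_members(recs[2])] == [0, 1, 2]

    def test_query_overlap_blocks_predecessor(self):
        """Database-ordered fragments overlapping on the query never chain."""
        f1 = make_fragment(0, 0, 10, 0, 10, score=5)
        f2 = make_fragment(1, 12, 22, 12, 22, score=5)
        f3 = make_fragment(2, 30, 40, 5, 15, score=5)  # overlaps f1 on y
        recs = sweep_chain([f1, f2, f3], GapParams("linear", 0.1, 0.1))
        members = chain_members(recs[2])
        assert f1 not in members

    def test_one_base_overlap_is_not_admissible(self):
        pred = make_fragment(0, 0, 11, 0, 10, score=50)  # last base at x=10
        succ = make_fragment(1, 10, 20, 15, 25, score=5)
        recs = sweep_chain([pred, succ], GapParams("linear", 0.0, 0.0))
        assert recs[1].pred is None and recs[1].score == 5

    def test_abutment_on_x_is_admissible(self):
        pred = make_fragment(0, 0, 10, 0, 10, score=50)
        succ = make_fragment(1, 10, 20, 15, 25, score=5)
        recs = sweep_chain([pred, succ], GapParams("linear", 0.0, 0.0))
        assert recs[1].pred is not None and recs[1].score == 55

    def test_mixed_groups_rejected(self):
        frags = [
            make_fragment(0, 0, 5, 0, 5, query_id="a"),
            make_fragment(1, 0, 5, 0, 5, query_id="b"),
        ]
        with pytest.raises(ValueError):
            sweep_chain(frags, GapParams("linear", 1, 1))

    def test_empty_input(self):
        assert sweep_chain([], GapParams("sop", 1, 0)) == []
        assert brute_force_chain([], GapParams("sop", 1, 0)) == []


class TestConnectDecision:
    def test_tie_connects(self):
        # predecessor score exactly pays the gap: connection is made
        assert connect_decision(0.0)

    def test_unaffordable_gap_starts_fresh(self):
        assert not connect_decision(-1.0)
        assert connect_decision(10.0)

    def test_tie_realized_in_sweep(self):
        pred = make_fragment(0, 0, 10, 0, 10, score=10)
        succ = make_fragment(1, 20, 30, 20, 30, score=7)  # gap cost 10+10 = 20? no
        p = GapParams("linear", 1.0, 0.0)  # cost = d_x = 10 = pred.score
        recs = sweep_chain([pred, succ], p)
        assert recs[1].score == pytest.approx(7)
        assert recs[1].pred is not None  # connected at value 0: longer chain


class TestOracleEquivalence:
    """The module's central property: sweep == quadratic DP."""

    @pytest.mark.parametrize("model", ["linear", "sop"])
    def test_random_instances(self, model):
        rng = random.Random(101 if model == "linear" else 202)
        for _ in range(200):
            frags = random_instance(rng, rng.randrange(5, 61))
            p = random_params(rng, model)
            s = sweep_chain(frags, p)
            b = brute_force_chain(frags, p)
            scores_match(s, b)
            rep_s = sorted(c.chain_score for c in report_chains(s))
            rep_b = sorted(c.chain_score for c in report_chains(b))
            assert rep_s == pytest.approx(rep_b, abs=TOL)

    @pytest.mark.parametrize("model", ["linear", "sop"])
    def test_dense_small_coordinates_force_ties(self, model):
        """Tiny integer coordinates and scores produce abutments, shared
        endpoints, and value ties; scores must still agree exactly."""
        rng = random.Random(303)
        for _ in range(100):
            frags = random_instance(
                rng, rng.randrange(3, 25), coord_max=40, len_max=8, score_max=5
            )
            for f in frags:
                f.score = float(int(f.score))  # integer scores: exact ties
            p = GapParams(model, 1.0, 1.0)
            scores_match(sweep_chain(frags, p), brute_force_chain(frags, p))

    def test_local_lower_bound_and_validity(self):
        rng = random.Random(404)
        for model in ("linear", "sop"):
            p = random_params(rng, model)
            frags = random_instance(rng, 50)
            recs = sweep_chain(frags, p)
            for rec in recs:
                assert rec.score >= rec.frag.score - TOL
                members = chain_members(rec)
                assert recompute_chain_score(members, p) == pytest.approx(
                    rec.score, abs=TOL
                )
                # colinear and disjoint along the chain
                for a, b in zip(members, members[1:]):
                    assert a.end_x <= b.beg_x and a.end_y <= b.beg_y

    def test_sop_needs_both_octants(self):
        """Dropping either octant structure loses chains on some instance."""
        p = GapParams("sop", 1.0, 0.2)
        # octant 1 pair: d_x > d_y  (succ diagonal larger); gap cost 36 < 60
        o1 = [
            make_fragment(0, 0, 10, 0, 10, score=60),
            make_fragment(1, 50, 60, 15, 25, score=60),
        ]
        # octant 2 pair: d_x < d_y
        o2 = [
            make_fragment(0, 0, 10, 0, 10, score=60),
            make_fragment(1, 15, 25, 50, 60, score=60),
        ]
        for frags in (o1, o2):
            recs = sweep_chain(frags, p)
            assert recs[1].pred is not None
            assert recs[1].score == pytest.approx(
                brute_force_chain(frags, p)[1].score
            )


class TestReporting:
    def test_best_chain_per_first_fragment_group(self):
        # two chains from the same head: A->B (cheap gap) and A->C (free gap)
        a = make_fragment(0, 0, 10, 0, 10, score=10)
        b = make_fragment(1, 30, 40, 12, 22, score=10)
        c = make_fragment(2, 20, 30, 20, 30, score=10)
        p = GapParams("sop", 1.0, 0.0)
        reports = report_chains(sweep_chain([a, b, c], p))
        heads = [r.fragment_uids[0] for r in reports]
        assert heads.count(0) == 1  # one report per head, the best one

    def test_min_score_filter(self):
        f = make_fragment(0, 0, 10, 0, 10, score=25)
        recs = sweep_chain([f], GapParams("linear", 1, 1))
        assert report_chains(recs, min_score=30.0) == []
        kept = report_chains(recs, min_score=25.0)  # boundary kept
        assert len(kept) == 1

    def test_interior_fragment_heads_no_report(self):
        a = make_fragment(0, 0, 10, 0, 10, score=10)
        b = make_fragment(1, 10, 20, 10, 20, score=10)
        c = make_fragment(2, 20, 30, 20, 30, score=10)
        reports = report_chains(sweep_chain([a, b, c], GapParams("sop", 1, 0)))
        assert all(r.fragment_uids[0] != 1 for r in reports)

    def test_report_spans_cover_members(self):
        rng = random.Random(55)
        frags = random_instance(rng, 30)
        p = GapParams("sop", 0.5, 0.0)
        for rep in report_chains(sweep_chain(frags, p)):
            assert rep.span_x[0] < rep.span_x[1]
            assert rep.n_fragments == len(rep.fragment_uids)
            assert rep.fragment_uids == sorted(
                rep.fragment_uids,
                key=lambda u: next(f.beg_x for f in frags if f.uid == u),
            )
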