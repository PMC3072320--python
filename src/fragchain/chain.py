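"""Local fragment chaining by line sweep with sparse dynamic programming.

The sweep walks fragment start and end points in database order.  At a
start point it asks the model's range-maximum structure(s) for the best
*active* chain that may precede the fragment; the fragment is connected
only if that chain's score covers the gap cost (local chaining: a chain's
score never drops below its last fragment's own score).  At an end point
the fragment's chain becomes active: it is inserted keyed by its end
coordinates (or end diagonal) with the model's priority.

Linear costs need a single 'max-below' staircase keyed by the query end.
Sum-of-pair costs are piecewise linear in two octants: octant 1
(predecessor diagonal ≤ successor diagonal) uses a 2D range tree keyed by
(diagonal, query end); octant 2 (strictly larger diagonal) a 'max-above'
staircase keyed by the diagonal alone, since a strictly larger diagonal
together with the sweep order already implies query-side disjointness.
The better of the two candidates — by true recomputed value, not by the
transformed priority — wins.

Chains sharing the same first fragment form one group; only the best
chain of each group is reported.  :func:`brute_force_chain` is the O(n²)
reference DP used as the oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .fragments import ChainReport, Fragment
from .gapcost import (
    GapParams,
    gap_cost,
    is_chainable,
    priority_linear,
    priority_sop,
)
from .rmq import KeyUniverse, RangeTree2D, Staircase

__all__ = [
    "ChainRecord",
    "sweep_chain",
    "brute_force_chain",
    "connect_decision",
    "report_chains",
    "chain_members",
    "recompute_chain_score",
]


@dataclass(slots=True)
class ChainRecord:
    """Best local chain ending at ``frag``: score, predecessor, chain head."""

    frag: Fragment
    score: float
    pred: Optional["ChainRecord"] = None
    first: Optional[Fragment] = None

    def __post_init__(self) -> None:
        if self.first is None:
            self.first = self.frag


def connect_decision(pred_value: float) -> bool:
    """Connect iff the predecessor chain's score covers the gap cost.

    ``pred_value`` is predecessor score minus gap cost; on an exact tie
    the connection is made (the longer chain is preferred).
    """
    return pred_value >= 0


def _events(fragments: list[Fragment]) -> list[tuple[int, int, Fragment]]:
    """Start/end events in sweep order.

    End events are scheduled at the last covered base (end_x − 1) and start
    events before end events at equal coordinates, so a fragment ending
    exactly where another begins (half-open abutment) is active in time,
    while a one-base overlap is not.
    """
    ev: list[tuple[int, int, Fragment]] = []
    for f in fragments:
        ev.append((f.beg_x, 0, f))
        ev.append((f.end_x - 1, 1, f))
    ev.sort(key=lambda e: (e[0], e[1]))
    return ev


def _connect(rec: ChainRecord, cand: Optional[ChainRecord], p: GapParams) -> None:
    """Apply the connect decision to ``rec`` given the retrieved candidate."""
    if cand is None:
        return
    value = cand.score - gap_cost(cand.frag, rec.frag, p)
    # >= so that a zero-value connection still extends (tie rule)
    if connect_decision(value) and rec.frag.score + value >= rec.score:
        rec.score = rec.frag.score + value
        rec.pred = cand
        rec.first = cand.first


def _sweep_linear(fragments: list[Fragment], p: GapParams) -> list[ChainRecord]:
    universe_y = KeyUniverse(
        [f.end_y for f in fragments] + [f.beg_y for f in fragments]
    )
    stair = Staircase(universe_y, "max-below")
    records = {f.uid: ChainRecord(frag=f, score=f.score) for f in fragments}
    for _, kind, f in _events(fragments):
        rec = records[f.uid]
        if kind == 0:
            cand = stair.query(f.beg_y, inclusive=True)
            _connect(rec, cand[1] if cand else None, p)
        else:
            stair.insert(
                f.end_y, priority_linear(rec.score, f.end_x, f.end_y, p), rec
            )
    return [records[f.uid] for f in fragments]


def _sweep_sop(fragments: list[Fragment], p: GapParams) -> list[ChainRecord]:
    diags = [f.end_x - f.end_y for f in fragments] + [
        f.beg_x - f.beg_y for f in fragments
    ]
    universe_d = KeyUniverse(diags)
    universe_y = KeyUniverse(
        [f.end_y for f in fragments] + [f.beg_y for f in fragments]
    )
    octant1 = RangeTree2D(universe_d, universe_y)
    octant2 = Staircase(universe_d, "max-above")
    records = {f.uid: ChainRecord(frag=f, score=f.score) for f in fragments}
    for _, kind, f in _events(fragments):
        rec = records[f.uid]
        diag = (f.beg_x - f.beg_y) if kind == 0 else (f.end_x - f.end_y)
        if kind == 0:
            # octant 1: diagonal <= successor diagonal AND end_y <= beg_y
            cand1 = octant1.query(diag, f.beg_y, inclusive1=True, inclusive2=True)
            _connect(rec, cand1[1] if cand1 else None, p)
            # octant 2: diagonal strictly larger; query disjointness implied
            cand2 = octant2.query(diag, inclusive=False)
            _connect(rec, cand2[1] if cand2 else None, p)
        else:
            octant1.insert(
                diag, f.end_y, priority_sop(rec.score, f.end_x, f.end_y, p, 1), rec
            )
            octant2.insert(
                diag, priority_sop(rec.score, f.end_x, f.end_y, p, 2), rec
            )
    return [records[f.uid] for f in fragments]


def sweep_chain(fragments: list[Fragment], p: GapParams) -> list[ChainRecord]:
    """Chain one (query, subject, strand) group; one record per fragment.

    Returns records in input order.  Runs in O(n log n) time for linear
    costs and O(n log² n) for sum-of-pair costs (staircase sizes counted
    as their logarithmic expectation).
    """
    if not fragments:
        return []
    if len({f.group_key for f in fragments}) != 1:
        raise ValueError("sweep_chain expects fragments from a single group")
    if p.model == "linear":
        return _sweep_linear(fragments, p)
    return _sweep_sop(fragments, p)


def brute_force_chain(fragments: list[Fragment], p: GapParams) -> list[ChainRecord]:
    """Quadratic reference DP over fragments sorted by database end.

    Evaluates every chainable predecessor directly with the gap cost
    functions — no priorities, no octants — and applies the identical
    connect decision.  Intended for small n (tests); returns records in
    input order like :func:`sweep_chain`.
    """
    order = sorted(fragments, key=lambda f: f.end_x)
    records: dict[int, ChainRecord] = {}
    for f in order:
        rec = ChainRecord(frag=f, score=f.score)
        for g in order:
            if g.uid == f.uid or not is_chainable(g, f):
                continue
            prev = records[g.uid]
            value = prev.score - gap_cost(g, f, p)
            if connect_decision(value) and f.score + value >= rec.score:
                rec.score = f.score + value
                rec.pred = prev
                rec.first = prev.first
        records[f.uid] = rec
    return [records[f.uid] for f in fragments]


def chain_members(rec: ChainRecord) -> list[Fragment]:
    """Fragments of ``rec``'s chain in chain (ascending-coordinate) order."""
    out = []
    cur: Optional[ChainRecord] = rec
    while cur is not None:
        out.append(cur.frag)
        cur = cur.pred
    out.reverse()
    return out


def recompute_chain_score(members: list[Fragment], p: GapParams) -> float:
    """Chain score from first principles: Σ scores − Σ consecutive gap costs."""
    total = sum(f.score for f in members)
    for a, b in zip(members, members[1:]):
        total -= gap_cost(a, b, p)
    return total


def report_chains(
    records: list[ChainRecord],
    min_score: float = 0.0,
    p: Optional[GapParams] = None,
) -> list[ChainReport]:
    """Group chains by their first fragment and report each group's best.

    A fragment that only ever occurs in the interior of chains heads no
    group and is absent from the reports.  Chains scoring below
    ``min_score`` are dropped.  Reports are ordered by descending score.
    """
    best: dict[int, ChainRecord] = {}
    for rec in records:
        assert rec.first is not None
        head = rec.first.uid
        cur = best.get(head)
        if cur is None or rec.score > cur.score:
            best[head] = rec
    reports = []
    for rec in best.values():
        if rec.score < min_score:
            continue
        members = chain_members(rec)
        f0 = members[0]
        reports.append(
            ChainReport(
                query_id=f0.query_id,
                subject_id=f0.subject_id,
                strand=f0.strand,
                chain_score=rec.score,
                span_x=(min(f.beg_x for f in members), max(f.end_x for f in members)),
                span_y=(min(f.beg_y for f in members), max(f.end_y for f in members)),
                n_fragments=len(members),
                fragment_uids=[f.uid for f in members],
            )
        )
    reports.sort(key=lambda c: (-c.chain_score, c.subject_id, c.span_x[0]))
    return reports
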