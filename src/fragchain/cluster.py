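"""Output-preserving clustering along the database axis.

The database is usually much larger than the query, so a fragment group
often falls apart into bundles separated by stretches of database sequence
that no chain could ever bridge: the cheapest possible gap cost across the
stretch already exceeds any achievable chain score.  Splitting at such
stretches lets each cluster be chained separately with *identical* output,
bounding the live size of the sweep structures.

The split test between the current cluster's database frontier and the
next fragment uses two conservative bounds:

* ``max_score_bound`` — an upper bound on the score of any chain formed
  entirely from fragments scanned so far (only those can precede the
  split).  Realized as the running sum of fragment scores, optionally
  tightened by query length × best per-position score when the query
  length is known.
* ``max_y`` — an upper bound on the query-axis distance of any fragment
  pair in the group, realized as the group's global query extent
  (max end_y − min beg_y).  A bound over the *whole* group is required:
  under sum-of-pair costs a cheap bridge needs a matching query-side
  distance, which a fragment scanned after the split point may still
  provide.

For a database gap D the cheapest bridge costs at least λ·D (linear) or
λ·(D − max_y) (sum-of-pair, achieved when the query distance matches as
far as possible), giving the thresholds below.  With λ = 0 the database
axis is free and no split is ever safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .fragments import Fragment
from .gapcost import GapParams

__all__ = ["ClusterState", "cluster_gap_threshold", "cluster_fragments"]


@dataclass(slots=True)
class ClusterState:
    """Running bounds during the clustering scan (both non-decreasing)."""

    max_score_bound: float = 0.0
    max_y: int = 0

    def add_score(self, score: float) -> None:
        self.max_score_bound += score


def cluster_gap_threshold(state: ClusterState, p: GapParams) -> float:
    """Smallest database gap D whose cheapest bridge always exceeds the bound.

    Returns +inf when λ = 0 (splitting is never safe).
    """
    if p.lam <= 0:
        return math.inf
    base = math.floor(state.max_score_bound / p.lam) + 1
    if p.model == "sop":
        return base + state.max_y
    return base


def cluster_fragments(
    fragments: list[Fragment],
    p: GapParams,
    query_len: Optional[int] = None,
) -> list[list[Fragment]]:
    """Split one group into clusters chainable independently, same output.

    ``fragments`` need not be pre-sorted; the scan runs over them in
    ascending database start order but the returned clusters preserve the
    original relative order of their members.  ``query_len``, when given,
    caps the score bound at query length × the best per-position fragment
    score seen so far.
    """
    if not fragments:
        return []
    order = sorted(fragments, key=lambda f: f.beg_x)
    global_max_y = max(f.end_y for f in fragments) - min(f.beg_y for f in fragments)
    state = ClusterState(max_score_bound=0.0, max_y=global_max_y)
    best_per_pos = 0.0

    clusters: list[list[Fragment]] = []
    current: list[Fragment] = []
    frontier = -1  # max end_x of the current cluster
    for f in order:
        if current and f.beg_x - frontier > cluster_gap_threshold(state, p):
            clusters.append(current)
            current = []
        current.append(f)
        frontier = max(frontier, f.end_x)
        state.add_score(f.score)
        if query_len is not None:
            best_per_pos = max(best_per_pos, f.score / f.len_y)
            state.max_score_bound = min(
                state.max_score_bound, query_len * best_per_pos
            )
    clusters.append(current)
    # restore each cluster's original input order (clusters are disjoint on x,
    # so membership is unaffected by the sort)
    by_uid = {f.uid: i for i, f in enumerate(fragments)}
    for c in clusters:
        c.sort(key=lambda f: by_uid[f.uid])
    return clusters
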