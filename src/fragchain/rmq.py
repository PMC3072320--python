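"""Range-maximum-query structures for the chaining line sweep.

The sweep needs two queries over the set of *active* chains:

* 1D: the maximum-priority chain whose key (query end or diagonal) lies
  below/above a bound — answered by a :class:`Staircase`, a dominance-
  pruned map over a fixed, rank-condensed key universe in which range-max
  reduces to a single predecessor (or successor) lookup.
* 2D (sum-of-pair octant 1): maximum priority subject to bounds on both
  the diagonal and the query end — answered by a :class:`RangeTree2D`, a
  static primary tree over the first key dimension whose nodes each hold a
  staircase over the second dimension for their canonical subset.

Both universes are fixed before the sweep by rank-condensing every value
that can ever be inserted or queried.  The module also provides the
linear-scan oracles that the test suite replays against the structures.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right, insort
from typing import Any, Hashable, Iterable, Optional

__all__ = [
    "KeyUniverse",
    "Staircase",
    "RangeTree2D",
    "oracle_scan_1d",
    "oracle_scan_2d",
]

Entry = tuple[float, Any]  # (priority, payload)


class KeyUniverse:
    """A fixed, sorted, distinct key domain; maps keys to dense ranks.

    Every key later inserted into or used as a bound by a structure built
    over this universe must be a member (rank condensation).
    """

    __slots__ = ("keys", "_rank")

    def __init__(self, keys: Iterable[Hashable]):
        self.keys = sorted(set(keys))
        self._rank = {k: i for i, k in enumerate(self.keys)}

    def __len__(self) -> int:
        return len(self.keys)

    def rank(self, key: Hashable) -> int:
        try:
            return self._rank[key]
        except KeyError:
            raise KeyError(f"key {key!r} not in universe") from None


class Staircase:
    """1D dominance staircase answering strict or inclusive range-max queries.

    direction 'max-below': queries ask for the best priority at key < bound
    (or ≤ with ``inclusive``); an entry dominates another if its key is
    smaller-or-equal and its priority is at least as high, so the stored
    entries have priorities strictly increasing in key and the answer is a
    predecessor lookup.  direction 'max-above' is the mirror image.

    Dominated entries are removed eagerly at insert time, which keeps every
    query O(log size) and bounds total removal work by total inserts.
    """

    __slots__ = ("universe", "direction", "_ranks", "_entries")

    def __init__(self, universe: KeyUniverse, direction: str = "max-below"):
        if direction not in ("max-below", "max-above"):
            raise ValueError(f"bad direction {direction!r}")
        self.universe = universe
        self.direction = direction
        self._ranks: list[int] = []  # sorted stored ranks
        self._entries: dict[int, Entry] = {}

    def __len__(self) -> int:
        return len(self._ranks)

    def items(self) -> list[tuple[Hashable, float, Any]]:
        """Stored (key, priority, payload) triples in key order."""
        return [
            (self.universe.keys[r], *self._entries[r]) for r in self._ranks
        ]

    def insert(self, key: Hashable, priority: float, payload: Any = None) -> bool:
        """Insert unless dominated; evict entries the new one dominates.

        Returns True if the entry was stored.
        """
        r = self.universe.rank(key)
        ranks = self._ranks
        i = bisect_left(ranks, r)
        if self.direction == "max-below":
            # dominating candidates sit at rank <= r: the one at position i-1,
            # or an existing entry at r itself
            if i < len(ranks) and ranks[i] == r:
                if self._entries[ranks[i]][0] >= priority:
                    return False
            if i > 0 and self._entries[ranks[i - 1]][0] >= priority:
                return False
            # evict entries at rank >= r with priority <= ours
            j = i
            while j < len(ranks) and self._entries[ranks[j]][0] <= priority:
                del self._entries[ranks[j]]
                j += 1
            del ranks[i:j]
        else:
            if i < len(ranks) and ranks[i] == r:
                if self._entries[ranks[i]][0] >= priority:
                    return False
                del self._entries[ranks[i]]
                del ranks[i]
            elif i < len(ranks) and self._entries[ranks[i]][0] >= priority:
                return False
            # evict entries at rank <= r with priority <= ours
            j = i
            while j > 0 and self._entries[ranks[j - 1]][0] <= priority:
                del self._entries[ranks[j - 1]]
                j -= 1
            del ranks[j:i]
            i = j
        insort(ranks, r)
        self._entries[r] = (priority, payload)
        return True

    def query(self, bound: Hashable, inclusive: bool = False) -> Optional[Entry]:
        """Best (priority, payload) at key < bound ('max-below', strict by
        default; ≤ with ``inclusive``), or key > bound / ≥ for 'max-above'.
        Returns None if the range holds no entry."""
        b = self.universe.rank(bound)
        ranks = self._ranks
        if self.direction == "max-below":
            i = (bisect_right(ranks, b) if inclusive else bisect_left(ranks, b)) - 1
            if i < 0:
                return None
            return self._entries[ranks[i]]
        i = bisect_left(ranks, b) if inclusive else bisect_right(ranks, b)
        if i >= len(ranks):
            return None
        return self._entries[ranks[i]]

    def check_invariant(self) -> None:
        """Assert the staircase shape (monotone priorities along keys)."""
        prios = [self._entries[r][0] for r in self._ranks]
        if self.direction == "max-below":
            assert all(a < b for a, b in zip(prios, prios[1:])), "not increasing"
        else:
            assert all(a > b for a, b in zip(prios, prios[1:])), "not decreasing"


class RangeTree2D:
    """Static range tree over dimension 1, staircases over dimension 2.

    The primary structure is an implicit, array-backed balanced tree over
    the rank-condensed first-dimension universe.  Each node owns a
    'max-below' staircase over the second dimension holding the elements of
    its canonical subset, so an inserted element appears in exactly the
    nodes on its leaf-to-root path (O(log U) of them).  A query decomposes
    the first-dimension prefix into at most ceil(log2 U) + 1 canonical
    nodes top-down and takes the best staircase answer among them; the
    ``query_lookups`` counter records staircase lookups for complexity
    audits.
    """

    __slots__ = ("universe1", "universe2", "_size", "_stairs", "query_lookups")

    def __init__(self, universe1: KeyUniverse, universe2: KeyUniverse):
        self.universe1 = universe1
        self.universe2 = universe2
        size = 1
        while size < max(len(universe1), 1):
            size *= 2
        self._size = size
        # staircases allocated lazily: most nodes of a sparse instance stay empty
        self._stairs: dict[int, Staircase] = {}
        self.query_lookups = 0

    def insert(self, key1: Hashable, key2: Hashable, priority: float, payload: Any = None) -> None:
        node = self._size + self.universe1.rank(key1)
        while node >= 1:
            stair = self._stairs.get(node)
            if stair is None:
                stair = self._stairs[node] = Staircase(self.universe2, "max-below")
            stair.insert(key2, priority, payload)
            node //= 2

    def query(
        self,
        bound1: Hashable,
        bound2: Hashable,
        inclusive1: bool = True,
        inclusive2: bool = False,
    ) -> Optional[Entry]:
        """Best element with key1 ≤ bound1 (or < with ``inclusive1=False``)
        and key2 < bound2 (≤ with ``inclusive2``)."""
        r1 = self.universe1.rank(bound1)
        if not inclusive1:
            r1 -= 1
        if r1 < 0:
            return None
        best: Optional[Entry] = None
        node, lo, hi = 1, 0, self._size - 1
        while True:
            stair = self._stairs.get(node)
            if hi <= r1:
                if stair is not None:
                    self.query_lookups += 1
                    cand = stair.query(bound2, inclusive=inclusive2)
                    if cand is not None and (best is None or cand[0] > best[0]):
                        best = cand
                break
            if stair is None:
                break  # empty subtree: nothing below either child
            mid = (lo + hi) // 2
            if r1 <= mid:
                node, hi = 2 * node, mid
            else:
                left = self._stairs.get(2 * node)
                if left is not None:
                    self.query_lookups += 1
                    cand = left.query(bound2, inclusive=inclusive2)
                    if cand is not None and (best is None or cand[0] > best[0]):
                        best = cand
                node, lo = 2 * node + 1, mid + 1
        return best

    def node_staircases(self) -> list[Staircase]:
        return list(self._stairs.values())


def oracle_scan_1d(
    elements: Iterable[tuple[Hashable, float, Any]],
    bound: Hashable,
    direction: str = "max-below",
    inclusive: bool = False,
) -> Optional[Entry]:
    """Reference semantics for :meth:`Staircase.query`: plain linear scan."""
    best: Optional[Entry] = None
    for key, priority, payload in elements:
        if direction == "max-below":
            ok = key <= bound if inclusive else key < bound
        else:
            ok = key >= bound if inclusive else key > bound
        if ok and (best is None or priority > best[0]):
            best = (priority, payload)
    return best


def oracle_scan_2d(
    elements: Iterable[tuple[Hashable, Hashable, float, Any]],
    bound1: Hashable,
    bound2: Hashable,
    inclusive1: bool = True,
    inclusive2: bool = False,
) -> Optional[Entry]:
    """Reference semantics for :meth:`RangeTree2D.query`."""
    best: Optional[Entry] = None
    for key1, key2, priority, payload in elements:
        ok1 = key1 <= bound1 if inclusive1 else key1 < bound1
        ok2 = key2 <= bound2 if inclusive2 else key2 < bound2
        if ok1 and ok2 and (best is None or priority > best[0]):
            best = (priority, payload)
    return best
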