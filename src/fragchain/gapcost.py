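"""Gap cost models and the priority transformations of the sweep.

Two penalty models for the gap between consecutive chain members, with
inter-fragment distances d_x (database) and d_y (query):

* linear:       g1(d)   = λ·d_x + ε·d_y
* sum-of-pair:  g_sop(d) = λ·|d_x − d_y| + ε·min(d_x, d_y)

In the sum-of-pair model λ is the penalty for aligning an anonymous
character against a gap position and ε the penalty for aligning two
anonymous characters; with ε = 0 only the *difference* of the two
distances is penalized, which suits homologs made of short conserved
blocks separated by variable-length spacers.  The closed form is the
cheapest alignment of the two anonymous blocks whenever ε ≤ 2λ.

The priority transformations re-express ``chain score − gap cost`` as
``priority − (term depending only on the successor)``, so the optimal
predecessor is simply the range-maximum over stored priorities.  The
sum-of-pair cost is piecewise linear, so it needs one transformation per
octant: octant 1 covers predecessor diagonals x−y ≤ successor diagonal
(d_x ≥ d_y), octant 2 the strict complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

from .fragments import Fragment

__all__ = [
    "GapParams",
    "GapDistances",
    "is_chainable",
    "gap_distances",
    "gap_linear",
    "gap_sop",
    "gap_cost",
    "priority_linear",
    "priority_sop",
]

MODELS = ("linear", "sop")


@dataclass(frozen=True, slots=True)
class GapParams:
    """Gap model selector and weights λ (lam) and ε (eps), both ≥ 0."""

    model: str = "sop"
    lam: float = 1.0
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.lam < 0 or self.eps < 0:
            raise ValueError("gap weights must be non-negative")
        if self.model == "sop" and self.eps > 2 * self.lam:
            # closed form then exceeds the cheapest anonymous-block alignment
            warnings.warn(
                "sum-of-pair gap costs with eps > 2*lam lose their "
                "alignment interpretation (eps <= 2*lam recommended)",
                stacklevel=2,
            )


class GapDistances(NamedTuple):
    """Characters strictly between two chained fragments on each axis."""

    d_x: int
    d_y: int


def is_chainable(pred: Fragment, succ: Fragment) -> bool:
    """True iff ``succ`` may follow ``pred``: disjoint and colinear on both axes.

    With half-open intervals equality means abutment (zero characters
    between the blocks), which is allowed.  Fragments overlapping on either
    sequence — even only on the query — can never be chained.
    """
    return pred.end_x <= succ.beg_x and pred.end_y <= succ.beg_y


def gap_distances(pred: Fragment, succ: Fragment) -> GapDistances:
    """Distances between chainable fragments; caller guarantees chainability."""
    d_x = succ.beg_x - pred.end_x
    d_y = succ.beg_y - pred.end_y
    if d_x < 0 or d_y < 0:
        raise ValueError("gap_distances called on non-chainable pair")
    return GapDistances(d_x, d_y)


def gap_linear(d: GapDistances, p: GapParams) -> float:
    """Linear gap cost λ·d_x + ε·d_y (λ weights the database axis)."""
    return p.lam * d.d_x + p.eps * d.d_y


def gap_sop(d: GapDistances, p: GapParams) -> float:
    """Sum-of-pair gap cost λ·|d_x − d_y| + ε·min(d_x, d_y)."""
    return p.lam * abs(d.d_x - d.d_y) + p.eps * min(d.d_x, d.d_y)


def gap_cost(pred: Fragment, succ: Fragment, p: GapParams) -> float:
    """Model-dispatched gap cost between two chainable fragments."""
    d = gap_distances(pred, succ)
    return gap_linear(d, p) if p.model == "linear" else gap_sop(d, p)


def priority_linear(chain_score: float, end_x: int, end_y: int, p: GapParams) -> float:
    """Priority under linear costs: score + λ·end_x + ε·end_y.

    For a fixed successor start (X', Y'):
    ``score − g1 = priority − (λ·X' + ε·Y')``, so the max-priority active
    chain is the optimal predecessor.
    """
    return chain_score + p.lam * end_x + p.eps * end_y


def priority_sop(
    chain_score: float, end_x: int, end_y: int, p: GapParams, octant: int
) -> float:
    """Octant priority under sum-of-pair costs.

    Octant 1 (predecessor diagonal end_x − end_y ≤ successor diagonal,
    i.e. d_x ≥ d_y): ``score + λ·end_x + (ε−λ)·end_y``.
    Octant 2 (strictly larger predecessor diagonal, d_x < d_y):
    ``score + (ε−λ)·end_x + λ·end_y``.
    Within its octant each satisfies
    ``score − g_sop = priority − c(X', Y')`` with c independent of the
    predecessor; the boundary d_x = d_y belongs to octant 1.
    """
    if octant == 1:
        return chain_score + p.lam * end_x + (p.eps - p.lam) * end_y
    if octant == 2:
        return chain_score + (p.eps - p.lam) * end_x + p.lam * end_y
    raise ValueError(f"octant must be 1 or 2, got {octant}")
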