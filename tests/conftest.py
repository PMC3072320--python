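"""Shared fixtures: random fragment instances for oracle comparisons."""

from __future__ import annotations

import random

import pytest

from fragchain import Fragment, GapParams


def make_fragment(
    uid: int,
    beg_x: int,
    end_x: int,
    beg_y: int,
    end_y: int,
    score: float = 1.0,
    query_id: str = "q",
    subject_id: str = "s",
    strand: str = "+",
) -> Fragment:
    return Fragment(
        uid=uid,
        query_id=query_id,
        subject_id=subject_id,
        strand=strand,
        beg_x=beg_x,
        end_x=end_x,
        beg_y=beg_y,
        end_y=end_y,
        score=score,
    )


def random_instance(
    rng: random.Random,
    n: int,
    coord_max: int = 5000,
    len_max: int = 100,
    score_max: float = 100.0,
) -> list[Fragment]:
    """n fragments with uniform starts, uniform lengths, positive scores."""
    frags = []
    for i in range(n):
        bx = rng.randrange(0, coord_max)
        by = rng.randrange(0, coord_max)
        frags.append(
            make_fragment(
                i,
                bx,
                bx + rng.randrange(1, len_max),
                by,
                by + rng.randrange(1, len_max),
                score=rng.uniform(1.0, score_max),
            )
        )
    return frags


def random_params(rng: random.Random, model: str) -> GapParams:
    """Random weights with eps <= 2*lam (the alignment-interpretable range)."""
    lam = rng.uniform(0.01, 2.0)
    eps = rng.uniform(0.0, 2.0 * lam)
    return GapParams(model=model, lam=lam, eps=eps)


def bundled_instance(rng: random.Random, query_len: int = 1000) -> list[Fragment]:
    """Several fragment bundles separated by huge database gaps.

    Exercises the clustering pre-pass: the gaps between bundles dwarf any
    achievable chain score, the gaps within do not.
    """
    frags: list[Fragment] = []
    uid = 0
    xoff = 0
    for _ in range(rng.randrange(1, 5)):
        xoff += rng.randrange(0, 500_000)
        for _ in range(rng.randrange(1, 15)):
            bx = xoff + rng.randrange(0, 3000)
            by = rng.randrange(0, query_len)
            frags.append(
                make_fragment(
                    uid,
                    bx,
                    bx + rng.randrange(1, 100),
                    by,
                    by + rng.randrange(1, 100),
                    score=rng.uniform(1.0, 50.0),
                )
            )
            uid += 1
        xoff += 3000
    return frags


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260)
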