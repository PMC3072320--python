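"""Synthetic fragment sets with controlled structure.

Two generators:

* :func:`generate_uniform_fragments` — the performance-test distribution:
  fixed-length fragments uniformly placed on a short query and a much
  larger virtual database, with truncated-normal scores.  Emulates the
  hit density of a sensitive seed search without any sequence content.
* :func:`generate_scattered_homology` — plants one colinear chain of
  conserved blocks whose database- and query-side spacings agree up to a
  jitter, buried among uniform decoys.  With zero jitter the planted
  chain has zero sum-of-pair gap cost at ε = 0 even though its absolute
  gaps are large — the scenario in which sum-of-pair costs beat linear
  ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragments import Fragment

__all__ = ["SimParams", "generate_uniform_fragments", "generate_scattered_homology"]


@dataclass(frozen=True, slots=True)
class SimParams:
    """Uniform-generator settings.

    Defaults mirror the performance-test setup: length-100 fragments on a
    1 kb query, sampled from a virtual 100 kb database, scores normal.
    The score distribution's mean/sd are not dictated by that setup; the
    defaults (20 ± 5, truncated positive) are an arbitrary but documented
    choice.  A given seed fixes the full output.
    """

    n_fragments: int = 1000
    frag_len: int = 100
    query_len: int = 1000
    db_len: int = 100_000
    score_mean: float = 20.0
    score_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.frag_len <= self.query_len <= self.db_len):
            raise ValueError("need 0 < frag_len <= query_len <= db_len")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal scores resampled until strictly positive."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def generate_uniform_fragments(sp: SimParams) -> list[Fragment]:
    """Fragments uniformly placed on query and database, i.i.d. scores."""
    rng = np.random.default_rng(sp.seed)
    beg_y = rng.integers(0, sp.query_len - sp.frag_len + 1, size=sp.n_fragments)
    beg_x = rng.integers(0, sp.db_len - sp.frag_len + 1, size=sp.n_fragments)
    scores = _truncated_normal(rng, sp.score_mean, sp.score_sd, sp.n_fragments)
    return [
        Fragment(
            uid=i,
            query_id="query",
            subject_id="db",
            strand="+",
            beg_x=int(beg_x[i]),
            end_x=int(beg_x[i]) + sp.frag_len,
            beg_y=int(beg_y[i]),
            end_y=int(beg_y[i]) + sp.frag_len,
            score=float(scores[i]),
        )
        for i in range(sp.n_fragments)
    ]


def generate_scattered_homology(
    n_blocks: int,
    block_len: int = 20,
    inter_block_jitter: int = 0,
    decoy_rate: float = 2.0,
    seed: int = 0,
    gap_range: tuple[int, int] = (50, 200),
    decoy_score_range: tuple[float, float] = (1.0, 5.0),
) -> tuple[list[Fragment], list[int]]:
    """Plant a colinear block chain among uniform decoys.

    The planted blocks score ``block_len`` each (the score-equals-length
    convention).  Consecutive blocks are separated by a random spacer drawn
    from ``gap_range`` on the query; the database spacer differs from it by
    at most ``inter_block_jitter``.  ``decoy_rate`` × ``n_blocks`` decoys of
    the same length with low scores are scattered uniformly over the span;
    they may overlap the planted chain.

    Returns the fragments (planted first, uids 0..n_blocks−1) and the
    ground-truth uid list of the planted chain.
    """
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    if inter_block_jitter > gap_range[0]:
        raise ValueError("jitter may not exceed the smallest spacer")
    rng = np.random.default_rng(seed)
    gaps_y = rng.integers(gap_range[0], gap_range[1] + 1, size=n_blocks - 1)
    jit = (
        rng.integers(-inter_block_jitter, inter_block_jitter + 1, size=n_blocks - 1)
        if inter_block_jitter > 0
        else np.zeros(n_blocks - 1, dtype=int)
    )
    gaps_x = gaps_y + jit

    fragments: list[Fragment] = []
    y = 0
    x = x0 = int(rng.integers(0, 5001))  # database offset of the homologous region
    truth: list[int] = []
    for i in range(n_blocks):
        fragments.append(
            Fragment(
                uid=i,
                query_id="query",
                subject_id="db",
                strand="+",
                beg_x=x,
                end_x=x + block_len,
                beg_y=y,
                end_y=y + block_len,
                score=float(block_len),
            )
        )
        truth.append(i)
        if i < n_blocks - 1:
            x += block_len + int(gaps_x[i])
            y += block_len + int(gaps_y[i])

    span_x = x + block_len
    span_y = y + block_len
    n_decoys = int(round(decoy_rate * n_blocks))
    if n_decoys:
        dx = x0 + rng.integers(0, span_x - x0 - block_len + 1, size=n_decoys)
        dy = rng.integers(0, span_y - block_len + 1, size=n_decoys)
        ds = rng.uniform(decoy_score_range[0], decoy_score_range[1], size=n_decoys)
        for j in range(n_decoys):
            fragments.append(
                Fragment(
                    uid=n_blocks + j,
                    query_id="query",
                    subject_id="db",
                    strand="+",
                    beg_x=int(dx[j]),
                    end_x=int(dx[j]) + block_len,
                    beg_y=int(dy[j]),
                    end_y=int(dy[j]) + block_len,
                    score=float(ds[j]),
                )
            )
    return fragments, truth
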