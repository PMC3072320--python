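# fragchain

Local fragment chaining for seed-based homology search, with both **linear**
and **sum-of-pair** gap cost models.

Sensitive BLAST searches for short, weakly conserved sequences — distant
homologs of structured RNAs such as box H/ACA snoRNAs are the canonical
case — have to run with tiny word sizes and huge expectation values, and
then dump millions of short match fragments. Chaining is the
post-processing step that turns that dump into a ranked list of candidate
loci: it connects fragments that are **colinear** (same order on query and
database), **disjoint** on both sequences, and close enough that their
scores pay for the gaps between them.

`fragchain` reads fragments from BLAST tabular output (`-outfmt 6` /
classic `-m 8`) or a generic TSV, chains each (query, subject, strand)
combination independently, and reports the best-scoring local chain per
chain family.

## The model

A fragment *f* matches database interval [*f*<sub>beg</sub>.*x*,
*f*<sub>end</sub>.*x*) to query interval [*f*<sub>beg</sub>.*y*,
*f*<sub>end</sub>.*y*) with score *f*.score ≥ 0. For consecutive chain
members *f* → *f′* with gap widths *d<sub>x</sub>* and *d<sub>y</sub>*
(characters strictly between the matched blocks), the gap cost is one of

* **linear**:  g₁ = λ·*d<sub>x</sub>* + ε·*d<sub>y</sub>*
* **sum-of-pair**:  g<sub>sop</sub> = λ·|*d<sub>x</sub>* − *d<sub>y</sub>*| + ε·min(*d<sub>x</sub>*, *d<sub>y</sub>*)

In the sum-of-pair model λ penalizes an anonymous character aligned
against a gap and ε two anonymous characters aligned with each other; with
ε = 0 only the *difference* of the distances is penalized, so conserved
blocks separated by long but equally long spacers chain for free — exactly
the geometry of scattered-homology families.

A chain's score is the sum of its fragment scores minus its gap costs.
Chaining is **local**: a fragment connects to the best predecessor chain
only if that chain's score covers the gap cost, so a chain's score never
drops below its last fragment's own score.

The optimal chains for all *n* fragments are computed by sparse dynamic
programming: a line sweep over fragment start/end points in database
order, with range-maximum queries over the set of *active* chains.
Priorities are transformed so the optimal predecessor is the range
maximum — one dominance staircase for linear costs, and for sum-of-pair
costs a (diagonal, query-end) range tree plus a diagonal staircase, one
per linearity octant of the cost. A clustering pre-pass splits fragment
groups at database gaps that provably no chain can bridge, bounding the
sweep's working set without changing any output.

## Worked example

Generate a planted scattered homology — four conserved blocks of length
20 whose query- and database-side spacings agree exactly, plus four
low-scoring decoys — and chain it:

```python
from fragchain import generate_scattered_homology, write_fragment_tsv

frags, truth = generate_scattered_homology(
    n_blocks=4, block_len=20, inter_block_jitter=0, decoy_rate=1.0, seed=3)
with open("demo.tsv", "w") as fh:
    write_fragment_tsv(frags, fh)
```

```console
$ fragchain -i demo.tsv -m sop -l 0.5 -e 0 -s 30 --members -v
fragchain: 8 fragments, 1 groups, 1 clusters, 1 chains >= 30
#query_id  subject_id  strand  chain_score  q_start  q_end  s_start  s_end  n_fragments  fragment_uids
query      db          +       80.0000      1        391    1185     1575   4            0;1;2;3
```

The four planted blocks (uids 0–3) chain into a single local chain with
score 80 = 4 × 20: the spacers between blocks are up to ~180 nt long, but
because their lengths agree on both sequences the sum-of-pair cost with
ε = 0 is zero. Under linear costs every one of those nucleotides is paid
for, and the same input yields no chain at all above score 30:

```console
$ fragchain -i demo.tsv -m linear -l 1 -e 1 -s 30 --members
#query_id  subject_id  strand  chain_score  q_start  q_end  s_start  s_end  n_fragments  fragment_uids
```

(Columns are tab-separated in the real output; coordinates print 1-based
inclusive.)

For BLAST input, `-f blast8 --score-from length` scores each hit by its
alignment length; a typical screening call is

```sh
fragchain -i hits.blast8 -f blast8 -m sop -l 0.5 -e 0 -s 30 -o chains.tsv
```

## Layout

| module                  | contents                                                     |
|-------------------------|--------------------------------------------------------------|
| `fragchain.fragments`   | `Fragment`/`ChainReport`, BLAST-tabular and TSV I/O, grouping |
| `fragchain.gapcost`     | both gap models, chainability, priority transformations      |
| `fragchain.rmq`         | dominance staircase, 2D range tree, linear-scan oracles      |
| `fragchain.chain`       | the line sweep, the quadratic reference DP, reporting        |
| `fragchain.cluster`     | output-preserving clustering pre-pass                        |
| `fragchain.synthetic`   | uniform and planted-homology fragment generators             |
| `fragchain.cli`         | the `fragchain` command                                      |

See `docs/methods.md` for the algorithmic details and design choices.
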