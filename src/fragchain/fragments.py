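"""Fragment containers and text I/O.

A *fragment* is one scored local match between an interval on a database
sequence (the x axis) and an interval on a query sequence (the y axis) —
typically a single BLAST hit.  Internally all coordinates are 0-based
half-open; BLAST tabular input and every printed report are 1-based
inclusive, the convention of the surrounding ecosystem.

Fragments from different (query, subject, strand) combinations are never
chained together; :func:`partition_by_group` performs that split.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

__all__ = [
    "Fragment",
    "ChainReport",
    "FragmentParseError",
    "read_blast_tabular",
    "read_fragment_tsv",
    "write_fragment_tsv",
    "partition_by_group",
    "write_chains",
    "write_bed6",
]

SCORE_MODES = ("bitscore", "length", "identity_x_length")


class FragmentParseError(ValueError):
    """Raised for malformed fragment input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(slots=True)
class Fragment:
    """One scored match with half-open coordinates on database (x) and query (y).

    Attributes
    ----------
    uid:
        Stable 0-based input index; distinct even for coordinate-identical
        fragments.
    beg_x, end_x:
        Database interval, 0-based half-open (``beg_x < end_x``).
    beg_y, end_y:
        Query interval, 0-based half-open.
    score:
        Non-negative fragment score.
    """

    uid: int
    query_id: str
    subject_id: str
    strand: str
    beg_x: int
    end_x: int
    beg_y: int
    end_y: int
    score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.beg_x < self.end_x and self.beg_y < self.end_y):
            raise ValueError(
                f"fragment uid={self.uid} is empty on one axis: "
                f"x=[{self.beg_x},{self.end_x}) y=[{self.beg_y},{self.end_y})"
            )
        if self.beg_x < 0 or self.beg_y < 0:
            raise ValueError(f"fragment uid={self.uid} has negative coordinates")
        if self.score < 0:
            raise ValueError(f"fragment uid={self.uid} has negative score")

    @property
    def len_x(self) -> int:
        return self.end_x - self.beg_x

    @property
    def len_y(self) -> int:
        return self.end_y - self.beg_y

    @property
    def group_key(self) -> tuple[str, str, str]:
        return (self.query_id, self.subject_id, self.strand)


@dataclass(slots=True)
class ChainReport:
    """A reported local chain: colinear, disjoint fragments and their score.

    ``chain_score`` equals the sum of member fragment scores minus the gap
    costs between consecutive members and is recomputable from
    ``fragment_uids`` plus the gap parameters used.
    Spans are half-open like fragment coordinates.
    """

    query_id: str
    subject_id: str
    strand: str
    chain_score: float
    span_x: tuple[int, int]
    span_y: tuple[int, int]
    n_fragments: int
    fragment_uids: list[int] = field(default_factory=list)


def _iter_data_lines(stream: Iterable[str]) -> Iterator[tuple[int, str]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def read_blast_tabular(
    stream: Iterable[str],
    score_mode: str = "length",
    strict: bool = True,
) -> list[Fragment]:
    """Read fragments from classic BLAST tabular output (-m 8 / outfmt 6).

    Expected columns (tab-separated, >= 12): qseqid, sseqid, pident, length,
    mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore; all
    coordinates 1-based inclusive.  Subject hits with ``sstart > send`` are
    minus-strand: coordinates are swapped and the fragment labeled '-'.

    Parameters
    ----------
    score_mode:
        ``"length"`` scores each hit by its alignment length (the scoring
        used for the snoRNA screens this tool targets), ``"bitscore"`` takes
        column 12, ``"identity_x_length"`` the identity fraction times the
        length.
    strict:
        If True, any malformed line raises :class:`FragmentParseError`;
        otherwise such lines are reported on stderr and skipped.
        Non-numeric coordinates are always fatal.
    """
    if score_mode not in SCORE_MODES:
        raise ValueError(f"unknown score_mode {score_mode!r}; pick one of {SCORE_MODES}")
    fragments: list[Fragment] = []
    uid = 0
    for lineno, line in _iter_data_lines(stream):
        cols = line.split("\t")
        if len(cols) < 12:
            err = FragmentParseError(
                lineno, f"expected >= 12 tab-separated columns, got {len(cols)}"
            )
            if strict:
                raise err
            print(f"skipping malformed {err}", file=sys.stderr)
            continue
        qid, sid = cols[0], cols[1]
        try:
            qstart, qend = int(cols[6]), int(cols[7])
            sstart, send = int(cols[8]), int(cols[9])
        except ValueError as exc:
            raise FragmentParseError(lineno, f"non-numeric coordinate: {exc}") from None
        try:
            pident = float(cols[2])
            length = float(cols[3])
            bitscore = float(cols[11])
        except ValueError as exc:
            err = FragmentParseError(lineno, f"non-numeric field: {exc}")
            if strict:
                raise err from None
            print(f"skipping malformed {err}", file=sys.stderr)
            continue
        strand = "+"
        if sstart > send:
            sstart, send = send, sstart
            strand = "-"
        if qstart > qend:
            err = FragmentParseError(lineno, f"qstart > qend ({qstart} > {qend})")
            if strict:
                raise err
            print(f"skipping malformed {err}", file=sys.stderr)
            continue
        if score_mode == "length":
            score = length
        elif score_mode == "bitscore":
            score = bitscore
        else:
            score = pident / 100.0 * length
        fragments.append(
            Fragment(
                uid=uid,
                query_id=qid,
                subject_id=sid,
                strand=strand,
                beg_x=sstart - 1,
                end_x=send,
                beg_y=qstart - 1,
                end_y=qend,
                score=score,
            )
        )
        uid += 1
    return fragments


def read_fragment_tsv(stream: Iterable[str]) -> list[Fragment]:
    """Read the generic fragment TSV.

    Columns: query_id, subject_id, score, beg_y, end_y, beg_x, end_x
    (coordinates 1-based inclusive; optional '#'-prefixed header).  An
    optional 8th column carries the strand ('+'/'-'); absent means '+'.
    """
    fragments: list[Fragment] = []
    uid = 0
    for lineno, line in _iter_data_lines(stream):
        cols = line.split("\t")
        if len(cols) < 7:
            raise FragmentParseError(lineno, f"expected >= 7 columns, got {len(cols)}")
        qid, sid = cols[0], cols[1]
        try:
            score = float(cols[2])
            beg_y, end_y = int(cols[3]), int(cols[4])
            beg_x, end_x = int(cols[5]), int(cols[6])
        except ValueError as exc:
            raise FragmentParseError(lineno, f"non-numeric field: {exc}") from None
        if end_y < beg_y or end_x < beg_x:
            raise FragmentParseError(
                lineno, f"end before begin: y=[{beg_y},{end_y}] x=[{beg_x},{end_x}]"
            )
        strand = cols[7] if len(cols) > 7 else "+"
        try:
            fragments.append(
                Fragment(
                    uid=uid,
                    query_id=qid,
                    subject_id=sid,
                    strand=strand,
                    beg_x=beg_x - 1,
                    end_x=end_x,
                    beg_y=beg_y - 1,
                    end_y=end_y,
                    score=score,
                )
            )
        except ValueError as exc:
            raise FragmentParseError(lineno, str(exc)) from None
        uid += 1
    return fragments


def write_fragment_tsv(fragments: Iterable[Fragment], stream: TextIO) -> None:
    """Write fragments in the generic TSV format (round-trips with the reader)."""
    stream.write("#query_id\tsubject_id\tscore\tq_start\tq_end\ts_start\ts_end\tstrand\n")
    for f in fragments:
        stream.write(
            f"{f.query_id}\t{f.subject_id}\t{f.score!r}\t"
            f"{f.beg_y + 1}\t{f.end_y}\t{f.beg_x + 1}\t{f.end_x}\t{f.strand}\n"
        )


def partition_by_group(
    fragments: Iterable[Fragment],
) -> dict[tuple[str, str, str], list[Fragment]]:
    """Split fragments into independently chained (query, subject, strand) groups.

    Fragments from different queries or database sequences can be processed
    in one pass but are chained separately; plus- and minus-strand hits are
    likewise never co-chained.  Group order follows first appearance.
    """
    groups: dict[tuple[str, str, str], list[Fragment]] = {}
    for f in fragments:
        groups.setdefault(f.group_key, []).append(f)
    return groups


CHAIN_HEADER = (
    "#query_id\tsubject_id\tstrand\tchain_score\t"
    "q_start\tq_end\ts_start\ts_end\tn_fragments"
)


def write_chains(
    chains: Iterable[ChainReport],
    stream: TextIO,
    emit_members: bool = False,
) -> None:
    """Write one TSV row per chain, 1-based inclusive coordinates.

    Rows are sorted by descending chain score, ties broken by
    (subject_id, database start).  With ``emit_members`` a final column
    lists the ';'-joined member fragment uids in chain order.
    """
    header = CHAIN_HEADER + ("\tfragment_uids" if emit_members else "")
    stream.write(header + "\n")
    ordered = sorted(chains, key=lambda c: (-c.chain_score, c.subject_id, c.span_x[0]))
    for c in ordered:
        row = (
            f"{c.query_id}\t{c.subject_id}\t{c.strand}\t{c.chain_score:.4f}\t"
            f"{c.span_y[0] + 1}\t{c.span_y[1]}\t{c.span_x[0] + 1}\t{c.span_x[1]}\t"
            f"{c.n_fragments}"
        )
        if emit_members:
            row += "\t" + ";".join(str(u) for u in c.fragment_uids)
        stream.write(row + "\n")


def write_bed6(chains: Iterable[ChainReport], stream: TextIO) -> None:
    """Export chain spans on the database sequence as BED6 records."""
    ordered = sorted(chains, key=lambda c: (-c.chain_score, c.subject_id, c.span_x[0]))
    for c in ordered:
        stream.write(
            f"{c.subject_id}\t{c.span_x[0]}\t{c.span_x[1]}\t"
            f"{c.query_id}\t{round(c.chain_score)}\t{c.strand}\n"
        )
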