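"""Maximal exact match enumeration and tie-breaking.

A MEM is a query substring that occurs somewhere in the indexed database and
cannot be extended by one symbol on either side *within the query* while
still occurring.  Maximality is judged against the whole database, not per
record: the labeling scheme exists precisely so that a match shared by many
records is handled once, via its LTU.

Classification uses the longest MEM; when several MEMs tie for the maximal
length, one is picked uniformly at random from a caller-seeded stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labeled_index import LabeledIndex, MatchInterval

DEFAULT_MIN_MEM = {"AA": 5, "NT": 15}


@dataclass(frozen=True)
class MemHit:
    """One maximal exact match and its lowest taxonomic unit."""

    query_start: int
    length: int
    interval: MatchInterval
    ltu_node: int
    frame: int | None = None


def find_mems(
    index: LabeledIndex,
    query: str,
    min_len: int | None = None,
    frame: int | None = None,
) -> list[MemHit]:
    """All MEMs of ``query`` against the index, length >= ``min_len``.

    Walks the query start positions left to right, taking the longest prefix
    match at each.  The match at start ``i`` (length ``l_i``) is right-maximal
    by construction and left-maximal iff ``l_i >= l_{i-1}`` (otherwise it is
    the trailing remainder of the previous start's match, extendable to the
    left); ``l_{-1} = 0``.  Results are sorted by query_start.
    """
    if min_len is None:
        min_len = DEFAULT_MIN_MEM[index.alphabet]
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    q = index.prepare_query(query)
    hits: list[MemHit] = []
    prev_len = 0
    for start in range(len(q)):
        length, interval = index.longest_prefix_match(q, start, prepared=True)
        if length >= min_len and length >= prev_len:
            hits.append(MemHit(start, length, interval, index.ltu(interval), frame))
        prev_len = length
    return hits


def best_hit(mems: list[MemHit], rng: np.random.Generator) -> MemHit | None:
    """The classification-determining MEM: longest, random among equal ties.

    Returns None for an empty list.  With several equally long MEMs one is
    chosen uniformly via ``rng``; a fixed seed gives a reproducible choice.
    """
    if not mems:
        return None
    top = max(m.length for m in mems)
    tied = [m for m in mems if m.length == top]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def count_tied_mems(mems: list[MemHit]) -> int:
    """Number of MEMs sharing the maximal length (0 for no MEMs)."""
    if not mems:
        return 0
    top = max(m.length for m in mems)
    return sum(1 for m in mems if m.length == top)
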