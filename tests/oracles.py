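"""Independent brute-force oracles used to verify the index and search.

Everything here works from first principles on plain Python strings and
explicit root-paths — none of it touches the suffix array, the range-LCA
table, or the MEM walker it is used to check.
"""

from __future__ import annotations

import numpy as np

from taxomem.seqdb import AA_ALPHABET, SequenceDatabase, SequenceRecord
from taxomem.taxonomy import TaxonomyTree


# -- trees -------------------------------------------------------------------

def root_path(tree: TaxonomyTree, node_id: int) -> list[int]:
    """Root-to-node path by explicit parent walking."""
    path = [node_id]
    while tree.node(path[-1]).parent_id is not None:
        path.append(tree.node(path[-1]).parent_id)
    return path[::-1]


def lca_by_path_intersection(tree: TaxonomyTree, a: int, b: int) -> int:
    pa, pb = root_path(tree, a), root_path(tree, b)
    deepest = pa[0]
    for x, y in zip(pa, pb):
        if x != y:
            break
        deepest = x
    return deepest


def random_edges(rng: np.random.Generator, max_nodes: int = 15, height: int = 4):
    """Random (not necessarily full) tree as a child→parent edge list."""
    levels = {"R": 0}
    names = ["R"]
    edges = []
    for i in range(int(rng.integers(2, max_nodes + 1))):
        parent = names[int(rng.integers(len(names)))]
        while levels[parent] >= height:
            parent = names[int(rng.integers(len(names)))]
        child = f"n{i}"
        edges.append((child, parent))
        names.append(child)
        levels[child] = levels[parent] + 1
    return edges


def random_database(
    rng: np.random.Generator,
    n_records_range=(2, 12),
    rec_len_range=(20, 120),
) -> tuple[TaxonomyTree, SequenceDatabase]:
    """Random AA database over a random 4-level tree (non-root labels)."""
    tree = TaxonomyTree.from_edges(random_edges(rng))
    candidates = [n.node_id for n in tree if n.parent_id is not None]
    n_rec = int(rng.integers(*n_records_range, endpoint=True))
    records = []
    for i in range(n_rec):
        length = int(rng.integers(*rec_len_range, endpoint=True))
        seq = "".join(
            AA_ALPHABET[j] for j in rng.integers(0, len(AA_ALPHABET), size=length)
        )
        records.append(SequenceRecord(f"S{i}", seq, int(rng.choice(candidates))))
    return tree, SequenceDatabase(records, "AA", tree)


# -- strings -----------------------------------------------------------------

def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def occurs(db: SequenceDatabase, pattern: str) -> bool:
    return any(pattern in rec.residues for rec in db.records)


def occurrence_positions(db: SequenceDatabase, pattern: str) -> set[int]:
    """Global text positions (record offsets + sentinel bookkeeping) of a pattern."""
    positions = set()
    offset = 0
    for rec in db.records:
        start = rec.residues.find(pattern)
        while start != -1:
            positions.add(offset + start)
            start = rec.residues.find(pattern, start + 1)
        offset += len(rec.residues) + 1  # +1 for the sentinel
    return positions


def containing_records(db: SequenceDatabase, pattern: str) -> list[SequenceRecord]:
    return [rec for rec in db.records if pattern in rec.residues]


def naive_longest_prefix(db: SequenceDatabase, query: str, start: int) -> int:
    """Max l such that query[start:start+l] is a substring of some record."""
    rest = query[start:]
    best = 0
    for l in range(len(rest), 0, -1):
        if occurs(db, rest[:l]):
            best = l
            break
    return best


def naive_mems(db: SequenceDatabase, query: str, min_len: int) -> list[tuple[int, int]]:
    """(start, length) of every MEM, straight from the definition:

    the substring occurs in some record and neither the one-symbol left
    extension nor the right extension (within the query) occurs.
    """
    out = []
    n = len(query)
    for i in range(n):
        for l in range(n - i, min_len - 1, -1):
            sub = query[i : i + l]
            if not occurs(db, sub):
                continue
            right_max = (i + l == n) or not occurs(db, query[i : i + l + 1])
            left_max = (i == 0) or not occurs(db, query[i - 1 : i + l])
            if right_max and left_max:
                out.append((i, l))
            break  # longer ones absent; shorter ones not right-maximal
    return out


def ltu_fold(db: SequenceDatabase, tree: TaxonomyTree, pattern: str) -> int | None:
    """LCA fold over the labels of every record containing the pattern."""
    recs = containing_records(db, pattern)
    if not recs:
        return None
    acc = recs[0].node_id
    for rec in recs[1:]:
        acc = lca_by_path_intersection(tree, acc, rec.node_id)
    return acc


def sample_pattern(rng: np.random.Generator, db: SequenceDatabase, mutate: bool = False) -> str:
    """A substring of a random record, optionally with one substitution."""
    rec = db.records[int(rng.integers(len(db.records)))]
    n = len(rec.residues)
    length = int(rng.integers(1, min(30, n) + 1))
    start = int(rng.integers(0, n - length + 1))
    pat = rec.residues[start : start + length]
    if mutate and length > 0:
        pos = int(rng.integers(length))
        repl = AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
        pat = pat[:pos] + repl + pat[pos + 1 :]
    return pat
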