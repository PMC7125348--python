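"""Hierarchically labeled generalized suffix index.

The index concatenates all database records, each terminated by a sentinel
that sorts before every residue, builds the suffix array of the concatenation,
and annotates each suffix with the taxonomy node of its source record.  A
sparse table over the suffix-ordered label array — with tree LCA as the
idempotent, associative combiner — then answers "lowest common ancestor of the
labels in suffix-rank interval [lo, hi)" in constant time: two table lookups
and one pairwise LCA, with no per-element work.  This is the labeling step
that lets a read be assigned directly to the lowest taxonomic unit (LTU)
shared by *all* database sequences containing its match, without enumerating
the matches.

Character conventions inside the concatenated text:

=============  ========  =====================================================
symbol         char      meaning
=============  ========  =====================================================
sentinel       ``\\x00``  record terminator; sorts first; never in a query
text wildcard  ``\\x02``  ambiguous database residue; never equals any query
query wildcard ``\\x03``  ambiguous query residue; never equals any text char
residues       A..Z      the declared alphabet, stored uppercase
=============  ========  =====================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqdb import ALPHABETS, WILDCARDS, SequenceDatabase
from .taxonomy import TaxonomyTree

SENTINEL = "\x00"
TEXT_WILDCARD = "\x02"
QUERY_WILDCARD = "\x03"
FORMAT_VERSION = 1


class LabeledIndexError(ValueError):
    """Raised for invalid index operations or corrupted on-disk indexes."""


@dataclass(frozen=True)
class MatchInterval:
    """Half-open suffix-array rank interval of suffixes sharing a prefix."""

    lo: int
    hi: int
    pattern_len: int

    @property
    def is_empty(self) -> bool:
        return self.lo >= self.hi

    @property
    def width(self) -> int:
        return max(0, self.hi - self.lo)


EMPTY_INTERVAL = MatchInterval(0, 0, 0)


def build_suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber–Myers), fully vectorized.

    ``codes`` is a 1-D integer array; returns int32 positions in strictly
    increasing lexicographic suffix order.
    """
    n = int(codes.size)
    if n == 0:
        return np.empty(0, dtype=np.int32)
    rank = np.asarray(codes, dtype=np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_sorted = rank[order]
        k_sorted = key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        np.cumsum(
            (r_sorted[1:] != r_sorted[:-1]) | (k_sorted[1:] != k_sorted[:-1]),
            out=bump[1:],
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = bump
        rank = new_rank
        if bump[-1] == n - 1:
            return order.astype(np.int32)
        k *= 2


def _query_table(alphabet: str) -> dict[int, str]:
    keep = set(ALPHABETS[alphabet])
    table: dict[int, str] = {}
    for code in range(128):
        ch = chr(code).upper()
        if alphabet == "NT" and ch == "U":
            ch = "T"
        table[code] = ch if ch in keep else QUERY_WILDCARD
    return table


_QUERY_CLEAN = {ab: _query_table(ab) for ab in ALPHABETS}



class LabeledIndex:
    """Generalized suffix array with constant-time range-LCA label queries."""

    def __init__(
        self,
        text: str,
        sa: np.ndarray,
        pos_doc: np.ndarray,
        record_ids: list[str],
        record_nodes: list[int],
        alphabet: str,
        tree: TaxonomyTree,
        format_version: int = FORMAT_VERSION,
    ):
        self.text = text
        self.sa = sa
        self.pos_doc = pos_doc
        self.record_ids = record_ids
        self.record_nodes = record_nodes
        self.alphabet = alphabet
        self.tree = tree
        self.format_version = format_version
        self._sa_list: list[int] = sa.tolist()
        self.doc = pos_doc[sa]
        nodes_arr = np.asarray(record_nodes, dtype=np.int32)
        self.labels = nodes_arr[self.doc]
        self._sparse = self._build_sparse(self.labels, tree)
        self._parents = tree._parents
        self._levels = [tree.node(i).level for i in range(len(tree))]

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, db: SequenceDatabase) -> "LabeledIndex":
        """Index a database: suffix structure first, then label annotation."""
        if len(db) == 0:
            raise LabeledIndexError("cannot index an empty database")
        wc = WILDCARDS[db.alphabet]
        parts: list[str] = []
        pos_doc = []
        for i, rec in enumerate(db.records):
            if SENTINEL in rec.residues:
                raise LabeledIndexError(f"record {rec.seq_id!r} contains the sentinel symbol")
            parts.append(rec.residues.replace(wc, TEXT_WILDCARD))
            parts.append(SENTINEL)
            pos_doc.extend([i] * (len(rec.residues) + 1))
        text = "".join(parts)
        codes = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
        sa = build_suffix_array(codes)
        return cls(
            text,
            sa,
            np.asarray(pos_doc, dtype=np.int32),
            [r.seq_id for r in db.records],
            [r.node_id for r in db.records],
            db.alphabet,
            db.tree,
        )

    @staticmethod
    def _build_sparse(labels: np.ndarray, tree: TaxonomyTree) -> list[np.ndarray]:
        """Sparse table S[j][i] = LCA of labels[i .. i + 2**j)."""
        n = labels.size
        table = [labels.astype(np.int32)]
        j = 1
        while (1 << j) <= n:
            half = 1 << (j - 1)
            prev = table[-1]
            table.append(tree.lca_vector(prev[: n - 2 * half + 1], prev[half : n - half + 1]))
            j += 1
        return table

    # -- query helpers -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.text)

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    def prepare_query(self, query: str) -> str:
        """Uppercase a query and mask out-of-alphabet symbols so they never match."""
        return query.upper().translate(_QUERY_CLEAN[self.alphabet])

    def _bisect(self, pat: str, upper: bool) -> int:
        """First rank whose suffix-prefix of len(pat) is >= pat (or > if upper)."""
        text = self.text
        sal = self._sa_list
        m = len(pat)
        lo, hi = 0, len(sal)
        while lo < hi:
            mid = (lo + hi) // 2
            p = sal[mid]
            s = text[p : p + m]
            if s < pat or (upper and s == pat):
                lo = mid + 1
            else:
                hi = mid
        return lo

    def match_interval(self, pattern: str, *, prepared: bool = False) -> MatchInterval:
        """Suffix-rank interval of all suffixes starting with ``pattern``.

        An absent pattern (including any pattern containing an ambiguity
        symbol) yields the empty interval; the empty pattern matches every
        suffix.
        """
        pat = pattern if prepared else self.prepare_query(pattern)
        if not pat:
            return MatchInterval(0, len(self.text), 0)
        lo = self._bisect(pat, upper=False)
        hi = self._bisect(pat, upper=True)
        if lo >= hi:
            return EMPTY_INTERVAL
        return MatchInterval(lo, hi, len(pat))

    def longest_prefix_match(
        self, query: str, start: int = 0, *, prepared: bool = False
    ) -> tuple[int, MatchInterval]:
        """Longest prefix of ``query[start:]`` occurring in the text.

        Locates the insertion rank of the remaining query among the sorted
        suffixes; the longest matching prefix is the longer of the common
        prefixes with the two neighboring suffixes.  Returns ``(0, empty)``
        when even the first symbol is absent.
        """
        q = query if prepared else self.prepare_query(query)
        if not 0 <= start < len(q):
            raise LabeledIndexError(f"start {start} outside query of length {len(q)}")
        rest = q[start:]
        text = self.text
        sal = self._sa_list
        n = len(sal)
        m = len(rest)
        lo, hi = 0, n
        while lo < hi:
            mid = (lo + hi) // 2
            p = sal[mid]
            if text[p : p + m] < rest:
                lo = mid + 1
            else:
                hi = mid
        best = 0
        tlen = len(text)
        for cand in (lo - 1, lo):
            if 0 <= cand < n:
                p = sal[cand]
                l = 0
                while l < m and p + l < tlen and text[p + l] == rest[l]:
                    l += 1
                if l > best:
                    best = l
        if best == 0:
            return 0, EMPTY_INTERVAL
        return best, self.match_interval(rest[:best], prepared=True)

    def ltu(self, interval: MatchInterval) -> int:
        """Lowest taxonomic unit of a nonempty interval: LCA of its labels.

        Constant time: the interval is covered by two overlapping
        power-of-two blocks of the sparse table, combined by one pairwise
        tree LCA (LCA is idempotent, so the overlap is harmless).
        """
        lo, hi = interval.lo, interval.hi
        if lo >= hi:
            raise LabeledIndexError("LTU of an empty interval")
        j = (hi - lo).bit_length() - 1
        block = self._sparse[j]
        return self._pair_lca(int(block[lo]), int(block[hi - (1 << j)]))

    def _pair_lca(self, a: int, b: int) -> int:
        levels = self._levels
        parents = self._parents
        la, lb = levels[a], levels[b]
        while la > lb:
            a = parents[a]
            la -= 1
        while lb > la:
            b = parents[b]
            lb -= 1
        while a != b:
            a = parents[a]
            b = parents[b]
        return a

    # -- persistence -------------------------------------------------------

    def save(self, dir_path) -> None:
        """Write the index as a directory: JSON manifest + binary arrays.

        Layout (format version 1): ``manifest.json`` with format_version,
        alphabet, record ids and node names, and text length; ``text.npy``
        (uint8 codes), ``sa.npy``, ``pos_doc.npy`` (int32); ``tree.tsv``
        (child TAB parent edges).  The range-LCA table is rebuilt on load.
        """
        d = Path(dir_path)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": self.format_version,
            "alphabet": self.alphabet,
            "n_text": len(self.text),
            "n_records": self.n_records,
            "record_ids": self.record_ids,
            "record_node_names": [self.tree.name_of(v) for v in self.record_nodes],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        np.save(d / "text.npy", np.frombuffer(self.text.encode("latin-1"), dtype=np.uint8))
        np.save(d / "sa.npy", self.sa)
        np.save(d / "pos_doc.npy", self.pos_doc)
        self.tree.write_tsv(d / "tree.tsv")

    @classmethod
    def load(cls, dir_path) -> "LabeledIndex":
        d = Path(dir_path)
        manifest_path = d / "manifest.json"
        if not manifest_path.exists():
            raise LabeledIndexError(f"no index manifest in {d}")
        manifest = json.loads(manifest_path.read_text())
        version = manifest.get("format_version")
        if version != FORMAT_VERSION:
            raise LabeledIndexError(
                f"index format version {version} unsupported (expected {FORMAT_VERSION})"
            )
        for name in ("text.npy", "sa.npy", "pos_doc.npy", "tree.tsv"):
            if not (d / name).exists():
                raise LabeledIndexError(f"index component {name} missing from {d}")
        tree = TaxonomyTree.from_tsv(d / "tree.tsv", max_height=None)
        text = np.load(d / "text.npy").tobytes().decode("latin-1")
        sa = np.load(d / "sa.npy")
        pos_doc = np.load(d / "pos_doc.npy")
        if len(text) != manifest["n_text"] or sa.size != len(text):
            raise LabeledIndexError("corrupted index: component sizes disagree")
        record_nodes = [tree.id_of(n) for n in manifest["record_node_names"]]
        return cls(
            text,
            sa.astype(np.int32),
            pos_doc.astype(np.int32),
            list(manifest["record_ids"]),
            record_nodes,
            manifest["alphabet"],
            tree,
            format_version=version,
        )


def build_index(db: SequenceDatabase) -> LabeledIndex:
    """Convenience alias for :meth:`LabeledIndex.build`."""
    return LabeledIndex.build(db)
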