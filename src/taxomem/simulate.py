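"""Synthetic annotated databases, error-bearing reads, and accuracy scoring.

The generator stands in for a real functionally annotated reference: a full
k-ary annotation tree (default four levels below the root, the shape of
enzyme-code hierarchies), uniform-random residue records each labeled with a
leaf (optionally a small fraction at internal nodes), and reads sampled as
record fragments with independent per-position substitution errors — the
divergence model used for accuracy grids at 5/10/30% error.

Scoring uses four-way categories relative to the known source node: correct,
(non-root proper) ancestor, root, incorrect — plus unassigned when no-match
reads are kept separate from root assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ReadAssignment
from .seqdb import ALPHABETS, SequenceDatabase, SequenceRecord
from .taxonomy import TaxonomyTree

CATEGORIES = ("correct", "ancestor", "root", "incorrect", "unassigned")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Read-simulation settings.

    error_rate is a per-position substitution probability; read_len is in
    residues of the database alphabet.  Defaults: 60-residue reads (the
    translated span of a typical short nucleotide read), no errors.
    """

    n_reads: int
    read_len: int = 60
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise SimulationError("error_rate must be in [0, 1)")
        if self.read_len < 1 or self.n_reads < 0:
            raise SimulationError("read_len >= 1 and n_reads >= 0 required")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    residues: str
    truth_node: int
    source_seq: str
    source_offset: int


@dataclass
class EvalSummary:
    """Category fractions and match statistics of one classification run."""

    fractions: dict[str, float]
    mean_mem_length: float
    mean_tied_mems: float
    level_histogram: dict[int, int] = field(default_factory=dict)
    n_reads: int = 0


def make_tree(branching: tuple[int, ...] = (2, 2, 2, 2), root_name: str = "R") -> TaxonomyTree:
    """Full tree with the given branching factor per level below the root.

    Node names are dotted path codes ("1", "1.2", "1.2.1", ...); the root is
    named ``root_name``.
    """
    if any(b < 1 for b in branching):
        raise SimulationError("branching factors must be >= 1")
    edges: list[tuple[str, str]] = []
    frontier = [root_name]
    for b in branching:
        nxt = []
        for parent in frontier:
            for k in range(1, b + 1):
                child = f"{k}" if parent == root_name else f"{parent}.{k}"
                edges.append((child, parent))
                nxt.append(child)
        frontier = nxt
    return TaxonomyTree.from_edges(edges, max_height=len(branching))


def make_fixture(
    seed: int,
    n_records: int = 50,
    record_len_range: tuple[int, int] = (200, 400),
    branching: tuple[int, ...] = (2, 2, 2, 2),
    alphabet: str = "AA",
    internal_frac: float = 0.0,
) -> tuple[TaxonomyTree, SequenceDatabase]:
    """Random annotated database over a full annotation tree.

    Residues are i.i.d. uniform over the alphabet; each record is labeled
    with a uniformly chosen leaf, or with probability ``internal_frac`` a
    uniformly chosen non-root internal node.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    tree = make_tree(branching)
    leaves = tree.leaves()
    internals = [
        n.node_id for n in tree if n.parent_id is not None and n.node_id not in set(leaves)
    ]
    symbols = np.frombuffer(ALPHABETS[alphabet].encode(), dtype=np.uint8)
    lo, hi = record_len_range
    records = []
    for i in range(n_records):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(symbols, size=length).tobytes().decode()
        if internals and internal_frac > 0 and rng.random() < internal_frac:
            node = int(rng.choice(internals))
        else:
            node = int(rng.choice(leaves))
        records.append(SequenceRecord(f"S{i:06d}", seq, node))
    return tree, SequenceDatabase(records, alphabet, tree)


def simulate_reads(db: SequenceDatabase, params: SimParams) -> list[SimulatedRead]:
    """Error-bearing fragments with ground truth.

    The source record is chosen with probability proportional to its length
    (among records long enough to yield a fragment), the offset uniformly;
    each position is substituted independently with probability
    ``error_rate``, to a uniformly chosen *different* symbol.
    """
    rng = np.random.default_rng(params.seed)
    eligible = [r for r in db.records if len(r.residues) >= params.read_len]
    if not eligible:
        raise SimulationError(f"no record is >= read_len ({params.read_len}) residues long")
    lens = np.array([len(r.residues) for r in eligible], dtype=np.float64)
    probs = lens / lens.sum()
    alphabet = ALPHABETS[db.alphabet]
    sym = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    sym_rank = np.zeros(256, dtype=np.int64)
    sym_rank[sym] = np.arange(len(sym))
    reads: list[SimulatedRead] = []
    choices = rng.choice(len(eligible), size=params.n_reads, p=probs)
    for i in range(params.n_reads):
        rec = eligible[int(choices[i])]
        off = int(rng.integers(0, len(rec.residues) - params.read_len + 1))
        frag = np.frombuffer(
            rec.residues[off : off + params.read_len].encode(), dtype=np.uint8
        ).copy()
        if params.error_rate > 0:
            mask = rng.random(params.read_len) < params.error_rate
            n_err = int(mask.sum())
            if n_err:
                # shift by 1..|A|-1 within the alphabet: uniform over other symbols
                shift = rng.integers(1, len(sym), size=n_err)
                frag[mask] = sym[(sym_rank[frag[mask]] + shift) % len(sym)]
        reads.append(
            SimulatedRead(f"read{i:07d}", frag.tobytes().decode(), rec.node_id, rec.seq_id, off)
        )
    return reads


def write_reads_fasta(reads: list[SimulatedRead], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.residues}\n")


def write_truth(reads: list[SimulatedRead], tree: TaxonomyTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\ttruth_node\tsource_seq\tsource_offset\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{tree.name_of(r.truth_node)}\t{r.source_seq}\t{r.source_offset}\n"
            )


def read_truth(path, tree: TaxonomyTree) -> dict[str, int]:
    truths: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise SimulationError("truth table must start with a read_id header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            truths[f[0]] = tree.id_of(f[1])
    return truths


def plant_shared_block(
    db: SequenceDatabase, tree: TaxonomyTree, node_id: int, block: str, offset: int = 0
) -> SequenceDatabase:
    """Overwrite ``block`` into every record labeled under ``node_id``.

    Deterministic construction of shared subtree content: reads drawn from the
    block then match all those records, so their LTU is exactly ``node_id``
    (provided the block occurs nowhere else — callers should verify on random
    fixtures).
    """
    new_records = []
    for rec in db.records:
        if tree.is_ancestor(node_id, rec.node_id):
            if len(rec.residues) < offset + len(block):
                raise SimulationError(f"record {rec.seq_id!r} too short for the block")
            seq = rec.residues[:offset] + block + rec.residues[offset + len(block):]
            new_records.append(SequenceRecord(rec.seq_id, seq, rec.node_id))
        else:
            new_records.append(rec)
    return SequenceDatabase(new_records, db.alphabet, tree)


def categorize(assigned: int | None, truth: int, tree: TaxonomyTree) -> str:
    """Four-way accuracy category (plus 'unassigned' for no assignment)."""
    tree.node(truth)
    if assigned is None:
        return "unassigned"
    if assigned == truth:
        return "correct"
    if assigned == tree.root_id:
        return "root"
    if tree.is_ancestor(assigned, truth):
        return "ancestor"
    return "incorrect"


def evaluate(
    assignments: list[ReadAssignment],
    truths: dict[str, int],
    tree: TaxonomyTree,
    merge_unassigned_into_root: bool = True,
) -> EvalSummary:
    """Score assignments against ground truth.

    Fractions over the five categories always sum to 1; with
    ``merge_unassigned_into_root`` unassigned reads count as root (the
    every-read-gets-a-label accounting).  Mean MEM length and mean tied-MEM
    count are over assigned reads; the level histogram counts assignments per
    tree level.
    """
    if len(assignments) != len(truths):
        raise SimulationError("assignments and truths differ in length")
    counts = {c: 0 for c in CATEGORIES}
    mem_lengths: list[int] = []
    tied: list[int] = []
    level_hist: dict[int, int] = {}
    for a in assignments:
        if a.read_id not in truths:
            raise SimulationError(f"read {a.read_id!r} missing from the truth table")
        node = a.node_id
        if node is None and merge_unassigned_into_root:
            node = tree.root_id
        counts[categorize(node, truths[a.read_id], tree)] += 1
        if a.assigned:
            mem_lengths.append(a.mem_length)
            tied.append(a.n_tied)
            level_hist[a.node_level] = level_hist.get(a.node_level, 0) + 1
    n = len(assignments)
    fractions = {c: (counts[c] / n if n else 0.0) for c in CATEGORIES}
    return EvalSummary(
        fractions=fractions,
        mean_mem_length=float(np.mean(mem_lengths)) if mem_lengths else 0.0,
        mean_tied_mems=float(np.mean(tied)) if tied else 0.0,
        level_histogram=dict(sorted(level_hist.items())),
        n_reads=n,
    )


def database_level_histogram(db: SequenceDatabase) -> dict[int, int]:
    """Records per tree level — the content baseline for assignment histograms."""
    hist: dict[int, int] = {}
    for rec in db.records:
        lvl = db.tree.level(rec.node_id)
        hist[lvl] = hist.get(lvl, 0) + 1
    return dict(sorted(hist.items()))
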