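"""End-to-end read classification and hierarchical profile aggregation.

A read is classified by its longest maximal exact match against the labeled
index: the assignment is the match's lowest taxonomic unit, obtained in
constant time from the index's range-LCA annotation.  Nucleotide reads
searched against an amino-acid index are first six-frame translated; MEMs
from all stop-free fragments are pooled before the tie-break, and reported
lengths are in amino acids.

Reads whose longest MEM falls below the minimum length are "unassigned".
With ``merge_unassigned_into_root`` (default on) such reads are *reported*
under the root node — reproducing the accounting where every read receives a
label and uninformative reads sit at the root — while the status column keeps
the two cases distinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import mem_search
from .labeled_index import LabeledIndex
from .mem_search import DEFAULT_MIN_MEM, MemHit
from .seqdb import six_frame_translate
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

ASSIGNMENT_COLUMNS = (
    "read_id",
    "status",
    "node_name",
    "node_level",
    "mem_length",
    "n_tied",
    "frame",
)


@dataclass(frozen=True)
class ClassifyParams:
    """Knobs of a classification run.

    min_mem: minimum MEM length in residues of the *index* alphabet
        (None = 5 AA / 15 nt default); translate: six-frame translate
    nucleotide reads before searching an amino-acid index; seed: root seed of
    the tie-break streams (each read derives its own stream from its ordinal,
    so results do not depend on processing order beyond the ordinal).
    """

    min_mem: int | None = None
    translate: bool = False
    seed: int = 0
    merge_unassigned_into_root: bool = True


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # "assigned" | "unassigned"
    node_id: int | None
    node_level: int | None
    mem_length: int
    n_tied: int
    frame: int | None = None

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


@dataclass
class LevelProfile:
    """Read counts aggregated to ancestors at one fixed tree level."""

    level: int
    counts: dict[int, int] = field(default_factory=dict)
    n_above_level: int = 0
    n_unassigned: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.n_above_level + self.n_unassigned


def classify_read(
    index: LabeledIndex,
    tree: TaxonomyTree,
    read_id: str,
    sequence: str,
    params: ClassifyParams,
    rng: np.random.Generator,
) -> ReadAssignment:
    """Assign one read to the LTU of its longest MEM (or mark it unassigned)."""
    min_mem = params.min_mem if params.min_mem is not None else DEFAULT_MIN_MEM[index.alphabet]
    mems: list[MemHit] = []
    if params.translate:
        if index.alphabet != "AA":
            raise ValueError("six-frame translation requires an amino-acid index")
        for frag in six_frame_translate(sequence):
            mems.extend(mem_search.find_mems(index, frag.aa_residues, min_mem, frame=frag.frame))
    else:
        mems = mem_search.find_mems(index, sequence, min_mem)
    best = mem_search.best_hit(mems, rng)
    if best is None:
        return ReadAssignment(read_id, "unassigned", None, None, 0, 0)
    return ReadAssignment(
        read_id,
        "assigned",
        best.ltu_node,
        tree.level(best.ltu_node),
        best.length,
        mem_search.count_tied_mems(mems),
        best.frame,
    )


def read_rng(seed: int, ordinal: int) -> np.random.Generator:
    """Per-read random stream, derived from the run seed and read ordinal."""
    return np.random.default_rng((seed, ordinal))


def _sniff_format(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def format_assignment_row(a: ReadAssignment, tree: TaxonomyTree, merge_root: bool) -> str:
    if a.assigned:
        name = tree.name_of(a.node_id)
        level = str(a.node_level)
    elif merge_root:
        name = tree.name_of(tree.root_id)
        level = "0"
    else:
        name = "NA"
        level = "NA"
    frame = f"{a.frame:+d}" if a.frame is not None else "NA"
    return "\t".join(
        (a.read_id, a.status, name, level, str(a.mem_length), str(a.n_tied), frame)
    )


def classify_file(
    index: LabeledIndex,
    tree: TaxonomyTree,
    reads_path,
    params: ClassifyParams,
    out_path=None,
) -> dict:
    """Classify every read of a FASTA/FASTQ file; one TSV row per read.

    Mates of paired files are independent reads.  Malformed records are
    skipped with a logged warning and counted in the summary.  Deterministic
    for a fixed seed.  Returns a summary dict (totals, per-status and
    per-level counts) alongside the optional TSV.
    """
    fmt = _sniff_format(reads_path)
    assignments: list[ReadAssignment] = []
    n_skipped = 0
    ordinal = 0
    with open(reads_path, "r", encoding="utf-8") as fh:
        parser = SeqIO.parse(fh, fmt)
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                logger.warning("skipping malformed record in %s: %s", reads_path, exc)
                n_skipped += 1
                break  # Biopython cannot resync after a malformed record
            assignments.append(
                classify_read(
                    index, tree, rec.id, str(rec.seq), params, read_rng(params.seed, ordinal)
                )
            )
            ordinal += 1
    if out_path is not None:
        write_assignments(assignments, tree, out_path, params.merge_unassigned_into_root)
    return summarize(assignments, tree, n_skipped=n_skipped)


def write_assignments(
    assignments: list[ReadAssignment],
    tree: TaxonomyTree,
    out_path,
    merge_root: bool = True,
) -> None:
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in assignments:
            fh.write(format_assignment_row(a, tree, merge_root) + "\n")


def read_assignments(path, tree: TaxonomyTree) -> list[ReadAssignment]:
    """Parse an assignment TSV back into ReadAssignment records."""
    out: list[ReadAssignment] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ASSIGNMENT_COLUMNS:
            raise ValueError(f"unexpected assignment columns: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            assigned = f[1] == "assigned"
            out.append(
                ReadAssignment(
                    f[0],
                    f[1],
                    tree.id_of(f[2]) if assigned else None,
                    int(f[3]) if assigned else None,
                    int(f[4]),
                    int(f[5]),
                    int(f[6]) if f[6] != "NA" else None,
                )
            )
    return out


def summarize(assignments: list[ReadAssignment], tree: TaxonomyTree, n_skipped: int = 0) -> dict:
    by_status = {"assigned": 0, "unassigned": 0}
    by_level: dict[int, int] = {}
    for a in assignments:
        by_status[a.status] += 1
        if a.assigned:
            by_level[a.node_level] = by_level.get(a.node_level, 0) + 1
    return {
        "n_reads": len(assignments),
        "n_skipped": n_skipped,
        "by_status": by_status,
        "assigned_by_level": dict(sorted(by_level.items())),
    }


def aggregate_profile(
    assignments: list[ReadAssignment], tree: TaxonomyTree, level: int
) -> LevelProfile:
    """Aggregate assignments to one tree level.

    Reads assigned at or below the level contribute one count to their
    ancestor at exactly that level; reads assigned strictly above it (e.g.,
    at the root) are tallied as ``n_above_level``; unassigned reads as
    ``n_unassigned``.  Counts + above + unassigned always equals the number
    of reads processed.
    """
    prof = LevelProfile(level=level)
    for a in assignments:
        if not a.assigned:
            prof.n_unassigned += 1
            continue
        anc = tree.level_ancestor(a.node_id, level)
        if anc is None:
            prof.n_above_level += 1
        else:
            prof.counts[anc] = prof.counts.get(anc, 0) + 1
    return prof
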