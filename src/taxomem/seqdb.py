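"""Annotated reference databases and six-frame translation.

A reference database is a FASTA file of amino-acid or nucleotide sequences
plus a two-column TSV mapping each sequence id to a node of the companion
annotation tree.  Symbols outside the declared alphabet (ambiguity codes such
as 'N', 'X', 'B', 'Z') are stored as a reserved wildcard character that the
index guarantees can never participate in an exact match, so ambiguous
positions terminate matches instead of silently matching.

Nucleotide reads destined for an amino-acid index are searched through all six
reading frames of the standard genetic code, split at stop codons into maximal
stop-free fragments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

from .taxonomy import TaxonomyTree

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"
AA_WILDCARD = "X"
NT_WILDCARD = "N"

ALPHABETS = {"AA": AA_ALPHABET, "NT": NT_ALPHABET}
WILDCARDS = {"AA": AA_WILDCARD, "NT": NT_WILDCARD}


class DatabaseError(ValueError):
    """Raised for malformed databases or label tables."""


def _clean_table(alphabet: str) -> dict[int, str]:
    keep = set(ALPHABETS[alphabet])
    wc = WILDCARDS[alphabet]
    table: dict[int, str] = {}
    for code in range(128):
        ch = chr(code).upper()
        if alphabet == "NT" and ch == "U":
            ch = "T"
        table[code] = ch if ch in keep else wc
    return table


_CLEAN = {ab: _clean_table(ab) for ab in ALPHABETS}


def clean_residues(seq: str, alphabet: str) -> str:
    """Uppercase and map out-of-alphabet symbols to the wildcard ('X'/'N')."""
    return seq.upper().translate(_CLEAN[alphabet])


@dataclass(frozen=True)
class SequenceRecord:
    seq_id: str
    residues: str
    node_id: int


@dataclass
class SequenceDatabase:
    """Validated, ordered collection of labeled reference sequences."""

    records: list[SequenceRecord]
    alphabet: str
    tree: TaxonomyTree

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise DatabaseError(f"unknown alphabet {self.alphabet!r}")
        seen: set[str] = set()
        for rec in self.records:
            if not rec.residues:
                raise DatabaseError(f"empty sequence {rec.seq_id!r}")
            if rec.seq_id in seen:
                raise DatabaseError(f"duplicate sequence id {rec.seq_id!r}")
            seen.add(rec.seq_id)
            self.tree.node(rec.node_id)  # raises on unknown handle

    def __len__(self) -> int:
        return len(self.records)

    def write_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(f">{rec.seq_id}\n{rec.residues}\n")

    def write_labels(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(f"{rec.seq_id}\t{self.tree.name_of(rec.node_id)}\n")


def read_labels(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise DatabaseError(f"malformed label row: {row!r}")
            if not labels and row[0].strip().lower() == "seq_id":
                continue
            labels[row[0].strip()] = row[1].strip()
    return labels


def load_database(
    fasta_path,
    labels: "dict[str, str] | str | Path",
    tree: TaxonomyTree,
    alphabet: str = "AA",
) -> SequenceDatabase:
    """Load FASTA + label table into a validated database.

    ``labels`` may be a path to a ``seq_id TAB node_name`` TSV or an
    already-parsed mapping.  Every FASTA record must be labeled and every
    label must name a tree node; record order is preserved.
    """
    if not isinstance(labels, dict):
        labels = read_labels(labels)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in labels:
            raise DatabaseError(f"sequence {rec.id!r} missing from the label table")
        name = labels[rec.id]
        if name not in tree:
            raise DatabaseError(f"label {name!r} for {rec.id!r} is not a tree node")
        records.append(
            SequenceRecord(rec.id, clean_residues(str(rec.seq), alphabet), tree.id_of(name))
        )
    return SequenceDatabase(records, alphabet, tree)


# -- six-frame translation -------------------------------------------------

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_AA[_stop] = "*"

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(nt: str) -> str:
    return nt.translate(_RC)[::-1]


@dataclass(frozen=True)
class TranslatedFragment:
    """A maximal stop-free amino-acid stretch from one reading frame.

    ``nt_offset`` is the 0-based offset of the fragment's first codon on the
    frame's template strand (the read itself for +1/+2/+3, its reverse
    complement for -1/-2/-3).
    """

    aa_residues: str
    frame: int
    nt_offset: int


FRAMES = (1, 2, 3, -1, -2, -3)


def translate_frame(nt: str, frame: int) -> str:
    """Translate one frame; stops are '*', ambiguous codons are the wildcard."""
    template = nt if frame > 0 else reverse_complement(nt)
    start = abs(frame) - 1
    out = []
    for i in range(start, len(template) - 2, 3):
        codon = template[i : i + 3]
        out.append(_CODON_AA.get(codon, AA_WILDCARD))
    return "".join(out)


def six_frame_translate(nt_read: str) -> list[TranslatedFragment]:
    """All stop-free amino-acid fragments of a nucleotide read, six frames.

    Uses translation table 1; reads shorter than one codon yield an empty
    list.  Codons containing ambiguity codes translate to the wildcard 'X'
    (which never matches), preserving codon offsets.
    """
    read = clean_residues(nt_read, "NT")
    fragments: list[TranslatedFragment] = []
    for frame in FRAMES:
        aa = translate_frame(read, frame)
        start_codon = abs(frame) - 1
        pos = 0
        for piece in aa.split("*"):
            if piece:
                fragments.append(
                    TranslatedFragment(piece, frame, start_codon + 3 * pos)
                )
            pos += len(piece) + 1
    return fragments
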