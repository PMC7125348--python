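# Methods

## Model

`taxomem` classifies a sequencing read against a reference database whose
records are annotated with nodes of a rooted functional hierarchy (root at
level 0; a full enzyme-code tree has leaves at level 4).  The classification
target of a read is the lowest taxonomic unit (LTU) of its longest maximal
exact match (MEM): the LCA of the annotation nodes of *all* records
containing that match.  The assumptions are those of exact-match
classification generally — reads are short relative to references, sequence
similarity concentrates within subtrees of the hierarchy, and substitution
divergence shortens MEMs but rarely relocates them into the wrong subtree.

## Index structure

The database records are concatenated with a per-record terminator `\x00`
that sorts before every residue, so no suffix comparison or pattern match can
cross a record boundary, and all suffixes are distinct.  The suffix array is
built by vectorized prefix doubling (Manber–Myers, O(n log² n)); at
desk scale (up to a few million residues) this is seconds of numpy work, and
the construction is verified against a naive suffix sort in the tests.

The labeling step stores, per suffix rank, the annotation node of the
suffix's source record, and preprocesses this label array into a sparse table
whose combiner is tree LCA.  LCA is idempotent and associative, so an
arbitrary interval `[lo, hi)` is covered by two overlapping blocks of width
`2^⌊log₂(hi−lo)⌋` and the answer is one pairwise LCA of two table cells.  A
query therefore costs O(1) table lookups plus one parent-climbing LCA
(O(height), height ≤ 4 for enzyme-code trees) regardless of interval width —
the per-query cost is independent of how many references share the match.
The table costs O(n log n) int32 entries; for the scale this package targets
that trade is the simplest structure meeting the constant-time contract, and
any replacement only needs to pass the same fold-equivalence oracle test.

Pairwise tree LCA is deliberately plain parent climbing: the hierarchy is
shallow, so Euler-tour/RMQ machinery would buy nothing.

## Pattern search

`match_interval` binary-searches the suffix array with direct string-slice
comparisons.  `longest_prefix_match(query, start)` finds the insertion rank
of the remaining query among the sorted suffixes; the longest matching prefix
is the longer of the common prefixes with the two neighboring suffixes, after
which two more binary searches delimit its interval.  MEM enumeration walks
the query start positions once: the longest match at start `i` (length `l_i`)
is right-maximal by construction and left-maximal iff `l_i ≥ l_{i−1}`
(otherwise it is the trailing remainder of the previous start's match), with
`l_{−1} = 0`.  Maximality is judged against the whole database, not per
record — per-record MEMs would multiply exactly the redundant hits the
labeling scheme exists to collapse.

## Alphabets, wildcards, sentinels

Residues are stored uppercase.  Out-of-alphabet symbols (NT: anything but
`ACGT`, with `U → T`; AA: anything but the 20 standard letters, including
`X B Z J U O`) become a wildcard — displayed `N`/`X`, encoded internally as
`\x02` in the text and `\x03` in queries.  Text-side and query-side wildcards
are distinct characters, so an ambiguous position can never participate in an
exact match; it terminates matches instead.  This keeps exact-match semantics
exact at the cost of slightly shorter MEMs around ambiguity codes.

Six-frame translation uses the standard genetic code (table 1); frames are
split at stop codons into maximal stop-free fragments, codons containing `N`
translate to the wildcard (preserving codon offsets), and fragment MEM
lengths are reported in amino acids.  Mates of paired-end data are classified
independently; no mate-reconciliation rule is applied.

## Classification parameters

| parameter | default | meaning |
|---|---|---|
| `min_mem` | 5 AA / 15 nt | minimum MEM length; shorter matches leave the read unassigned |
| `translate` | off | six-frame translate NT reads against an AA index |
| `seed` | 0 | root seed; each read's tie-break stream is derived from (seed, read ordinal), so results are order-robust and byte-reproducible |
| `merge_unassigned_into_root` | on | report no-match reads under the root node while keeping `status = unassigned` distinguishable in the output |

The 5-AA default reflects the short end of informative amino-acid MEM lengths
observed in practice; raising it trades sensitivity for a lower false-positive
rate.  Ties among equally long MEMs are resolved by a uniform random choice
(the default, matching the per-read statistic `n_tied` that is also
reported); an LCA-over-ties strict mode was considered and rejected as the
default because it systematically pushes multi-matching reads upward, losing
the resolution the random representative retains.

Cross-frame ties in translated search enter the same uniform tie-break as
within-frame ties.

## Synthetic data generator

`make_fixture` emulates an annotated reference: a full k-ary hierarchy
(default branching 2,2,2,2 → 4 levels), records of i.i.d. uniform residues
labeled with uniformly chosen leaves (optionally a fraction at internal
nodes), and `simulate_reads` samples fragments with the source record chosen
proportional to length, a uniform offset, and independent per-position
substitutions to a uniformly chosen *different* symbol.  Substitution-only is
the minimal divergence model that keeps truth offsets exact; indels and
platform error profiles are out of scope.  Default read length is 60
residues, roughly the translated span of a typical short nucleotide read.

What the generator does **not** reproduce about real databases: residue
composition bias, homology (sequences within a subtree are unrelated strings
here unless a shared block is planted explicitly via `plant_shared_block`),
abundance skew, and database incompleteness.  Consequently synthetic accuracy
is much higher than on real data — uniform random records rarely collide, so
almost every read retains a unique long MEM even at 30% divergence.  Passing
tests therefore demonstrate the *mechanics* (oracle-exact matching, correct
LTU algebra, monotone degradation with divergence, shared-content enrichment
at internal nodes), not field accuracy on real microbiomes.

## Evaluation

Assignments are scored four ways against the simulation truth: `correct`
(assigned = source node), `ancestor` (non-root proper ancestor), `root`, and
`incorrect` (anything else, e.g. a sibling); `unassigned` is a fifth category
when not merged into root.  The summary also reports mean MEM length and mean
tied-MEM count over assigned reads and a per-level assignment histogram,
which can be compared against the database's own per-level content.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; suffix-array intervals are
  `[lo, hi)`.
- A single sentinel symbol with per-position document bookkeeping replaces
  per-record sentinels; queries can never contain the sentinel, so
  distinctness of suffixes is already guaranteed.
- The on-disk index is a directory: JSON manifest (format version 1,
  alphabet, record ids and node names) plus `.npy` arrays and the tree TSV.
  The sparse table is rebuilt on load rather than serialized — it is cheap to
  rebuild and keeps the format small and versionable.
- Degenerate inputs: empty pattern → full interval; empty interval → LTU is
  an error; empty MEM list → unassigned; an empty database refuses to index.
- The acceptance study runs 3,000 reads × 4 error rates over a 60-record ×
  300-residue fixture (81-leaf hierarchy) — sizes chosen so the full grid,
  including index build and evaluation, completes in well under a minute
  while keeping binomial noise on the reported fractions below a percentage
  point.

## Known limitations

- No compressed or sampled suffix arrays and no multithreaded construction;
  the design targets reference implementations and desk-scale experiments,
  not billion-residue production databases.
- No approximate matching: a single substitution splits a MEM, which is
  exactly the degradation the error-rate grid quantifies.
- Multi-parent annotation graphs (e.g. enzyme-code transfers) are
  unsupported; the hierarchy must be a tree.
- Incomplete annotation codes (e.g. `1.1.1.-`) are treated as ordinary
  internal nodes at their level; records may be labeled at internal nodes.
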