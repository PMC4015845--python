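# Methods

## Federation model

The federated library is a set of protein sequences with three
normalization passes:

1. **Parsing** — FASTA entries are uppercased, trailing stop characters
   stripped; the header's first token is the accession (possibly itself
   a semicolon-joined federated string). The accepted alphabet is the
   20 standard residues plus X, B, Z and U. Isoleucine and leucine are
   treated as distinct characters, and ambiguity codes compare
   literally: sequence identity here means byte identity, the
   conservative choice for a database whose purpose is exact substring
   mapping of peptides.
2. **Merging** — byte-identical sequences collapse into one record; the
   accession list is the sorted union, descriptions are
   semicolon-joined duplicate-free in accession order of the
   constituent records. Attaching one accession to two different
   sequences is an error, not a silent overwrite.
3. **Subset absorption** — "perfect subset" is interpreted as
   *contiguous substring* (not subsequence), matching
   fragment/partial-entry semantics. An absorbed record's accessions
   are appended to its superset; when several supersets exist, the
   longest wins, ties broken by lexicographically smallest first
   accession, so output is deterministic. Containment chains resolve
   transitively to the maximal record.

The accession multiset is conserved across both passes (a tested
invariant), so no identifier is ever lost.

Substring queries (subset detection, peptide mapping) run through one
primitive: an Aho–Corasick automaton built over the pattern set and
scanned once per text, with the contract "all patterns contained in the
text, no false positives or negatives". A brute-force `in`-scan oracle
checks it property-based in the tests.

## Ingestion

Each study file declares its dialect (`format_name`) in config; parsers
are looked up in a registry rather than sniffed, for reproducibility.
Peptide strings are normalized by stripping a single-residue flank
token (`K.PEPTIDE.R`), deleting bracketed modification groups (`(ph)`,
`[+16]`) wholesale, uppercasing, and dropping any remaining
non-alphabet character. Deleting bracketed groups *before* the
character filter matters: the letters inside `(ph)` are themselves
valid residue codes.

Peptides shorter than `min_peptide_length` (default 6) are excluded —
substring mapping of very short peptides is uninformative — and every
exclusion is counted: `rows_in == observations + rejects` exactly.
When a source lists peptides without spectral counts each row counts
as one detection, so redundant counts equal row counts.

Accession normalization strips NCBI-style pipe dialects
(`gi|…|ref|X|`, `sp|…|…`) to a bare token and flags anything it cannot
interpret instead of guessing.

## Evidence store and reduction

The store is an embedded SQLite database (tables `study`, `protein`,
`observation`, `mapping`) so that redundant/distinct/unique counts are
plain SQL aggregations, answerable without re-ingesting. A peptide
mapping to a protein at several offsets yields one mapping row —
identification semantics, not coverage. Unmapped peptides are retained
and flagged, never dropped.

Uniqueness is defined **against the subset-reduced library**: if
fragments were still present, every peptide of a fragment record would
be shared with its parent by construction and no characteristic peptide
could exist. The pipeline therefore federates and subset-reduces before
mapping.

Confidence tiers (`single`/`double`/`high` at 1/2/≥3 distinct
peptides) encode the empirical false-positive split of decoy and
random-spectrum experiments: ~88% of false positives carry one
peptide, ~11% two, and under 1% reach three or more.

Peptide-per-protein histograms are stored as raw integer counts; the
log10 axes seen in typical plots of these distributions are a
presentation choice, not part of the data.

## Homology and protein types

The internal aligner is Smith–Waterman (Biopython `PairwiseAligner`,
local mode) under BLOSUM62 with gap open 11 / extend 1 — the standard
protein BLAST scoring. From the aligned blocks we derive identities,
mismatches, gap openings, alignment length (aligned columns plus gap
columns) and the *longest perfect run*: the maximal stretch of
identical aligned columns broken by any mismatch or gap. Residues
outside the BLOSUM62 alphabet (selenocysteine U) are scored as X but
compared literally for identity counting. No Karlin–Altschul e-value
calibration is attempted: e-values are optional, carried through from
imported BLAST tabular files when present, and the match criterion
never needs them. In the e-value histogram, internally computed
alignments occupy an explicit `unavailable` bin and values below 1e-180
a `machine_zero` bin, so bin totals always equal the input count.

The match criterion is `identities / full_query_length > 0.75`
(strict) and `longest_perfect_run >= 20`. Using the full query length
as denominator — not the alignment length — is deliberate: it makes
the criterion asymmetric in exactly the useful direction, fragments
matching their parents but not vice versa. Collapse takes each query's
top non-self hit (max bitscore, ties by lower e-value then subject id),
keeps the hits that satisfy the criterion as undirected edges, and
takes connected components as protein types; components make the
partition well defined and independent of edge direction. The
representative is the longest member (ties by accession). Tightening
either criterion parameter can only remove edges, so the cluster count
is monotone non-decreasing — a tested property.

Imported 12-column BLAST tabular hits reconstruct identities as
`round(pident x length / 100)` but cannot supply the perfect-run
length; applying the criterion to them requires re-alignment (the
`collapse` CLI verb does this automatically).

## Annotation

GO labels are flat atomic strings: curated summary tables key their
rows on comma-joined label sets, so no DAG traversal is performed and a
`term` granularity that splits on commas is available where individual
terms are wanted. Frequency = count/total rounded half-even to 5
decimals; the comparison tolerance anywhere printed values are involved
is ±1e-5, because published tables mix rounding and truncation at the
fifth decimal. The denominator defaults to annotation rows (switchable
to labeled proteins). Keyword category queries match case-insensitive
substrings over description + GO labels + gene symbol and then filter
by minimum distinct peptide count (n = 0 meaning unfiltered); the
result is monotone in n.

Records without a direct accession match inherit annotations from
their cluster (the representative when annotated, else any annotated
member), with `direct`/`transferred` provenance recorded per protein.

## Detection-limit arithmetic

Pure unit conversions, exact by construction: `pM = ng_ml * 1e6 / Da`
and `fmol = pM * ul * recovery / 1000`. Instrument presets are 1 fmol
(ion-trap detection limit) and 10 fmol (confident identification);
recovery defaults to 1.0 (efficient capture assumed). Both functions
are strictly monotone in every argument and invert each other to
machine precision.

## Synthetic corpus generator

The generator emulates the structure of a federated blood-protein
corpus, not its biology:

- **Families** of `variants_per_family` sequences built from one random
  base (lengths uniform in 100–300 residues) by point substitutions at
  5% of positions, never touching the last 30 residues. Within-family
  identity is therefore ≥ ~90% of the full length with a guaranteed
  ≥30-residue perfect run — comfortably inside the 75%/20-aa criterion —
  while independent random bases put cross-family identity far below
  40%, so default tests never sit on the criterion boundary (boundary
  behavior is tested separately with hand-built alignment results).
- **Fragments** (20% of the full-sequence count by default) are proper
  contiguous slices of a parent, re-drawn until the slice occurs in
  *only* its parent so that absorption has a unique, checkable
  destination.
- **Studies** (3 by default) report the tryptic digest
  (cleave after K/R unless before P; min length 6) of every protein
  with a stated detection probability — default 1.0, the noise-free
  condition under which planted recovery must be *exact* — with
  geometric spectral counts and per-study accession/peptide dialects to
  exercise ingestion.
- **Truth** (family partition, fragment→parent pairs, unique-peptide
  sets computed by brute-force `in`-scan against the distinct library)
  is emitted as JSON and all randomness flows from a single stated
  seed, so a corpus regenerates byte-identically.

What the generator does **not** emulate: spectra and correlation-score
noise, retention times, shared peptides between unrelated real
proteins, homology that sits near the 75% boundary, and real GO
annotation sparsity. Passing planted-recovery tests therefore
demonstrates the correctness of the bookkeeping (federation, mapping,
counting, collapsing) under clean conditions, not robustness to
search-engine error — confidence tiers exist precisely because real
inputs contain such error.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: corpora of ~18
records / 3 studies end to end, oracle-equivalence checks on random
instances up to 500 elements, and alignment-oracle comparisons on
sequences up to 30 residues (the Gotoh dynamic-programming oracle is
quadratic). The procedures themselves are scale-free; the evidence
store and automaton are the components that carry the design to larger
corpora. Score comparisons against the alignment oracle are exact;
identity-count comparisons are asserted only on unambiguous pairs,
since co-optimal local alignments of equal score may differ in identity
count. Degenerate inputs are defined explicitly: empty libraries pass
through subset removal, zero observations produce a valid empty store,
disjoint-alphabet alignments return all-zero results, and empty
annotation categories give an empty table with total 0.
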