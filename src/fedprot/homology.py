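"""Pairwise protein homology and collapsing into protein types.

Two proteins are considered the same "protein type" when the top-scoring
local alignment between them covers more than 75% of the full query
length with identities AND contains a perfect match string of at least
20 contiguous amino acids.  Match edges between proteins are closed into
connected components; each component is one protein type with the
longest member as representative.  Proteins with no matching edge have
no close homologues and stay singletons.

Alignments come either from the internal Smith-Waterman aligner
(BLOSUM62, gap open 11 / extend 1) or from externally computed BLAST
tabular files (outfmt-6 dialect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .library import FederatedLibrary, ProteinRecord
from .reduction import DistributionTable

#: e-values below this are reported by BLAST as machine zero
MACHINE_ZERO_EVALUE = 1e-180


@dataclass(frozen=True)
class MatchCriterion:
    """The homology match standard: identity share of the full query
    length (strict >) plus a minimum perfect-match run length."""

    min_identity_fraction: float = 0.75
    min_perfect_run: int = 20

    def __post_init__(self):
        if not 0 < self.min_identity_fraction <= 1:
            raise ValueError("min_identity_fraction must be in (0, 1]")
        if self.min_perfect_run < 1:
            raise ValueError("min_perfect_run must be >= 1")


@dataclass
class AlignmentResult:
    """Statistics of one pairwise local alignment.

    ``longest_perfect_run`` is the longest stretch of aligned columns
    that are identical with no intervening mismatch or gap; it is None
    for imported tabular hits (the alignment strings are not available)
    and the match criterion then requires re-alignment.  ``e_value`` is
    None for internally computed alignments (no Karlin-Altschul
    calibration is attempted).
    """

    query_id: str
    subject_id: str
    n_identities: int
    alignment_length: int
    mismatches: int
    gap_openings: int
    bitscore: float
    query_length: int | None = None
    e_value: float | None = None
    longest_perfect_run: int | None = None

    def __post_init__(self):
        if self.n_identities > self.alignment_length:
            raise ValueError("identities exceed alignment length")
        if self.longest_perfect_run is not None and self.longest_perfect_run > self.alignment_length:
            raise ValueError("perfect run exceeds alignment length")
        if self.gap_openings < 0 or (self.e_value is not None and self.e_value < 0):
            raise ValueError("negative gap openings / e-value")


@dataclass
class ProteinTypeCluster:
    """A collapsed set of mutually homologous proteins."""

    members: list[str]
    representative: str

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a member")

    def __len__(self) -> int:
        return len(self.members)


def _make_aligner(open_gap: float = 11.0, extend_gap: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


_MATRIX_ALPHABET = set(substitution_matrices.load("BLOSUM62").alphabet)


def _scoreable(seq: str) -> str:
    # residues absent from BLOSUM62 (e.g. selenocysteine U) score as X;
    # identity counting below still compares the original characters
    return "".join(ch if ch in _MATRIX_ALPHABET else "X" for ch in seq)


def align_pair(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    aligner: Align.PairwiseAligner | None = None,
    query_id: str | None = None,
    subject_id: str | None = None,
) -> AlignmentResult:
    """Smith-Waterman local alignment of two protein sequences.

    Deterministic for a fixed scoring configuration; `a` is the query
    (its full length is the identity denominator in the match
    criterion).  Sequences with no positive-scoring local alignment
    yield an all-zero result.
    """
    qid = query_id or (a.primary_accession if isinstance(a, ProteinRecord) else "query")
    sid = subject_id or (b.primary_accession if isinstance(b, ProteinRecord) else "subject")
    qseq = a.sequence if isinstance(a, ProteinRecord) else a
    sseq = b.sequence if isinstance(b, ProteinRecord) else b
    if not qseq or not sseq:
        raise ValueError("cannot align an empty sequence")
    aligner = aligner or _make_aligner()

    alignments = aligner.align(_scoreable(qseq), _scoreable(sseq))
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(qid, sid, 0, 0, 0, 0, 0.0, query_length=len(qseq),
                               longest_perfect_run=0)
    aln = alignments[0]

    identities = mismatches = gap_openings = 0
    aligned_cols = 0
    longest_run = run = 0
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in zip(aln.aligned[0], aln.aligned[1]):
        if prev_qe is not None:
            if qs > prev_qe:
                gap_openings += 1
            if ss > prev_se:
                gap_openings += 1
            run = 0
        for qi, si in zip(range(qs, qe), range(ss, se)):
            aligned_cols += 1
            if qseq[qi] == sseq[si]:
                identities += 1
                run += 1
                longest_run = max(longest_run, run)
            else:
                mismatches += 1
                run = 0
        prev_qe, prev_se = qe, se

    qb, qe_all = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    sb, se_all = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    alignment_length = aligned_cols + ((qe_all - qb) - aligned_cols) + ((se_all - sb) - aligned_cols)
    return AlignmentResult(
        query_id=qid,
        subject_id=sid,
        n_identities=identities,
        alignment_length=alignment_length,
        mismatches=mismatches,
        gap_openings=gap_openings,
        bitscore=float(aln.score),
        query_length=len(qseq),
        longest_perfect_run=longest_run,
    )


class BlastTabularError(ValueError):
    pass


def import_blast_tabular(path: str | Path) -> list[AlignmentResult]:
    """Read a 12-column BLAST tabular file (outfmt-6 dialect).

    Columns: query, subject, %identity, alignment length, mismatches,
    gap openings, q.start, q.end, s.start, s.end, e-value, bitscore.
    ``n_identities`` is reconstructed as round(%identity x length / 100);
    ``longest_perfect_run`` is unavailable from this format.
    """
    results = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 12:
                raise BlastTabularError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            pident = float(fields[2])
            length = int(fields[3])
            results.append(
                AlignmentResult(
                    query_id=fields[0],
                    subject_id=fields[1],
                    n_identities=round(pident * length / 100.0),
                    alignment_length=length,
                    mismatches=int(fields[4]),
                    gap_openings=int(fields[5]),
                    e_value=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return results


def write_blast_tabular(results: Iterable[AlignmentResult], path: str | Path) -> None:
    """Write results in the 12-column tabular dialect (best-effort fields)."""
    with open(path, "w") as handle:
        for r in results:
            pident = 100.0 * r.n_identities / r.alignment_length if r.alignment_length else 0.0
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.subject_id, f"{pident:.2f}", r.alignment_length,
                        r.mismatches, r.gap_openings, 0, 0, 0, 0,
                        r.e_value if r.e_value is not None else 0.0, r.bitscore,
                    )
                )
                + "\n"
            )


def is_match(result: AlignmentResult, criterion: MatchCriterion = MatchCriterion()) -> bool:
    """Apply the homology match standard to one alignment.

    True iff identities strictly exceed ``min_identity_fraction`` of the
    full query length AND the alignment contains a perfect run of at
    least ``min_perfect_run`` residues.
    """
    if not result.query_length:
        raise ValueError(
            f"query_length unknown for {result.query_id}->{result.subject_id}; "
            "attach it from the library before applying the criterion"
        )
    if result.longest_perfect_run is None:
        raise ValueError(
            f"{result.query_id}->{result.subject_id} lacks a perfect-run length "
            "(imported tabular hit); re-align to apply the criterion"
        )
    frac = result.n_identities / result.query_length
    return frac > criterion.min_identity_fraction and (
        result.longest_perfect_run >= criterion.min_perfect_run
    )


def top_hit_per_query(results: Iterable[AlignmentResult]) -> dict[str, AlignmentResult]:
    """Best non-self hit per query: maximal bitscore, ties broken by
    lower e-value then lexicographic subject id.  Queries with only
    self-hits are omitted."""
    best: dict[str, AlignmentResult] = {}
    for r in sorted(
        results,
        key=lambda r: (
            r.query_id,
            -r.bitscore,
            r.e_value if r.e_value is not None else 0.0,
            r.subject_id,
        ),
    ):
        if r.query_id == r.subject_id:
            continue
        best.setdefault(r.query_id, r)
    return best


def all_pairs_alignments(
    library: FederatedLibrary | Sequence[ProteinRecord],
    aligner: Align.PairwiseAligner | None = None,
) -> list[AlignmentResult]:
    """Every ordered non-self pair — the internal stand-in for an
    all-vs-all BLAST of a small library."""
    aligner = aligner or _make_aligner()
    records = list(library)
    out = []
    for q in records:
        for s in records:
            if q is s:
                continue
            out.append(align_pair(q, s, aligner=aligner))
    return out


def collapse_types(
    library: FederatedLibrary | Sequence[ProteinRecord],
    top_hits: Mapping[str, AlignmentResult],
    criterion: MatchCriterion = MatchCriterion(),
) -> list[ProteinTypeCluster]:
    """Collapse proteins into types via connected components of match edges.

    Every top hit satisfying the criterion contributes an undirected
    edge; components are protein types.  The partition is independent of
    edge direction even when the criterion itself is asymmetric
    (fragment as query matches its parent, not vice versa).  The
    representative is the longest member, ties broken by accession.
    Clusters are returned sorted by representative.
    """
    records = {r.primary_accession: r for r in library}
    graph = nx.Graph()
    graph.add_nodes_from(records)
    for hit in top_hits.values():
        if hit.query_id in records and hit.subject_id in records and is_match(hit, criterion):
            graph.add_edge(hit.query_id, hit.subject_id)
    clusters = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        rep = min(members, key=lambda acc: (-records[acc].length, acc))
        clusters.append(ProteinTypeCluster(members, rep))
    return sorted(clusters, key=lambda c: c.representative)


def singleton_count(clusters: Iterable[ProteinTypeCluster]) -> int:
    """Proteins with no close homologue (clusters of size one)."""
    return sum(1 for c in clusters if len(c) == 1)


def write_cluster_table(clusters: Iterable[ProteinTypeCluster], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"cluster_id": i, "representative": c.representative, "members": ";".join(c.members)}
        for i, c in enumerate(clusters, start=1)
    ]
    pd.DataFrame(rows, columns=["cluster_id", "representative", "members"]).to_csv(
        path, sep="\t", index=False
    )


def _log10_bin(value: float) -> int:
    return math.floor(math.log10(value))


def alignment_distributions(
    results: Iterable[AlignmentResult],
) -> dict[str, DistributionTable]:
    """The five alignment-statistic histograms.

    e-value (log10 exponent bins, values below 1e-180 in a separate
    ``machine_zero`` bin, internally computed alignments without an
    e-value in an ``unavailable`` bin), gap openings, log10 alignment
    length, log10 mismatches (separate zero bin), percent identity
    (integer percent).  Each table's bin totals equal the input count.
    """
    results = list(results)
    evalue_bins, gaps, loglen, logmm, pident = [], [], [], [], []
    for r in results:
        if r.e_value is None:
            evalue_bins.append("unavailable")
        elif r.e_value < MACHINE_ZERO_EVALUE:
            evalue_bins.append("machine_zero")
        else:
            evalue_bins.append(_log10_bin(r.e_value))
        gaps.append(r.gap_openings)
        loglen.append(_log10_bin(r.alignment_length) if r.alignment_length else "empty")
        logmm.append(_log10_bin(r.mismatches) if r.mismatches else "zero")
        pident.append(
            round(100.0 * r.n_identities / r.alignment_length) if r.alignment_length else 0
        )
    return {
        "e_value": DistributionTable.from_values("e_value_log10", evalue_bins),
        "gap_openings": DistributionTable.from_values("gap_openings", gaps),
        "alignment_length": DistributionTable.from_values("alignment_length_log10", loglen),
        "mismatches": DistributionTable.from_values("mismatches_log10", logmm),
        "percent_identity": DistributionTable.from_values("percent_identity", pident),
    }
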