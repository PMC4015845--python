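"""The evidence-reduction cascade.

Raw peptide lists are reduced in stages — exact dedupe, removal of
peptides that are contiguous substrings of longer peptides, substring
mapping onto the federated library — and the per-protein counters that
fall out (redundant, distinct, unique peptide counts) drive the
confidence tiers: proteins supported by three or more distinct peptides
carry a false-positive expectation below one percent, while roughly 88%
of false positives are single-peptide hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .library import FederatedLibrary, ProteinRecord
from .search import SubstringIndex
from .store import EvidenceStore

TIER_SINGLE = "single"
TIER_DOUBLE = "double"
TIER_HIGH = "high"

#: minimum distinct peptides for the high-confidence tier (<1% FDR heuristic)
HIGH_CONFIDENCE_MIN_PEPTIDES = 3


@dataclass
class DistributionTable:
    """A labelled histogram; frequencies sum to the number counted."""

    name: str
    bins: list = field(default_factory=list)
    frequencies: list[int] = field(default_factory=list)

    @classmethod
    def from_values(cls, name: str, values: Iterable) -> "DistributionTable":
        counts: dict = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        keys = sorted(counts, key=lambda k: (isinstance(k, str), k))
        return cls(name, keys, [counts[k] for k in keys])

    @property
    def total(self) -> int:
        return sum(self.frequencies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bins, "frequency": self.frequencies})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def distinct_peptides(peptides: Iterable[str]) -> set[str]:
    """Exact string dedupe (SQL ``DISTINCT`` semantics)."""
    return set(peptides)


def remove_subset_peptides(peptides: set[str]) -> set[str]:
    """Drop peptides that are contiguous substrings of longer peptides.

    Only maximal elements survive; overlap without containment keeps
    both.  Linear-time via the shared Aho-Corasick automaton.
    """
    peps = list(peptides)
    if not peps:
        return set()
    index = SubstringIndex(peps)
    contained: set[str] = set()
    for host in peps:
        for hit in index.patterns_in(host):
            if hit != host:
                contained.add(hit)
    return set(peps) - contained


def map_peptides_to_library(
    peptides: Iterable[str], library: FederatedLibrary
) -> tuple[list[tuple[str, ProteinRecord]], list[str]]:
    """Exhaustive substring mapping of peptides onto library sequences.

    Returns ``(rows, unmapped)`` where a row ``(p, r)`` exists iff `p` is
    a contiguous substring of ``r.sequence``; a peptide occurring at
    several offsets in one protein yields a single row.
    """
    hits = library.map_peptides(peptides)
    rows = [(pep, rec) for pep, recs in sorted(hits.items()) for rec in recs]
    unmapped = sorted(p for p, recs in hits.items() if not recs)
    return rows, unmapped


def protein_counts(store: EvidenceStore) -> pd.DataFrame:
    """Per-protein (redundant_count, distinct_peptide_count, unique_peptide_count)."""
    return store.protein_counts()


def peptide_protein_distribution(
    store: EvidenceStore, mode: Literal["redundant", "distinct"] = "distinct"
) -> DistributionTable:
    """Histogram of proteins by their peptide count (detected proteins only).

    The sum of frequencies equals the number of proteins with at least
    one mapped peptide.  Log-scaled axes, as used when plotting these
    distributions, are presentation only — the table stores raw counts.
    """
    counts = store.protein_counts()
    col = "redundant_count" if mode == "redundant" else "distinct_peptide_count"
    values = counts.loc[counts.distinct_peptide_count > 0, col]
    return DistributionTable.from_values(f"peptides_per_protein_{mode}", values)


def unique_peptide_proteins(store: EvidenceStore) -> tuple[set[str], set[str]]:
    """Proteins backed by at least one unique (characteristic) peptide.

    A peptide is unique iff it occurs in exactly one distinct protein
    sequence of the library.  Returns ``(with_unique, high_confidence)``
    where the second set additionally requires >= 3 distinct peptides in
    total; it is always a subset of the first.  Protein identity is the
    federated accession string.
    """
    counts = store.protein_counts()
    with_unique = set(counts.loc[counts.unique_peptide_count >= 1, "accessions"])
    high = set(
        counts.loc[
            (counts.unique_peptide_count >= 1)
            & (counts.distinct_peptide_count >= HIGH_CONFIDENCE_MIN_PEPTIDES),
            "accessions",
        ]
    )
    return with_unique, high


def confidence_tier(distinct_peptide_count: int) -> str:
    """Map a distinct-peptide count to its confidence tier.

    One peptide -> ``single`` (the bulk of false positives), two ->
    ``double``, three or more -> ``high`` (<1% expected false-positive
    rate).
    """
    if distinct_peptide_count < 1:
        raise ValueError("confidence tier needs a count >= 1")
    if distinct_peptide_count == 1:
        return TIER_SINGLE
    if distinct_peptide_count == 2:
        return TIER_DOUBLE
    return TIER_HIGH


def cascade_summary(raw_peptides: list[str]) -> dict[str, int]:
    """Counts along the peptide reduction cascade (raw >= distinct >= post-subset)."""
    distinct = distinct_peptides(raw_peptides)
    maximal = remove_subset_peptides(distinct)
    return {
        "raw_peptides": len(raw_peptides),
        "distinct_peptides": len(distinct),
        "post_subset_peptides": len(maximal),
    }
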