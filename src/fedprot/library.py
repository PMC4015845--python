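"""Federated, non-redundant protein sequence libraries.

A federated library merges protein sequences drawn from several source
databases (RefSeq, Ensembl, UniProt, ...) into a single non-redundant
collection: records with byte-identical sequences are collapsed into one
record whose accessions are concatenated, and sequences that are perfect
contiguous substrings of a longer sequence (fragments, partial entries)
are absorbed by their superset record.  All peptide evidence downstream
is mapped onto this library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .search import SubstringIndex

#: the 20 standard residues plus ambiguity/extended codes accepted in library
#: sequences.  I and L are distinct; ambiguity codes compare literally.
RESIDUE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")


class FastaParseError(ValueError):
    """A FASTA entry could not be turned into a valid protein record."""


class AccessionConflictError(ValueError):
    """The same accession is attached to two different sequences."""


@dataclass
class ProteinRecord:
    """One library sequence with its federated accessions and annotations.

    Parameters
    ----------
    sequence : str
        Uppercase amino-acid string.  Stop characters (``*``) are the
        caller's responsibility to strip; see :func:`load_fasta`.
    accessions : list of str
        Ordered, duplicate-free accession list.  Serialized forms join
        them with semicolons.
    sources : list of str
        Names of the source libraries this record was drawn from.
    description : str
        Free text; semicolon-concatenated when records are merged.
    go_cc, go_mf, go_bp : list of str
        Gene Ontology label strings (cellular component, molecular
        function, biological process).  Labels are treated atomically.
    """

    sequence: str
    accessions: list[str]
    sources: list[str] = field(default_factory=list)
    description: str = ""
    go_cc: list[str] = field(default_factory=list)
    go_mf: list[str] = field(default_factory=list)
    go_bp: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("protein sequence must be non-empty")
        if not self.accessions:
            raise ValueError("protein record needs at least one accession")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError(f"duplicate accessions: {self.accessions}")
        if any(not a for a in self.accessions):
            raise ValueError("empty accession field")
        bad = set(self.sequence) - RESIDUE_ALPHABET
        if bad:
            raise ValueError(
                f"non-residue characters {sorted(bad)} in sequence of "
                f"{self.accessions[0]}"
            )

    @property
    def length(self) -> int:
        """Residue count."""
        return len(self.sequence)

    @property
    def primary_accession(self) -> str:
        return self.accessions[0]

    @property
    def accession_string(self) -> str:
        """Semicolon-concatenated accessions (no empty fields)."""
        return ";".join(self.accessions)


class FederatedLibrary:
    """A non-redundant set of :class:`ProteinRecord` with a substring index.

    Invariants: no two records share an identical sequence, and every
    accession maps to exactly one record.
    """

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        seqs: dict[str, str] = {}
        self._by_accession: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.sequence in seqs:
                raise ValueError(
                    f"duplicate sequence shared by {seqs[rec.sequence]} and "
                    f"{rec.primary_accession}; merge libraries first"
                )
            seqs[rec.sequence] = rec.primary_accession
            for acc in rec.accessions:
                if acc in self._by_accession:
                    raise AccessionConflictError(
                        f"accession {acc!r} attached to two records"
                    )
                self._by_accession[acc] = rec
        self._index: SubstringIndex | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FederatedLibrary):
            return NotImplemented
        key = lambda r: r.sequence
        return sorted(self.records, key=key) == sorted(other.records, key=key)

    def get(self, accession: str) -> ProteinRecord:
        return self._by_accession[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def records_containing(self, query: str) -> list[ProteinRecord]:
        """All records whose sequence contains `query` as a substring."""
        return [r for r in self.records if query in r.sequence]

    def map_peptides(self, peptides: Iterable[str]) -> dict[str, list[ProteinRecord]]:
        """Map many peptides at once via the Aho-Corasick index.

        Returns ``{peptide: [records containing it]}`` for every input
        peptide (unmapped peptides map to an empty list).
        """
        peptides = list(dict.fromkeys(peptides))
        if self._index is None or set(self._index.patterns) != set(peptides):
            self._index = SubstringIndex(peptides)
        hits: dict[str, list[ProteinRecord]] = {p: [] for p in peptides}
        for rec in self.records:
            for pep in self._index.patterns_in(rec.sequence):
                hits[pep].append(rec)
        return hits


def load_fasta(path: str | Path, source: str | None = None) -> list[ProteinRecord]:
    """Parse a FASTA file into protein records.

    The header's first whitespace-delimited token is the accession (it may
    itself be a semicolon-concatenated federated accession string); the
    remainder of the header is the description.  Sequences are uppercased
    and trailing stop characters (``*``) stripped.  No deduplication is
    performed here — merging happens in :func:`merge_libraries`.
    """
    path = Path(path)
    src = source if source is not None else path.stem
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise FastaParseError(f"entry {entry.id!r} in {path} has an empty sequence")
        accessions = [a for a in entry.id.split(";") if a]
        desc = entry.description[len(entry.id):].strip()
        try:
            records.append(
                ProteinRecord(seq, accessions, sources=[src], description=desc)
            )
        except ValueError as exc:
            raise FastaParseError(f"entry {entry.id!r} in {path}: {exc}") from exc
    return records


def merge_libraries(libraries: Sequence[Sequence[ProteinRecord]]) -> FederatedLibrary:
    """Federate several record lists into one non-redundant library.

    Records with byte-identical sequences merge into a single record whose
    accession list is the sorted union and whose descriptions are
    semicolon-concatenated in accession order of the constituent records.
    Raises :class:`AccessionConflictError` if one accession is attached to
    two different sequences.
    """
    from .annotate import merge_descriptions

    by_seq: dict[str, list[ProteinRecord]] = {}
    acc_seq: dict[str, str] = {}
    for lib in libraries:
        for rec in lib:
            for acc in rec.accessions:
                if acc in acc_seq and acc_seq[acc] != rec.sequence:
                    raise AccessionConflictError(
                        f"accession {acc!r} attached to two different sequences"
                    )
                acc_seq[acc] = rec.sequence
            by_seq.setdefault(rec.sequence, []).append(rec)

    merged = []
    for seq, group in by_seq.items():
        group = sorted(group, key=lambda r: min(r.accessions))
        accessions = sorted({a for r in group for a in r.accessions})
        description = merge_descriptions([r.description for r in group if r.description])
        sources = list(dict.fromkeys(s for r in group for s in r.sources))
        go = {
            cat: list(dict.fromkeys(t for r in group for t in getattr(r, cat)))
            for cat in ("go_cc", "go_mf", "go_bp")
        }
        merged.append(
            ProteinRecord(seq, accessions, sources=sources, description=description, **go)
        )
    return FederatedLibrary(merged)


def remove_subset_proteins(library: FederatedLibrary) -> FederatedLibrary:
    """Drop records that are perfect contiguous substrings of a longer record.

    The absorbed record's accessions are appended to its superset record.
    When a fragment is contained in several longer records, the superset
    chosen is the longest one, ties broken by lexicographically smallest
    first accession, so the output is deterministic.
    """
    recs = sorted(library.records, key=lambda r: (-r.length, r.primary_accession))
    index = SubstringIndex([r.sequence for r in recs])
    by_seq = {r.sequence: r for r in recs}
    # containers[fragment_seq] = chosen superset sequence
    containers: dict[str, str] = {}
    for host in recs:
        for frag_seq in index.patterns_in(host.sequence):
            if frag_seq == host.sequence:
                continue
            cur = containers.get(frag_seq)
            if cur is None:
                containers[frag_seq] = host.sequence
            else:
                best = by_seq[cur]
                if (-host.length, host.primary_accession) < (-best.length, best.primary_accession):
                    containers[frag_seq] = host.sequence

    # follow chains so fragments-of-fragments land in a surviving record
    def resolve(seq: str) -> str:
        while seq in containers:
            seq = containers[seq]
        return seq

    absorbed: dict[str, list[ProteinRecord]] = {}
    for frag_seq in containers:
        absorbed.setdefault(resolve(frag_seq), []).append(by_seq[frag_seq])

    out = []
    for rec in recs:
        if rec.sequence in containers:
            continue
        extra = sorted(absorbed.get(rec.sequence, []), key=lambda r: r.primary_accession)
        if not extra:
            out.append(rec)
            continue
        accessions = rec.accessions + [a for r in extra for a in r.accessions]
        out.append(
            ProteinRecord(
                rec.sequence,
                accessions,
                sources=list(dict.fromkeys(rec.sources + [s for r in extra for s in r.sources])),
                description=rec.description,
                go_cc=rec.go_cc,
                go_mf=rec.go_mf,
                go_bp=rec.go_bp,
            )
        )
    return FederatedLibrary(out)


def write_fasta(library: FederatedLibrary | Iterable[ProteinRecord], path: str | Path) -> None:
    """Export as FASTA with semicolon-concatenated accession headers, 60-col wrap."""
    entries = [
        SeqRecord(Seq(rec.sequence), id=rec.accession_string, description=rec.description)
        for rec in library
    ]
    with open(path, "w") as handle:
        SeqIO.write(entries, handle, "fasta")


def write_library_table(library: FederatedLibrary, path: str | Path) -> None:
    """Export the library as a TSV (accessions, length, sources, description)."""
    import pandas as pd

    rows = [
        {
            "accessions": rec.accession_string,
            "length": rec.length,
            "sources": ";".join(rec.sources),
            "description": rec.description,
        }
        for rec in sorted(library, key=lambda r: r.primary_accession)
    ]
    pd.DataFrame(rows, columns=["accessions", "length", "sources", "description"]).to_csv(
        path, sep="\t", index=False
    )
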