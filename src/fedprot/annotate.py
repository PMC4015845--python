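"""Annotation transfer and GO frequency summaries.

Annotations (description, gene symbol, GO cellular component /
molecular function / biological process labels) attach to federated
records directly by accession; records without a direct hit inherit
from their protein-type cluster representative (homology transfer), and
the provenance of every attachment is recorded.  GO labels are treated
as flat atomic strings — the comma-joined label sets that annotation
pipelines emit are kept as single rows, with an optional split-to-terms
granularity — and summarized as count/frequency tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .library import FederatedLibrary, ProteinRecord

GO_CATEGORIES = {"cc": "go_cc", "mf": "go_mf", "bp": "go_bp"}


def merge_descriptions(descriptions: Iterable[str]) -> str:
    """Duplicate-free, order-stable semicolon join."""
    return ";".join(dict.fromkeys(d for d in descriptions if d))


@dataclass
class Annotation:
    accession: str
    description: str = ""
    gene_symbol: str = ""
    go_cc: list[str] = field(default_factory=list)
    go_mf: list[str] = field(default_factory=list)
    go_bp: list[str] = field(default_factory=list)


@dataclass
class AnnotatedProtein:
    """A library record plus attached annotation and its provenance."""

    record: ProteinRecord
    description: str = ""
    gene_symbol: str = ""
    go_cc: list[str] = field(default_factory=list)
    go_mf: list[str] = field(default_factory=list)
    go_bp: list[str] = field(default_factory=list)
    provenance: Literal["direct", "transferred", "none"] = "none"

    @property
    def accession(self) -> str:
        return self.record.primary_accession


@dataclass
class AnnotationReport:
    n_direct: int = 0
    n_transferred: int = 0
    n_unannotated: int = 0
    orphan_accessions: list[str] = field(default_factory=list)  # not in library


def read_annotation_table(path: str | Path) -> list[Annotation]:
    """TSV columns: accession, description, gene_symbol, go_cc, go_mf, go_bp.

    Each GO cell is one atomic label string (may contain commas, matching
    the comma-joined style of curated exports); empty cells give no label.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Annotation(
                accession=row.accession,
                description=getattr(row, "description", ""),
                gene_symbol=getattr(row, "gene_symbol", ""),
                go_cc=[row.go_cc] if getattr(row, "go_cc", "") else [],
                go_mf=[row.go_mf] if getattr(row, "go_mf", "") else [],
                go_bp=[row.go_bp] if getattr(row, "go_bp", "") else [],
            )
        )
    return out


def attach_annotations(
    library: FederatedLibrary,
    annotations: Sequence[Annotation],
    clusters: Sequence | None = None,
) -> tuple[list[AnnotatedProtein], AnnotationReport]:
    """Attach annotations by accession, then transfer within clusters.

    A record matching any annotation accession gets a ``direct``
    attachment; an unannotated member of a cluster whose representative
    (or any other member) is annotated inherits that annotation with
    ``transferred`` provenance.  Annotation rows whose accession occurs
    nowhere in the library are counted in the report.
    """
    report = AnnotationReport()
    by_acc: dict[str, Annotation] = {}
    for ann in annotations:
        by_acc[ann.accession] = ann
        if ann.accession not in library:
            report.orphan_accessions.append(ann.accession)

    annotated: dict[str, AnnotatedProtein] = {}
    for rec in library:
        hit = next((by_acc[a] for a in rec.accessions if a in by_acc), None)
        ap = AnnotatedProtein(record=rec)
        if hit is not None:
            ap.description = hit.description or rec.description
            ap.gene_symbol = hit.gene_symbol
            ap.go_cc, ap.go_mf, ap.go_bp = list(hit.go_cc), list(hit.go_mf), list(hit.go_bp)
            ap.provenance = "direct"
            report.n_direct += 1
        else:
            ap.description = rec.description
        annotated[rec.primary_accession] = ap

    if clusters:
        for cluster in clusters:
            members = [annotated[m] for m in cluster.members if m in annotated]
            donors = [m for m in members if m.provenance == "direct"]
            if not donors:
                continue
            rep = annotated.get(cluster.representative)
            donor = rep if (rep is not None and rep.provenance == "direct") else donors[0]
            for ap in members:
                if ap.provenance == "none":
                    ap.description = ap.description or donor.description
                    ap.gene_symbol = donor.gene_symbol
                    ap.go_cc = list(donor.go_cc)
                    ap.go_mf = list(donor.go_mf)
                    ap.go_bp = list(donor.go_bp)
                    ap.provenance = "transferred"
                    report.n_transferred += 1

    report.n_unannotated = sum(1 for ap in annotated.values() if ap.provenance == "none")
    return [annotated[k] for k in sorted(annotated)], report


@dataclass
class FrequencyTable:
    """Rows of (term, count, frequency) over a stated total.

    Frequencies are count/total rounded half-even to 5 decimals; the
    implicit "Total" row has frequency 1 and appears on TSV export.
    """

    rows: list[tuple[str, int, float]]
    total: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], total: int | None = None) -> "FrequencyTable":
        tot = total if total is not None else sum(counts.values())
        rows = [
            (term, n, round(n / tot, 5) if tot else 0.0)
            for term, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return cls(rows, tot)

    def frequency_of(self, term: str) -> float:
        for t, _, f in self.rows:
            if t == term:
                return f
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame([("Total", self.total, 1.0)], columns=["term", "count", "frequency"])
        body = pd.DataFrame(self.rows, columns=["term", "count", "frequency"])
        return pd.concat([head, body], ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def frequency_table(
    annotated: Sequence[AnnotatedProtein],
    category: Literal["cc", "mf", "bp"],
    granularity: Literal["joined", "term"] = "joined",
    total_mode: Literal["rows", "proteins"] = "rows",
) -> FrequencyTable:
    """GO label frequency table for one category.

    ``joined`` granularity counts each attached label string atomically
    (one row per label set, as in curated summary tables); ``term``
    splits labels on commas into individual terms.  The denominator is
    the number of annotation rows (labels) by default, or the number of
    labeled proteins with ``total_mode='proteins'``.
    """
    attr = GO_CATEGORIES[category]
    counts: dict[str, int] = {}
    labeled_proteins = 0
    n_rows = 0
    for ap in annotated:
        labels = getattr(ap, attr)
        if granularity == "term":
            labels = [t.strip() for lab in labels for t in lab.split(",") if t.strip()]
        if labels:
            labeled_proteins += 1
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
            n_rows += 1
    total = n_rows if total_mode == "rows" else labeled_proteins
    if not counts:
        return FrequencyTable([], 0)
    return FrequencyTable.from_counts(counts, total)


def query_category(
    annotated: Sequence[AnnotatedProtein],
    keywords: Sequence[str],
    min_distinct_peptides: int = 0,
    peptide_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Keyword category query with minimum-peptide filtering.

    Selects proteins whose description, GO labels or gene symbol contain
    at least one keyword (case-insensitive substring) and whose distinct
    peptide count reaches ``min_distinct_peptides`` (0 = unfiltered).
    ``peptide_counts`` maps either primary or federated accession
    strings to distinct peptide counts.  The output carries gene symbols
    for downstream network tools.
    """
    if not keywords:
        raise ValueError("at least one keyword is required")
    kws = [k.lower() for k in keywords]
    counts = peptide_counts or {}
    rows = []
    for ap in annotated:
        haystack = " ".join(
            [ap.description, ap.gene_symbol, *ap.go_cc, *ap.go_mf, *ap.go_bp]
        ).lower()
        if not any(k in haystack for k in kws):
            continue
        n = counts.get(ap.accession, counts.get(ap.record.accession_string, 0))
        if n < min_distinct_peptides:
            continue
        rows.append((ap.accession, ap.gene_symbol, n))
    return pd.DataFrame(rows, columns=["accession", "gene_symbol", "distinct_peptide_count"])
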