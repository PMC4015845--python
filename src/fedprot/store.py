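"""Relational evidence store: peptides, proteins and their mapping.

The store keeps every observation, the peptide-to-protein substring
mapping against the federated library, and per-study provenance in an
embedded SQLite database, so redundant/distinct/unique counts can be
answered with plain SQL without re-ingesting the source files.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ingest import PeptideObservation, StudyMeta
from .library import FederatedLibrary

_SCHEMA = """
CREATE TABLE IF NOT EXISTS study (
    study_id TEXT PRIMARY KEY,
    label TEXT,
    format_name TEXT
);
CREATE TABLE IF NOT EXISTS protein (
    protein_id INTEGER PRIMARY KEY,
    accessions TEXT NOT NULL,
    length INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS observation (
    obs_id INTEGER PRIMARY KEY,
    peptide TEXT NOT NULL,
    study_id TEXT NOT NULL,
    reported_accession TEXT,
    spectral_count INTEGER NOT NULL,
    mapped INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS mapping (
    peptide TEXT NOT NULL,
    protein_id INTEGER NOT NULL,
    UNIQUE (peptide, protein_id)
);
CREATE INDEX IF NOT EXISTS idx_mapping_peptide ON mapping (peptide);
CREATE INDEX IF NOT EXISTS idx_obs_peptide ON observation (peptide);
"""


class StoreIntegrityError(RuntimeError):
    pass


class EvidenceStore:
    """Peptide/protein evidence in an embedded relational database.

    Use :func:`build_evidence_store` to create one from observations and
    a federated library; open an existing file with ``EvidenceStore(path)``.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    # -- loading ----------------------------------------------------------

    def add_studies(self, studies: Iterable[StudyMeta]) -> None:
        self.conn.executemany(
            "INSERT OR REPLACE INTO study VALUES (?,?,?)",
            [(s.study_id, s.label, s.format_name) for s in studies],
        )
        self.conn.commit()

    def load(
        self,
        observations: Sequence[PeptideObservation],
        library: FederatedLibrary,
    ) -> None:
        """Persist observations and their substring mapping onto `library`.

        Peptides mapping to zero library proteins are retained with
        ``mapped = 0`` and show up in :meth:`unmapped_peptides`.
        """
        acc_to_id: dict[str, int] = {}
        rows = []
        for pid, rec in enumerate(
            sorted(library, key=lambda r: r.primary_accession), start=1
        ):
            rows.append((pid, rec.accession_string, rec.length))
            acc_to_id[rec.primary_accession] = pid
        self.conn.executemany("INSERT INTO protein VALUES (?,?,?)", rows)

        hits = library.map_peptides([o.peptide for o in observations])
        self.conn.executemany(
            "INSERT OR IGNORE INTO mapping VALUES (?,?)",
            [
                (pep, acc_to_id[rec.primary_accession])
                for pep, recs in sorted(hits.items())
                for rec in recs
            ],
        )
        self.conn.executemany(
            "INSERT INTO observation (peptide, study_id, reported_accession,"
            " spectral_count, mapped) VALUES (?,?,?,?,?)",
            [
                (o.peptide, o.study_id, o.reported_accession, o.spectral_count,
                 1 if hits[o.peptide] else 0)
                for o in observations
            ],
        )
        self.conn.commit()

    # -- queries ----------------------------------------------------------

    def observed_peptides(self, distinct: bool = True) -> list[str]:
        q = "SELECT {} peptide FROM observation ORDER BY peptide".format(
            "DISTINCT" if distinct else ""
        )
        return [r[0] for r in self.conn.execute(q)]

    def unmapped_peptides(self) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute(
                "SELECT DISTINCT peptide FROM observation WHERE mapped = 0"
                " ORDER BY peptide"
            )
        ]

    def n_observations(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM observation").fetchone()[0]

    def protein_table(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT protein_id, accessions, length FROM protein ORDER BY protein_id",
            self.conn,
        )

    def protein_counts(self) -> pd.DataFrame:
        """Per-protein redundant, distinct and unique peptide counters.

        redundant_count — total spectrum correlations (sum of spectral
        counts over all observations of the protein's peptides);
        distinct_peptide_count — number of different peptide sequences;
        unique_peptide_count — peptides found in exactly one distinct
        protein sequence of the library.
        """
        df = pd.read_sql_query(
            """
            WITH pep_obs AS (
                SELECT peptide, SUM(spectral_count) AS n_obs
                FROM observation GROUP BY peptide
            ),
            pep_deg AS (
                SELECT peptide, COUNT(*) AS n_proteins FROM mapping GROUP BY peptide
            )
            SELECT p.protein_id,
                   p.accessions,
                   COALESCE(SUM(po.n_obs), 0) AS redundant_count,
                   COUNT(m.peptide) AS distinct_peptide_count,
                   COALESCE(SUM(CASE WHEN pd.n_proteins = 1 THEN 1 ELSE 0 END), 0)
                       AS unique_peptide_count
            FROM protein p
            LEFT JOIN mapping m ON m.protein_id = p.protein_id
            LEFT JOIN pep_obs po ON po.peptide = m.peptide
            LEFT JOIN pep_deg pd ON pd.peptide = m.peptide
            GROUP BY p.protein_id
            ORDER BY p.protein_id
            """,
            self.conn,
        )
        bad = df[
            (df.redundant_count < df.distinct_peptide_count)
            | (df.distinct_peptide_count < df.unique_peptide_count)
        ]
        if len(bad):
            raise StoreIntegrityError(
                f"count invariant violated for proteins {bad.protein_id.tolist()}"
            )
        return df

    def peptide_degeneracy(self) -> pd.DataFrame:
        """How many distinct proteins each mapped peptide occurs in."""
        return pd.read_sql_query(
            "SELECT peptide, COUNT(*) AS n_proteins FROM mapping"
            " GROUP BY peptide ORDER BY peptide",
            self.conn,
        )


def build_evidence_store(
    observations: Sequence[PeptideObservation],
    library: FederatedLibrary,
    studies: Iterable[StudyMeta] = (),
    path: str | Path = ":memory:",
) -> EvidenceStore:
    """Create and populate an :class:`EvidenceStore`."""
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    store = EvidenceStore(path)
    store.add_studies(studies)
    store.load(observations, library)
    return store
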