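"""End-to-end builds and the consolidated corpus report.

``run_build`` executes the whole pipeline — federate the sequence
libraries, ingest every study, reduce the peptide evidence, collapse
homologous proteins into types, attach annotations — from one
declarative config, persisting the evidence store and a report whose
counters can be regenerated byte-identically.  ``summarize`` recomputes
the store-derived counters from the persisted store alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import annotate as ann
from . import homology, reduction
from .ingest import IngestError, StudyMeta, parse_study
from .library import (
    load_fasta,
    merge_libraries,
    remove_subset_proteins,
    write_fasta,
    write_library_table,
)
from .store import EvidenceStore, build_evidence_store


class BuildError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class BuildReport:
    """Corpus counters, distribution tables and provenance of one build."""

    counters: dict[str, int] = field(default_factory=dict)
    distributions: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counters": self.counters,
            "distributions": {
                name: {"bins": [str(b) for b in t.bins], "frequencies": t.frequencies}
                for name, t in self.distributions.items()
            },
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @property
    def report_hash(self) -> str:
        blob = json.dumps(
            {"counters": self.counters, "provenance": self.provenance}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def summarize(store: EvidenceStore) -> BuildReport:
    """Recompute all store-derived counters without re-ingesting."""
    try:
        counts = store.protein_counts()
    except Exception as exc:  # corrupt or half-written store
        raise BuildError(f"summarize: store integrity failure: {exc}") from exc
    observed = store.observed_peptides(distinct=False)
    distinct = reduction.distinct_peptides(observed)
    maximal = reduction.remove_subset_peptides(distinct)
    with_unique, high_unique = reduction.unique_peptide_proteins(store)
    detected = counts[counts.distinct_peptide_count > 0]
    report = BuildReport()
    report.counters = {
        "raw_peptides": len(observed),
        "distinct_peptides": len(distinct),
        "post_subset_peptides": len(maximal),
        "library_proteins": int(len(counts)),
        "detected_proteins": int(len(detected)),
        "high_confidence_proteins": int(
            (detected.distinct_peptide_count >= reduction.HIGH_CONFIDENCE_MIN_PEPTIDES).sum()
        ),
        "unique_peptide_proteins": len(with_unique),
        "unique_high_confidence_proteins": len(high_unique),
        "unmapped_peptides": len(store.unmapped_peptides()),
    }
    report.distributions = {
        "peptides_per_protein_distinct": reduction.peptide_protein_distribution(store, "distinct"),
        "peptides_per_protein_redundant": reduction.peptide_protein_distribution(store, "redundant"),
    }
    return report


def run_build(
    config: Mapping[str, Any] | str | Path,
    outdir: str | Path | None = None,
) -> tuple[BuildReport, EvidenceStore]:
    """Execute federate -> ingest -> reduce -> collapse -> annotate.

    `config` is a mapping (or path to a YAML file) with keys:
    ``library.fasta`` (list of FASTA paths), ``studies`` (list of
    ``{study_id, label, format, path}``), optional ``annotations`` (TSV
    path), ``min_peptide_length``, ``criterion.identity_fraction`` /
    ``criterion.min_perfect_run``, ``db`` (store path, default memory),
    ``seed``.  Writes the store, a JSON report and TSV tables under
    `outdir` when given.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # -- federate ---------------------------------------------------------
    fasta_paths = config.get("library", {}).get("fasta", [])
    if not fasta_paths:
        raise BuildError("federate: config lists no library FASTA files")
    try:
        libraries = [load_fasta(p) for p in fasta_paths]
        merged = merge_libraries(libraries)
        distinct_lib = remove_subset_proteins(merged)
    except BuildError:
        raise
    except Exception as exc:
        raise BuildError(f"federate: {exc}") from exc
    n_redundant = sum(len(lib) for lib in libraries)

    # -- ingest -----------------------------------------------------------
    study_cfgs = config.get("studies", [])
    if not study_cfgs:
        raise BuildError("ingest: config lists no studies")
    min_len = int(config.get("min_peptide_length", 6))
    observations, rejects, metas = [], 0, []
    try:
        for sc in study_cfgs:
            meta = StudyMeta(sc["study_id"], sc.get("label", ""),
                             sc.get("format", "simple_tsv"))
            rep = parse_study(sc["path"], meta, min_peptide_length=min_len)
            observations.extend(rep.observations)
            rejects += len(rep.rejects)
            metas.append(meta)
    except (IngestError, KeyError, OSError) as exc:
        raise BuildError(f"ingest: {exc}") from exc

    # -- reduce -----------------------------------------------------------
    db_path = config.get("db", ":memory:")
    if outdir is not None and db_path != ":memory:" and not Path(db_path).is_absolute():
        db_path = outdir / db_path
    if db_path != ":memory:":
        Path(db_path).unlink(missing_ok=True)
    store = build_evidence_store(observations, distinct_lib, studies=metas, path=db_path)
    report = summarize(store)

    # -- collapse ---------------------------------------------------------
    crit_cfg = config.get("criterion", {})
    criterion = homology.MatchCriterion(
        min_identity_fraction=float(crit_cfg.get("identity_fraction", 0.75)),
        min_perfect_run=int(crit_cfg.get("min_perfect_run", 20)),
    )
    alignments = homology.all_pairs_alignments(distinct_lib)
    top_hits = homology.top_hit_per_query(alignments)
    clusters = homology.collapse_types(distinct_lib, top_hits, criterion)
    report.distributions.update(homology.alignment_distributions(alignments))

    # -- annotate ---------------------------------------------------------
    annotated, ann_report = None, None
    if config.get("annotations"):
        table = ann.read_annotation_table(config["annotations"])
        annotated, ann_report = ann.attach_annotations(distinct_lib, table, clusters)

    report.counters.update(
        {
            "redundant_proteins": n_redundant,
            "distinct_proteins": len(merged),
            "post_subset_proteins": len(distinct_lib),
            "ingest_rejects": rejects,
            "protein_types": len(clusters),
            "singleton_proteins": homology.singleton_count(clusters),
        }
    )
    if ann_report is not None:
        report.counters.update(
            {
                "annotated_direct": ann_report.n_direct,
                "annotated_transferred": ann_report.n_transferred,
                "annotation_orphans": len(ann_report.orphan_accessions),
            }
        )
    report.provenance = {
        "config_hash": _config_hash(dict(config)),
        "seed": config.get("seed"),
        "inputs": {
            "fasta": [str(p) for p in fasta_paths],
            "studies": [str(s["path"]) for s in study_cfgs],
        },
        "criterion": {
            "identity_fraction": criterion.min_identity_fraction,
            "min_perfect_run": criterion.min_perfect_run,
        },
    }

    if outdir is not None:
        report.to_json(outdir / "report.json")
        write_fasta(distinct_lib, outdir / "federated_library.fasta")
        write_library_table(distinct_lib, outdir / "library_table.tsv")
        store.protein_counts().to_csv(outdir / "protein_counts.tsv", sep="\t", index=False)
        homology.write_cluster_table(clusters, outdir / "clusters.tsv")
        for name, table in report.distributions.items():
            table.to_tsv(outdir / f"dist_{name}.tsv")
        if annotated is not None:
            for cat in ("cc", "mf", "bp"):
                ann.frequency_table(annotated, cat).to_tsv(outdir / f"go_{cat}_frequency.tsv")
    return report, store
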