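"""Deterministic synthetic corpora with planted ground truth.

The generator emulates the shape of a federated blood-protein corpus:
families of closely related sequences (splice variants / alleles built
from one base sequence by point substitutions), exact-substring
fragments, and several studies that each report tryptic peptides of the
library proteins in their own file dialect.  Within-family identity is
kept at or above roughly 90% of the full length with a long protected
perfect run, and across families sequences are independent random
strings (expected local identity far below 40%), so the 75%-identity /
20-residue-run match criterion separates families with a wide margin.
All randomness flows from one seeded generator, so a corpus is fully
reproducible and every pipeline stage can be checked against the
emitted truth tables.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .ingest import StudyMeta
from .library import ProteinRecord, write_fasta

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: tail residues never mutated, guaranteeing a within-family perfect run
PROTECTED_TAIL = 30
#: fraction of positions substituted per variant (well above the 75% line)
MUTATION_RATE = 0.05

_DESCRIPTIONS = [
    ("serum albumin precursor", "ALB", "Extracellular region,", "Protein binding,", "Transport,"),
    ("zinc finger transcription factor", "ZNF1", "Nucleus,", "DNA binding, zinc ion binding,",
     "Transcription, regulation of transcription, DNA-dependent,"),
    ("RNA binding protein", "RBP1", "Nucleus, cytoplasm,", "RNA binding,", "Translation,"),
    ("calcium ion binding receptor", "CABR", "Membrane, integral to membrane,",
     "Calcium ion binding, receptor activity,", "Signal transduction,"),
    ("serine protease", "PRSS", "Extracellular space,", "Catalytic activity,", "Proteolysis,"),
    ("cytoskeletal keratin", "KRT", "Cytoskeleton,", "Structural molecule activity,",
     "Cell adhesion,"),
]


class FixtureConfigurationError(ValueError):
    pass


@dataclass
class PlantedTruth:
    """Everything the generator decided, for later exact comparison."""

    seed: int
    n_families: int
    variants_per_family: int
    fragment_fraction: float
    length_range: tuple[int, int]
    families: dict[str, int] = field(default_factory=dict)  # accession -> family
    fragments: list[tuple[str, str]] = field(default_factory=list)  # (fragment, parent)
    unique_peptides: dict[str, list[str]] = field(default_factory=dict)
    abundant_accession: str | None = None
    n_studies: int = 0
    detection_probability: float = 1.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["length_range"] = tuple(data["length_range"])
        data["fragments"] = [tuple(p) for p in data["fragments"]]
        return cls(**data)


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(RESIDUES) for _ in range(length))


def _mutate(rng: random.Random, base: str) -> str:
    """Point-substitute ~5% of positions, never inside the protected tail."""
    editable = len(base) - PROTECTED_TAIL
    n_mut = max(1, int(len(base) * MUTATION_RATE))
    positions = rng.sample(range(editable), min(n_mut, editable))
    seq = list(base)
    for pos in positions:
        seq[pos] = rng.choice([r for r in RESIDUES if r != base[pos]])
    return "".join(seq)


def generate_library(
    n_families: int = 5,
    variants_per_family: int = 3,
    fragment_fraction: float = 0.2,
    length_range: tuple[int, int] = (100, 300),
    seed: int = 7,
) -> tuple[list[ProteinRecord], PlantedTruth]:
    """Build a library of variant families plus exact-substring fragments.

    Emits ``n_families * variants_per_family`` full-length sequences and
    ``round(fragment_fraction * that)`` fragment records that are proper
    contiguous substrings of a parent, cycling over parents.
    """
    if n_families < 1 or variants_per_family < 1:
        raise FixtureConfigurationError("need at least one family and one variant")
    if length_range[0] < PROTECTED_TAIL + 20:
        raise FixtureConfigurationError(
            f"minimum length {length_range[0]} cannot hold the protected "
            f"{PROTECTED_TAIL}-residue run plus an editable region"
        )
    rng = random.Random(seed)
    records: list[ProteinRecord] = []
    truth = PlantedTruth(seed, n_families, variants_per_family, fragment_fraction,
                         tuple(length_range))

    seen: set[str] = set()
    for fam in range(1, n_families + 1):
        base = _random_sequence(rng, rng.randint(*length_range))
        desc, symbol, cc, mf, bp = _DESCRIPTIONS[(fam - 1) % len(_DESCRIPTIONS)]
        for var in range(1, variants_per_family + 1):
            seq = base if var == 1 else _mutate(rng, base)
            while seq in seen:
                seq = _mutate(rng, base)
            seen.add(seq)
            acc = f"F{fam:02d}V{var}"
            records.append(
                ProteinRecord(seq, [acc], sources=["synthetic"],
                              description=f"{desc} variant {var}")
            )
            truth.families[acc] = fam

    full = list(records)
    n_fragments = round(fragment_fraction * len(full))
    for i in range(n_fragments):
        parent = full[i % len(full)]
        # a fragment must be a substring of its parent ONLY, so that
        # subset absorption has a unique, checkable destination; slices of
        # a conserved region would sit inside every family variant
        for _attempt in range(200):
            lo = rng.randint(0, parent.length // 3)
            hi = rng.randint(lo + max(40, parent.length // 2), parent.length - 1)
            frag_seq = parent.sequence[lo:hi]
            hosts = [r for r in full if frag_seq in r.sequence]
            if frag_seq not in seen and hosts == [parent]:
                break
        else:
            raise FixtureConfigurationError(
                f"could not cut an unambiguous fragment from {parent.primary_accession}"
            )
        seen.add(frag_seq)
        acc = f"{parent.primary_accession}FR{i + 1}"
        records.append(
            ProteinRecord(frag_seq, [acc], sources=["synthetic"],
                          description=f"{parent.description} fragment")
        )
        truth.fragments.append((acc, parent.primary_accession))
    return records, truth


def tryptic_digest(
    sequence: str, min_length: int = 1, missed_cleavages: int = 0
) -> list[str]:
    """In-silico trypsin digest: cleave after K or R unless followed by P.

    With ``missed_cleavages`` up to 2, concatenations of up to that many
    adjacent fragments are emitted as well; peptides shorter than
    ``min_length`` are dropped.  With defaults the concatenation of the
    output reconstructs the input.
    """
    if not 0 <= missed_cleavages <= 2:
        raise ValueError("missed_cleavages must be 0, 1 or 2")
    frags: list[str] = []
    start = 0
    for i, ch in enumerate(sequence):
        if ch in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            frags.append(sequence[start:i + 1])
            start = i + 1
    if start < len(sequence):
        frags.append(sequence[start:])
    peptides = []
    for k in range(missed_cleavages + 1):
        for i in range(len(frags) - k):
            pep = "".join(frags[i:i + k + 1])
            if len(pep) >= min_length:
                peptides.append(pep)
    return peptides


def _accession_dialect(acc: str, style: int, rng: random.Random) -> str:
    if style == 1:
        return f"gi|{rng.randint(10_000, 999_999)}|ref|{acc}|"
    if style == 2:
        return f"sp|{acc}|{acc}_HUMAN"
    return acc


def generate_studies(
    records: list[ProteinRecord],
    outdir: str | Path,
    n_studies: int = 3,
    detection_probability: float = 1.0,
    count_geometric_p: float = 0.5,
    min_peptide_length: int = 6,
    abundant_accession: str | None = None,
    abundance_factor: int = 10,
    seed: int = 7,
) -> list[StudyMeta]:
    """Write per-study TSVs of sampled tryptic peptides in mixed dialects.

    Each study reports every digest peptide of every protein with the
    stated probability; spectral counts are geometric (support >= 1), and
    the optional abundant protein's counts are multiplied so it tops the
    redundant-count ranking.  Study files rotate through the registered
    dialects (bare, gi-pipe and sp-pipe accessions; one study uses
    flanked peptide strings) to exercise ingestion.
    """
    rng = random.Random(seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas = []
    for s in range(1, n_studies + 1):
        fmt = "flanked_tsv" if s % 3 == 0 else "simple_tsv"
        meta = StudyMeta(study_id=f"study{s:02d}", label=f"synthetic study {s}",
                         format_name=fmt)
        lines = ["peptide\taccession\tcount"]
        for rec in records:
            for pep in tryptic_digest(rec.sequence, min_length=min_peptide_length):
                if rng.random() > detection_probability:
                    continue
                count = 1
                while rng.random() > count_geometric_p:
                    count += 1
                if rec.primary_accession == abundant_accession:
                    count *= abundance_factor
                if fmt == "flanked_tsv":
                    pos = rec.sequence.find(pep)
                    before = rec.sequence[pos - 1] if pos > 0 else "-"
                    after_i = pos + len(pep)
                    after = rec.sequence[after_i] if after_i < rec.length else "-"
                    pep_str = f"{before}.{pep}.{after}"
                else:
                    pep_str = pep
                acc = _accession_dialect(rec.primary_accession, (s - 1) % 3, rng)
                lines.append(f"{pep_str}\t{acc}\t{count}")
        (outdir / f"{meta.study_id}.tsv").write_text("\n".join(lines) + "\n")
        metas.append(meta)
    return metas


def write_annotation_table(records: list[ProteinRecord], path: str | Path) -> None:
    """Annotation TSV for each family's first variant (others inherit by
    homology transfer through their cluster)."""
    lines = ["accession\tdescription\tgene_symbol\tgo_cc\tgo_mf\tgo_bp"]
    for rec in records:
        acc = rec.primary_accession
        if not acc.endswith("V1") or "FR" in acc:
            continue
        fam = int(acc[1:3])
        desc, symbol, cc, mf, bp = _DESCRIPTIONS[(fam - 1) % len(_DESCRIPTIONS)]
        lines.append(f"{acc}\t{desc}\t{symbol}\t{cc}\t{mf}\t{bp}")
    Path(path).write_text("\n".join(lines) + "\n")


def compute_unique_peptide_truth(
    records: list[ProteinRecord],
    distinct_sequences: list[str],
    min_peptide_length: int = 6,
) -> dict[str, list[str]]:
    """Brute-force unique-peptide truth against the distinct library.

    For every digest peptide of every record, count (with plain ``in``)
    how many distinct library sequences contain it; a protein owns the
    peptide uniquely when that count is one.  Keyed by the sequence so it
    can be matched to post-reduction records regardless of accession
    merging.
    """
    all_peptides = sorted({
        pep
        for rec in records
        for pep in tryptic_digest(rec.sequence, min_length=min_peptide_length)
    })
    unique: dict[str, list[str]] = {}
    for pep in all_peptides:
        hosts = [s for s in distinct_sequences if pep in s]
        if len(hosts) == 1:
            unique.setdefault(hosts[0], []).append(pep)
    return unique


def generate_corpus(
    outdir: str | Path,
    n_families: int = 5,
    variants_per_family: int = 3,
    fragment_fraction: float = 0.2,
    length_range: tuple[int, int] = (100, 300),
    n_studies: int = 3,
    detection_probability: float = 1.0,
    abundant_accession: str | None = None,
    seed: int = 7,
) -> tuple[list[ProteinRecord], list[StudyMeta], PlantedTruth]:
    """Emit a complete corpus: FASTA, study TSVs, annotation TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_library(
        n_families, variants_per_family, fragment_fraction, length_range, seed
    )
    write_fasta(records, outdir / "library.fasta")
    metas = generate_studies(
        records, outdir, n_studies=n_studies,
        detection_probability=detection_probability,
        abundant_accession=abundant_accession, seed=seed,
    )
    write_annotation_table(records, outdir / "annotations.tsv")

    # unique-peptide truth is defined against the subset-reduced distinct
    # library: fragment sequences are absorbed before uniqueness counts
    frag_accs = {f for f, _ in truth.fragments}
    distinct = [r.sequence for r in records if r.primary_accession not in frag_accs]
    seq_unique = compute_unique_peptide_truth(records, distinct)
    acc_of = {r.sequence: r.primary_accession for r in records}
    truth.unique_peptides = {
        acc_of[s]: peps for s, peps in sorted(seq_unique.items(), key=lambda kv: acc_of[kv[0]])
    }
    truth.abundant_accession = abundant_accession
    truth.n_studies = n_studies
    truth.detection_probability = detection_probability
    truth.to_json(outdir / "truth.json")
    return records, metas, truth
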