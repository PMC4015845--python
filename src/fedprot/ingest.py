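"""Parsing heterogeneous per-study identification lists.

Each federated study reports peptides in its own dialect (flanked
peptides like ``K.ELVISLIVESK.R``, inline modification annotations like
``M(ox)``, varied accession formats such as NCBI ``gi|...|ref|...|``).
A registry of named parsers turns each dialect into uniform
:class:`PeptideObservation` rows; rows that cannot be salvaged are
counted and reported, never silently dropped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .library import RESIDUE_ALPHABET

DEFAULT_MIN_PEPTIDE_LENGTH = 6

#: flank token: single residue (or dash) + dot at either end, e.g. "K.PEP.R"
_FLANK_RE = re.compile(r"^(?:[A-Z-]\.)?(.*?)(?:\.[A-Z-])?$", re.IGNORECASE)
#: bracketed modification annotations, e.g. "(ph)", "[+15.99]", "{gl}"
_MOD_GROUP_RE = re.compile(r"\([^)]*\)|\[[^\]]*\]|\{[^}]*\}")


class ConfigurationError(ValueError):
    """An unregistered parser name or otherwise unusable study config."""


class IngestError(ValueError):
    """A study file yielded zero parseable observations."""


@dataclass(frozen=True)
class StudyMeta:
    """Identity and parsing dialect of one federated study."""

    study_id: str
    label: str = ""
    format_name: str = "simple_tsv"


@dataclass(frozen=True)
class PeptideObservation:
    """One reported peptide detection — the redundant-count unit."""

    peptide: str
    study_id: str
    reported_accession: str = ""
    spectral_count: int = 1

    def __post_init__(self):
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be >= 1")


@dataclass
class IngestReport:
    """Book-keeping for one parsed study: conservation holds exactly,
    rows_in == len(observations) + len(rejects)."""

    study_id: str
    rows_in: int = 0
    observations: list[PeptideObservation] = field(default_factory=list)
    rejects: list[tuple[int, str, str]] = field(default_factory=list)  # (line, row, reason)


def clean_peptide(raw: str) -> str:
    """Normalize a reported peptide string to a bare residue sequence.

    Removes a leading/trailing single-residue flank token (``K.XXX.R``
    dialect), deletes bracketed modification groups like ``(ph)`` or
    ``[+16]`` wholesale, uppercases, then drops any remaining character
    not in the residue alphabet.
    """
    core = _FLANK_RE.match(raw.strip()).group(1)
    core = _MOD_GROUP_RE.sub("", core).upper()
    return "".join(ch for ch in core if ch in RESIDUE_ALPHABET)


# NCBI pipe dialects: the bare accession is the token after ref/sp/tr/gb/emb/dbj,
# or the numeric gi when nothing else is present.
_PIPE_KEYS = ("ref", "sp", "tr", "gb", "emb", "dbj", "pdb", "prf")


def normalize_accession(raw: str) -> tuple[str, bool]:
    """Strip database prefixes to a bare accession token.

    Returns ``(token, ok)``; ``ok`` is False when the string could not be
    interpreted and is returned verbatim.
    """
    s = raw.strip()
    if not s:
        raise ValueError("empty accession")
    if "|" not in s and ":" not in s:
        return s, True
    if ":" in s and "|" not in s:  # e.g. "IPI:IPI00022434.4"
        token = s.split(":")[-1]
        return (token, True) if token else (s, False)
    fields = s.split("|")
    for key in _PIPE_KEYS:
        if key in fields:
            i = fields.index(key)
            if i + 1 < len(fields) and fields[i + 1]:
                return fields[i + 1], True
    if fields[0] == "gi" and len(fields) > 1 and fields[1]:
        # bare gi number with no named database section
        named = [f for f in fields[2:] if f]
        return (named[-1], True) if named else (fields[1], True)
    tokens = [f for f in fields if f]
    if tokens:
        return tokens[-1], True
    return s, False


ParserFunc = Callable[[Path], Iterable[tuple[str, str, int]]]
_PARSERS: dict[str, ParserFunc] = {}


def register_parser(name: str):
    """Decorator registering a study-file parser under `name`.

    A parser yields raw ``(peptide, accession, count)`` tuples; cleaning
    and validation are applied uniformly afterwards.
    """

    def deco(fn: ParserFunc) -> ParserFunc:
        _PARSERS[name] = fn
        return fn

    return deco


def registered_formats() -> list[str]:
    return sorted(_PARSERS)


def _delimited_rows(path: Path, delimiter: str):
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        header = next(reader, None)
        if header is None:
            return
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        for row in reader:
            yield cols, row


def _mapped(cols, row, names, default=""):
    for name in names:
        if name in cols and cols[name] < len(row):
            return row[cols[name]].strip()
    return default


def _generic_tsv(path: Path, delimiter: str):
    for cols, row in _delimited_rows(path, delimiter):
        pep = _mapped(cols, row, ("peptide", "sequence", "pep_seq"))
        acc = _mapped(cols, row, ("accession", "protein", "protein_accession"))
        cnt = _mapped(cols, row, ("count", "spectral_count", "spectra"), default="1")
        yield pep, acc, int(cnt) if cnt.isdigit() and int(cnt) > 0 else 1


@register_parser("simple_tsv")
def parse_simple_tsv(path: Path):
    """Headered TSV with peptide / accession / optional count columns."""
    yield from _generic_tsv(path, "\t")


@register_parser("simple_csv")
def parse_simple_csv(path: Path):
    yield from _generic_tsv(path, ",")


@register_parser("flanked_tsv")
def parse_flanked_tsv(path: Path):
    """TSV whose peptide column carries K.XXX.R-style flank tokens."""
    yield from _generic_tsv(path, "\t")  # flank stripping happens in clean_peptide


def parse_study(
    path: str | Path,
    meta: StudyMeta,
    min_peptide_length: int = DEFAULT_MIN_PEPTIDE_LENGTH,
) -> IngestReport:
    """Parse one study file into observations plus an explicit reject list.

    Raises :class:`ConfigurationError` for an unregistered format and
    :class:`IngestError` when no row at all can be parsed.
    """
    if meta.format_name not in _PARSERS:
        raise ConfigurationError(
            f"format {meta.format_name!r} is not registered "
            f"(known: {registered_formats()})"
        )
    path = Path(path)
    report = IngestReport(study_id=meta.study_id)
    for lineno, (pep_raw, acc_raw, count) in enumerate(_PARSERS[meta.format_name](path), start=2):
        report.rows_in += 1
        peptide = clean_peptide(pep_raw)
        if not peptide:
            report.rejects.append((lineno, pep_raw, "no residue characters"))
            continue
        if len(peptide) < min_peptide_length:
            report.rejects.append(
                (lineno, pep_raw, f"peptide shorter than {min_peptide_length}")
            )
            continue
        accession = ""
        if acc_raw:
            accession, _ = normalize_accession(acc_raw)
        report.observations.append(
            PeptideObservation(peptide, meta.study_id, accession, max(1, count))
        )
    if report.rows_in and not report.observations:
        raise IngestError(f"study {meta.study_id}: zero parseable rows in {path}")
    if report.rows_in == 0:
        raise IngestError(f"study {meta.study_id}: {path} contains no data rows")
    return report
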