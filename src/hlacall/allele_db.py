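"""Allele reference database: nomenclature, exon segmentation, persistence.

The typing pipeline matches reads against a panel of known allele sequences
(an IMGT/HLA-style registry, or the synthetic panel from
:mod:`hlacall.simulate`).  Alleles are modelled at exon level — many registry
entries lack full genomic sequence — with the full (exon+intron) sequence
kept when available.

Allele names follow HLA nomenclature, ``GENE*F1:F2:F3:F4`` in the modern
colon-separated form or the legacy run-together digit form (``B*0702``).
"Resolution" is the number of leading name fields compared: one field is the
classic 2-digit resolution, two fields the 4-digit resolution.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleName",
    "Allele",
    "AlleleDatabase",
    "AlleleNameError",
    "DatabaseConsistencyError",
    "parse_allele_name",
    "truncate_resolution",
    "resolution_key",
    "load_database",
    "write_database",
]


class AlleleNameError(ValueError):
    """Raised for allele labels that do not follow HLA nomenclature."""


class DatabaseConsistencyError(ValueError):
    """Raised when FASTA and exon-map contents disagree."""


_MODERN_FIELD = re.compile(r"^\d+[A-Z]?$")
_LEGACY = re.compile(r"^(\d+)([A-Z]?)$")


@dataclass(frozen=True)
class AlleleName:
    """Parsed allele label: gene symbol plus ordered numeric fields.

    An optional expression suffix letter (N/L/S/Q...) stays attached to the
    last field; it is preserved verbatim but ignored when names are compared
    at a given resolution.
    """

    gene: str
    fields: tuple[str, ...]
    raw: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise AlleleNameError(f"empty gene symbol in {self.raw!r}")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleNameError(
                f"{self.raw!r}: expected 1-4 name fields, got {len(self.fields)}"
            )
        for f in self.fields:
            if not _MODERN_FIELD.match(f):
                raise AlleleNameError(f"{self.raw!r}: malformed field {f!r}")

    def __str__(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}"


def parse_allele_name(label: str) -> AlleleName:
    """Parse ``GENE*fields`` labels, modern (colon) or legacy (run-together).

    Legacy digit-only names are split into two-character fields, so
    ``B*0702`` compares equal to ``B*07:02`` at 4-digit resolution.
    """
    if "*" not in label:
        raise AlleleNameError(f"allele label {label!r} lacks 'GENE*' prefix")
    gene, _, rest = label.partition("*")
    if not gene or not rest:
        raise AlleleNameError(f"malformed allele label {label!r}")
    if ":" in rest:
        fields = tuple(rest.split(":"))
    else:
        m = _LEGACY.match(rest)
        if not m:
            raise AlleleNameError(f"malformed allele label {label!r}")
        digits, suffix = m.groups()
        fields_l = [digits[i : i + 2] for i in range(0, len(digits), 2)]
        if suffix:
            fields_l[-1] += suffix
        fields = tuple(fields_l)
    return AlleleName(gene=gene, fields=fields, raw=label)


def truncate_resolution(name: AlleleName, n_fields: int) -> AlleleName:
    """Keep the leading ``n_fields`` name fields (idempotent, monotone)."""
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if n_fields >= len(name.fields):
        return name
    kept = name.fields[:n_fields]
    return AlleleName(gene=name.gene, fields=kept, raw=str(replace(name, fields=kept)))


def resolution_key(name: AlleleName, n_fields: int | None = None) -> tuple:
    """Comparison key at a resolution; expression suffix letters ignored."""
    fields = name.fields if n_fields is None else name.fields[:n_fields]
    return (name.gene,) + tuple(re.sub(r"[A-Z]$", "", f) for f in fields)


@dataclass(frozen=True)
class Allele:
    """One database allele: ordered exon sequences, optional full sequence.

    ``exon_spans`` gives, when the full (genomic) sequence is present, the
    0-based half-open interval of each exon on it.
    """

    name: AlleleName
    exons: tuple[str, ...]
    full_sequence: str | None = None
    exon_spans: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.name.raw}: allele needs at least one exon")
        for i, e in enumerate(self.exons, 1):
            if not e or set(e) - set("ACGT"):
                raise ValueError(f"{self.name.raw} exon {i}: not plain ACGT DNA")
        if self.exon_spans is not None:
            if self.full_sequence is None or len(self.exon_spans) != len(self.exons):
                raise ValueError(f"{self.name.raw}: exon_spans inconsistent")
            for (s, e), seq in zip(self.exon_spans, self.exons):
                if self.full_sequence[s:e] != seq:
                    raise ValueError(f"{self.name.raw}: exon span does not match sequence")

    @property
    def n_exons(self) -> int:
        return len(self.exons)


class AlleleDatabase:
    """Collection of alleles keyed by raw name, with a per-exon index.

    ``exon_index[(gene, exon_number)]`` is the set of distinct exon sequences
    seen in any allele of that gene (exon numbers are 1-based).
    """

    def __init__(self, alleles: dict[str, Allele] | None = None):
        self.alleles: dict[str, Allele] = {}
        self.genes: set[str] = set()
        self.exon_index: dict[tuple[str, int], set[str]] = {}
        for a in (alleles or {}).values():
            self.add(a)

    def add(self, allele: Allele) -> None:
        if allele.name.raw in self.alleles:
            raise DatabaseConsistencyError(f"duplicate allele name {allele.name.raw!r}")
        self.alleles[allele.name.raw] = allele
        self.genes.add(allele.name.gene)
        for k, seq in enumerate(allele.exons, 1):
            self.exon_index.setdefault((allele.name.gene, k), set()).add(seq)

    def rebuild_exon_index(self) -> dict[tuple[str, int], set[str]]:
        idx: dict[tuple[str, int], set[str]] = {}
        for a in self.alleles.values():
            for k, seq in enumerate(a.exons, 1):
                idx.setdefault((a.name.gene, k), set()).add(seq)
        return idx

    def gene_alleles(self, gene: str) -> list[Allele]:
        """Alleles of one gene, in lexicographic name order."""
        return [a for n, a in sorted(self.alleles.items()) if a.name.gene == gene]

    def exon_sequences(self, gene: str, exon_number: int) -> set[str]:
        return self.exon_index.get((gene, exon_number), set())

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, raw_name: str) -> bool:
        return raw_name in self.alleles


_EXON_TOKEN = re.compile(r"\bexon(\d+)\b", re.IGNORECASE)


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.description in seen:
            raise DatabaseConsistencyError(f"duplicate FASTA header {rec.description!r}")
        seen.add(rec.description)
        records.append((rec.description, str(rec.seq).upper()))
    return records


def load_database(sequences: str | Path, exon_map: str | Path | None = None) -> AlleleDatabase:
    """Load an allele database from FASTA (+ optional exon manifest).

    Two dialects are accepted:

    * **manifest dialect** — one FASTA record per allele holding its full
      sequence, plus a tab-separated manifest with columns
      ``allele_name  exon_number  start  end`` (1-based inclusive on the
      allele sequence);
    * **exon-split dialect** (``exon_map=None``) — one FASTA record per
      exon, with an ``exon<k>`` token in the header after the allele name.
    """
    fasta = _read_fasta(sequences)
    db = AlleleDatabase()
    if exon_map is None:
        per_allele: dict[str, dict[int, str]] = {}
        order: list[str] = []
        for header, seq in fasta:
            m = _EXON_TOKEN.search(header)
            if not m:
                raise DatabaseConsistencyError(
                    f"header {header!r} lacks an exon<k> token and no exon map was given"
                )
            raw = header.split()[0]
            if raw not in per_allele:
                order.append(raw)
            exons = per_allele.setdefault(raw, {})
            k = int(m.group(1))
            if k in exons:
                raise DatabaseConsistencyError(f"duplicate exon {k} for allele {raw!r}")
            exons[k] = seq
        for raw in order:
            exons = per_allele[raw]
            if sorted(exons) != list(range(1, len(exons) + 1)):
                raise DatabaseConsistencyError(
                    f"allele {raw!r}: exon numbers {sorted(exons)} are not 1..n"
                )
            db.add(Allele(name=parse_allele_name(raw), exons=tuple(exons[k] for k in sorted(exons))))
    else:
        spans: dict[str, dict[int, tuple[int, int]]] = {}
        with open(exon_map) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise DatabaseConsistencyError(
                        f"{exon_map}:{line_no}: expected 4 tab-separated columns"
                    )
                raw, k, start, end = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                spans.setdefault(raw, {})[k] = (start - 1, end)  # to 0-based half-open
        seqs = {header.split()[0]: seq for header, seq in fasta}
        missing_seq = sorted(set(spans) - set(seqs))
        missing_map = sorted(set(seqs) - set(spans))
        if missing_seq or missing_map:
            raise DatabaseConsistencyError(
                f"exon map / FASTA mismatch: in map only {missing_seq}, in FASTA only {missing_map}"
            )
        for raw, seq in seqs.items():
            by_k = spans[raw]
            if sorted(by_k) != list(range(1, len(by_k) + 1)):
                raise DatabaseConsistencyError(
                    f"allele {raw!r}: exon numbers {sorted(by_k)} are not 1..n"
                )
            ordered = [by_k[k] for k in sorted(by_k)]
            db.add(
                Allele(
                    name=parse_allele_name(raw),
                    exons=tuple(seq[s:e] for s, e in ordered),
                    full_sequence=seq,
                    exon_spans=tuple(ordered),
                )
            )
    logger.info("loaded %d alleles across %d genes", len(db), len(db.genes))
    return db


def write_database(db: AlleleDatabase, fasta_path: str | Path, map_path: str | Path | None = None) -> None:
    """Write a database back out in the dialect it can round-trip through.

    Alleles with a full sequence go to the manifest dialect (requires
    ``map_path``); pure-exon alleles to the exon-split dialect.
    """
    has_full = all(a.full_sequence is not None for a in db.alleles.values())
    records: list[SeqRecord] = []
    if has_full and map_path is not None:
        with open(map_path, "w") as fh:
            for raw, a in sorted(db.alleles.items()):
                records.append(SeqRecord(Seq(a.full_sequence), id=raw, description=""))
                for k, (s, e) in enumerate(a.exon_spans, 1):
                    fh.write(f"{raw}\t{k}\t{s + 1}\t{e}\n")
    else:
        for raw, a in sorted(db.alleles.items()):
            for k, seq in enumerate(a.exons, 1):
                records.append(SeqRecord(Seq(seq), id=raw, description=f"exon{k}"))
    SeqIO.write(records, str(fasta_path), "fasta")
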