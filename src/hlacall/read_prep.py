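"""Per-gene read harvesting from coordinate-sorted alignments.

The pipeline's first step pulls, for each HLA gene, every read pair with at
least one end mapped inside the gene's genomic interval, plus fully unmapped
pairs of sufficient base quality (these cannot be placed positionally; they
ride along with every gene's read set and are resolved downstream when reads
are matched against the allele database).  PCR-duplicate-flagged records are
dropped, as are secondary/supplementary alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

__all__ = [
    "SequenceRead",
    "GeneRegion",
    "GeneReadSet",
    "extract_gene_reads",
    "load_region_table",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class SequenceRead:
    """A read as the pipeline sees it: sequence, qualities, provenance."""

    id: str
    sequence: str
    qualities: tuple[int, ...]
    mate_of: str | None = None
    is_mapped: bool = True
    is_duplicate: bool = False
    category: str = "mapped_pair"  # or "unmapped_rescue"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        if set(self.sequence) - _VALID:
            raise ValueError(f"{self.id}: sequence not over ACGTN")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities))


@dataclass(frozen=True)
class GeneRegion:
    """Genomic interval of a gene, stored 0-based half-open."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene}: empty region [{self.start}, {self.end})")


@dataclass
class GeneReadSet:
    """Reads harvested for one gene, with per-category counts."""

    gene: str
    reads: list[SequenceRead] = field(default_factory=list)
    stats: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        assert sum(self.stats.values()) == len(self.reads)


def load_region_table(path: str | Path) -> list[GeneRegion]:
    """Read a gene-region TSV: gene, chrom, start, end (1-based inclusive)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, chrom, start, end = line.split("\t")[:4]
            regions.append(GeneRegion(gene, chrom, int(start) - 1, int(end)))
    return regions


def _overlaps(aln: pysam.AlignedSegment, region: GeneRegion) -> bool:
    # half-open semantics: a read ending exactly at region.start is excluded
    if aln.is_unmapped or aln.reference_name != region.chrom:
        return False
    return aln.reference_start < region.end and aln.reference_end > region.start


def extract_gene_reads(
    alignments: str | Path,
    region: GeneRegion,
    quality_floor: float = 20.0,
) -> GeneReadSet:
    """Harvest the candidate read pool for one gene from SAM/BAM.

    Keeps (a) both mates of every pair with >=1 end overlapping ``region``
    and (b) both mates of fully-unmapped pairs whose mean base Phred quality
    is >= ``quality_floor`` (the rescue pool).  The file is streamed once;
    records are paired by query name, so sort order does not matter.
    """
    mode = "rb" if str(alignments).endswith(".bam") else "r"
    pairs: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(alignments), mode, check_sq=False) as fh:
        if region.chrom not in fh.references:
            raise ValueError(f"contig {region.chrom!r} absent from alignment header")
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            pairs.setdefault(aln.query_name, []).append(aln)

    out = GeneReadSet(gene=region.gene, stats={"mapped_pair": 0, "unmapped_rescue": 0})
    for qname in sorted(pairs):
        members = pairs[qname]
        if any(_overlaps(a, region) for a in members):
            category = "mapped_pair"
        elif all(a.is_unmapped for a in members) and all(
            np.mean(a.query_qualities) >= quality_floor for a in members
        ):
            category = "unmapped_rescue"
        else:
            continue
        for a in members:
            suffix = "/1" if a.is_read1 else "/2" if a.is_read2 else ""
            # pysam reports reverse-strand records in reference orientation;
            # downstream matching tries both strands, so no flip is needed
            seq = a.query_sequence
            qual = a.query_qualities
            out.reads.append(
                SequenceRead(
                    id=qname + suffix,
                    sequence=seq.upper(),
                    qualities=tuple(qual),
                    mate_of=qname + ("/2" if suffix == "/1" else "/1" if suffix == "/2" else ""),
                    is_mapped=not a.is_unmapped,
                    category=category,
                )
            )
            out.stats[category] += 1
    out.check()
    return out
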