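"""End-to-end typing: reads in, per-gene allele calls out.

Glues the pipeline steps together: gene assignment (positional, from a
SAM/BAM plus a gene-region table; or sequence-based via a k-mer index, for
reads straight from the simulator), reference-guided correction, exon
assembly and allele-pair calling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .allele_db import AlleleDatabase
from .assembly import ScoringConfig, assemble_gene
from .correction import MatchConfig, correct_gene_reads, reverse_complement
from .genotyping import TypingConfig, TypingResult, call_gene
from .read_prep import GeneRegion, SequenceRead, extract_gene_reads

__all__ = ["PipelineConfig", "HlaTyper", "report_tsv"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline in one place."""

    match: MatchConfig = MatchConfig()
    scoring: ScoringConfig = ScoringConfig()
    typing: TypingConfig = TypingConfig()
    min_overlap: int = 10  # perfect-overlap length for assembly
    quality_floor: float = 20.0  # mean Phred floor for unmapped-pair rescue
    assign_kmer: int = 21  # k-mer size for sequence-based gene assignment
    bridge: bool = True


class HlaTyper:
    """Types every gene of an allele database from a read pool."""

    def __init__(self, db: AlleleDatabase, config: PipelineConfig = PipelineConfig()):
        self.db = db
        self.config = config
        self._kmer_index: dict[str, tuple[str, str]] | None = None

    # -- sequence-based gene assignment --------------------------------------

    def _build_kmer_index(self) -> dict[str, tuple[str, str]]:
        """k-mer -> (gene, strand); k-mers shared between genes are dropped."""
        k = self.config.assign_kmer
        index: dict[str, tuple[str, str]] = {}
        ambiguous: set[str] = set()
        for gene in sorted(self.db.genes):
            for allele in self.db.gene_alleles(gene):
                refs = [allele.full_sequence] if allele.full_sequence else list(allele.exons)
                for ref in refs:
                    for strand, seq in (("+", ref), ("-", reverse_complement(ref))):
                        for i in range(len(seq) - k + 1):
                            km = seq[i : i + k]
                            hit = index.get(km)
                            if hit is None:
                                index[km] = (gene, strand)
                            elif hit[0] != gene:
                                ambiguous.add(km)
        for km in ambiguous:
            index.pop(km, None)
        return index

    def assign_genes(self, reads) -> dict[str, list[SequenceRead]]:
        """Bin reads by gene via shared k-mers (reads' own strand resolved).

        Reads matching no gene's k-mers (deep in error, or off target) are
        left out; correction would discard them anyway.
        """
        if self._kmer_index is None:
            self._kmer_index = self._build_kmer_index()
        k = self.config.assign_kmer
        index = self._kmer_index
        out: dict[str, list[SequenceRead]] = defaultdict(list)
        self._strand_hints: dict[str, str] = {}
        for read in reads:
            seq = read.sequence
            hit = None
            for i in range(0, len(seq) - k + 1):
                hit = index.get(seq[i : i + k])
                if hit is not None:
                    break
            if hit is None:
                continue
            gene, ref_strand = hit
            out[gene].append(read)
            # reference k-mer on '-' strand means the read is reverse-complement
            self._strand_hints[read.id] = "+" if ref_strand == "+" else "-"
        return dict(out)

    # -- typing entry points --------------------------------------------------

    def type_reads_by_gene(
        self, reads_by_gene: dict[str, list[SequenceRead]],
        strand_hints: dict[str, str] | None = None,
    ) -> dict[str, TypingResult]:
        """Run correction, assembly and calling for pre-binned reads."""
        cfg = self.config
        results: dict[str, TypingResult] = {}
        for gene in sorted(self.db.genes):
            reads = reads_by_gene.get(gene, [])
            corrected, ledger, _stats = correct_gene_reads(
                reads, self.db, gene, cfg.match, strand_hints
            )
            exon_sets = assemble_gene(
                corrected, self.db, gene,
                min_overlap=cfg.min_overlap, scoring=cfg.scoring, bridge=cfg.bridge,
            )
            results[gene] = call_gene(
                exon_sets, corrected, ledger.records(), self.db, gene, cfg.typing
            )
        return results

    def type_reads(self, reads) -> dict[str, TypingResult]:
        """Type an unbinned read pool (e.g. simulator output or FASTQ)."""
        binned = self.assign_genes(reads)
        return self.type_reads_by_gene(binned, self._strand_hints)

    def type_alignments(
        self, alignments: str | Path, regions: list[GeneRegion]
    ) -> dict[str, TypingResult]:
        """Type from a SAM/BAM: positional harvest per gene, then the pipeline."""
        reads_by_gene: dict[str, list[SequenceRead]] = {}
        for region in regions:
            if region.gene not in self.db.genes:
                continue
            grs = extract_gene_reads(alignments, region, self.config.quality_floor)
            reads_by_gene[region.gene] = grs.reads
        return self.type_reads_by_gene(reads_by_gene)


def report_tsv(results: dict[str, TypingResult], sample_id: str = "sample") -> str:
    """Typing report: one row per gene, TSV."""
    lines = [
        "sample\tgene\tallele1\tallele2\tzygosity\tratio\ttscore1\ttscore2\tascore"
    ]
    for gene in sorted(results):
        r = results[gene]
        if r.status != "ok":
            lines.append(f"{sample_id}\t{gene}\tNA\tNA\tuntypeable\tNA\tNA\tNA\tNA")
            continue
        a1 = r.alleles[0]
        a2 = r.alleles[1] if len(r.alleles) > 1 else r.alleles[0]
        t1 = r.tscores.get(a1, float("nan"))
        t2 = r.tscores.get(a2, float("nan"))
        lines.append(
            f"{sample_id}\t{gene}\t{a1}\t{a2}\t{r.zygosity}\t{r.ratio:.4f}\t"
            f"{t1:.3f}\t{t2:.3f}\t{r.ascore:.4f}"
        )
    return "\n".join(lines) + "\n"
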