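"""Allele-pair calling from assembled exon haplotypes.

Candidate full-gene types are the database alleles compatible with at least
one surviving exon assembly.  Each candidate is scored with

    TScore = Σ_exons  N_e · S_e

over the exons where it has a compatible assembly (``N_e`` reads in the
best such assembly, ``S_e`` its haplotype score).  The two top-ranked
candidates are compared through the zygosity ratio

    ratio = unique supporting reads of the runner-up / supporting reads of the best

where a read supports a candidate when its corrected sequence occurs in
that allele's exon, and is *unique* to the runner-up when no higher-ranked
candidate also contains it.  A ratio below 0.1 calls a homozygote (single
allele); at or above 0.1, a heterozygote (both alleles).  Call confidence is

    AScore = (S2 − S1) / S0

with S2 the final (best) type's score, S1 the score of its closest
competitor outside the call, and S0 the summed score mass (Σ S·N) of every
surviving assembly of the gene.  Finally, discordances logged during error
correction are promoted to novel-variant calls when well supported and
absent from every database allele of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .allele_db import AlleleDatabase
from .assembly import AssembledHaplotype, ExonAssemblySet
from .correction import CorrectedRead, VariantRecord

__all__ = [
    "TypingConfig",
    "CandidateType",
    "NovelVariant",
    "TypingResult",
    "enumerate_candidates",
    "tscore",
    "select_pair",
    "call_zygosity",
    "ascore",
    "judge_novel_variants",
    "call_gene",
]


def tscore(candidate: "CandidateType") -> float:
    """Type score: Σ over supported exons of N_e × S_e (monotone in both)."""
    return float(
        sum(h.n_reads * h.hscore for h in candidate.exon_support.values())
    )


@dataclass(frozen=True)
class TypingConfig:
    """Thresholds and pluggable score of the calling step."""

    het_threshold: float = 0.1  # ratio at/above which a gene is heterozygous
    min_novel_support: int = 4  # read support floor for novel-variant calls
    tscore: Callable[["CandidateType"], float] = tscore


@dataclass
class CandidateType:
    """A database allele considered as (half of) the gene's type."""

    allele: str
    exon_support: dict[int, AssembledHaplotype] = field(default_factory=dict)
    n_support: int = 0
    n_unique_support: int = 0
    tscore: float = 0.0
    support_ids: frozenset = frozenset()


@dataclass(frozen=True)
class NovelVariant:
    """A ledger discordance judged novel, tied to a called allele."""

    variant: VariantRecord
    linked_allele: str


@dataclass
class TypingResult:
    """Final call for one gene."""

    gene: str
    status: str  # "ok" or "untypeable"
    zygosity: str | None = None
    alleles: tuple[str, ...] = ()
    ratio: float = 0.0
    ascore: float = float("nan")
    tscores: dict[str, float] = field(default_factory=dict)
    novel_variants: list[NovelVariant] = field(default_factory=list)
    best_support: int = 0
    subopt_unique_support: int = 0


def enumerate_candidates(
    exon_sets: dict[int, ExonAssemblySet] | Sequence[ExonAssemblySet],
    db: AlleleDatabase,
    gene: str,
) -> list[CandidateType]:
    """One candidate per allele compatible with >=1 surviving assembly.

    ``exon_support`` keeps, per exon, the compatible assembly with the
    highest HScore (ties broken by sequence).
    """
    sets = list(exon_sets.values()) if isinstance(exon_sets, dict) else list(exon_sets)
    per_allele: dict[str, dict[int, AssembledHaplotype]] = {}
    for es in sets:
        for h in sorted(es.haplotypes, key=lambda h: (-h.hscore, h.sequence)):
            for name in h.compatible_alleles:
                per_allele.setdefault(name, {}).setdefault(es.exon_number, h)
    return [
        CandidateType(allele=name, exon_support=per_allele[name])
        for name in sorted(per_allele)
    ]


def compute_support(
    candidates: Sequence[CandidateType],
    corrected_reads: Sequence[CorrectedRead],
    db: AlleleDatabase,
    gene: str,
) -> None:
    """Fill each candidate's supporting-read set and count (in place).

    A read supports an allele when its corrected sequence is a substring of
    that allele's sequence for the exon the read was matched to.
    """
    exons = {a.name.raw: a.exons for a in db.gene_alleles(gene)}
    cache: dict[tuple[str, int], frozenset[str]] = {}
    per_allele: dict[str, set[int]] = {c.allele: set() for c in candidates}
    for idx, cr in enumerate(corrected_reads):
        key = (cr.sequence, cr.match.exon_number)
        compat = cache.get(key)
        if compat is None:
            k = cr.match.exon_number
            compat = frozenset(
                name
                for name, exs in exons.items()
                if k <= len(exs) and cr.sequence in exs[k - 1]
            )
            cache[key] = compat
        for name in compat:
            if name in per_allele:
                per_allele[name].add(idx)
    for c in candidates:
        c.support_ids = frozenset(per_allele[c.allele])
        c.n_support = len(c.support_ids)


def select_pair(
    candidates: Sequence[CandidateType],
    config: TypingConfig = TypingConfig(),
) -> tuple[CandidateType, CandidateType | None]:
    """Top two candidates by TScore; fills tscore and unique supports.

    Ranking: higher TScore, then higher read support, then lexicographic
    allele name.  Unique support of a candidate counts its supporting reads
    claimed by no higher-ranked candidate; reads shared between the top two
    count in both supports but in neither unique count.
    """
    if not candidates:
        raise ValueError("select_pair needs at least one candidate")
    for c in candidates:
        c.tscore = config.tscore(c)
    ranked = sorted(candidates, key=lambda c: (-c.tscore, -c.n_support, c.allele))
    claimed: set = set()
    for c in ranked:
        c.n_unique_support = len(c.support_ids - claimed)
        claimed |= c.support_ids
    return ranked[0], (ranked[1] if len(ranked) > 1 else None)


def call_zygosity(
    best: CandidateType,
    suboptimal: CandidateType | None,
    config: TypingConfig = TypingConfig(),
) -> tuple[str, float]:
    """Zygosity from the unique-support ratio; boundary counts heterozygous.

    ratio = suboptimal unique support / best support; strictly below the
    threshold (default 0.1) the gene is homozygous for the best type.
    """
    if best.n_support == 0:
        raise ValueError("best candidate has no supporting reads")
    ratio = 0.0 if suboptimal is None else suboptimal.n_unique_support / best.n_support
    zygosity = "heterozygote" if ratio >= config.het_threshold else "homozygote"
    return zygosity, ratio


def ascore(s0: float, s1: float, s2: float) -> float:
    """Call confidence (S2 − S1)/S0 clamped to [0, 1]; NaN when S0 <= 0."""
    if s0 <= 0:
        return float("nan")
    return min(1.0, max(0.0, (s2 - s1) / s0))


def judge_novel_variants(
    ledger_records: Sequence[VariantRecord],
    called_alleles: Sequence[str],
    db: AlleleDatabase,
    gene: str,
    min_support: int = 4,
) -> list[NovelVariant]:
    """Promote well-supported discordances absent from every known allele.

    A SNP whose alternate base occurs at that position in any allele of the
    gene is evidence of that other allele, not novelty.  Indel records are
    position-shifted between alleles and are only support-filtered.  Each
    novel variant is linked to a called allele: the allele it was recorded
    against when called, else a called allele with the identical exon
    sequence, else the dominant called allele.
    """
    alleles = {a.name.raw: a for a in db.gene_alleles(gene)}
    out: list[NovelVariant] = []
    for rec in ledger_records:
        if rec.support < min_support:
            continue
        if rec.ref_bases and rec.alt_bases and len(rec.ref_bases) == len(rec.alt_bases):
            seen = any(
                rec.exon_number <= a.n_exons
                and rec.position + len(rec.alt_bases) <= len(a.exons[rec.exon_number - 1])
                and a.exons[rec.exon_number - 1][
                    rec.position : rec.position + len(rec.alt_bases)
                ]
                == rec.alt_bases
                for a in alleles.values()
            )
            if seen:
                continue
        if not called_alleles:
            continue
        if rec.allele in called_alleles:
            linked = rec.allele
        else:
            ref_exon = (
                alleles[rec.allele].exons[rec.exon_number - 1]
                if rec.allele in alleles and rec.exon_number <= alleles[rec.allele].n_exons
                else None
            )
            same = [
                n
                for n in called_alleles
                if n in alleles
                and rec.exon_number <= alleles[n].n_exons
                and alleles[n].exons[rec.exon_number - 1] == ref_exon
            ]
            linked = same[0] if same else called_alleles[0]
        out.append(NovelVariant(variant=rec, linked_allele=linked))
    return out


def call_gene(
    exon_sets: dict[int, ExonAssemblySet],
    corrected_reads: Sequence[CorrectedRead],
    ledger_records: Sequence[VariantRecord],
    db: AlleleDatabase,
    gene: str,
    config: TypingConfig = TypingConfig(),
) -> TypingResult:
    """Run the whole calling step for one gene; never raises on empty input."""
    all_haps = [h for es in exon_sets.values() for h in es.haplotypes]
    if not all_haps:
        return TypingResult(gene=gene, status="untypeable")
    candidates = enumerate_candidates(exon_sets, db, gene)
    compute_support(candidates, corrected_reads, db, gene)
    best, subopt = select_pair(candidates, config)
    if best.n_support == 0:
        return TypingResult(gene=gene, status="untypeable")
    zygosity, ratio = call_zygosity(best, subopt, config)
    alleles = (best.allele,) if zygosity == "homozygote" else (best.allele, subopt.allele)
    s0 = sum(h.hscore * h.n_reads for h in all_haps)
    competitor = next(
        (
            c
            for c in sorted(candidates, key=lambda c: (-c.tscore, -c.n_support, c.allele))
            if c.allele not in alleles
        ),
        None,
    )
    s1 = competitor.tscore if competitor is not None else 0.0
    result = TypingResult(
        gene=gene,
        status="ok",
        zygosity=zygosity,
        alleles=alleles,
        ratio=ratio,
        ascore=ascore(s0, s1, best.tscore),
        tscores={c.allele: c.tscore for c in candidates if c.allele in alleles},
        best_support=best.n_support,
        subopt_unique_support=0 if subopt is None else subopt.n_unique_support,
    )
    result.novel_variants = judge_novel_variants(
        ledger_records, list(alleles), db, gene, config.min_novel_support
    )
    return result
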