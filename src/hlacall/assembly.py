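"""Exon-level haplotype assembly by perfect-overlap chaining, and scoring.

Corrected reads of one exon are joined wherever one read's prefix matches
the growing assembly's suffix over at least ``min_overlap`` bases (default
10) with zero mismatches.  All maximal assemblies are enumerated — the
result is a *set*, independent of the order reads are considered — and any
assembly that is a substring of another is dropped.  Assemblies whose
sequence does not occur in the allele database for that exon are artefacts
(chimeras of the two chromosome copies, usually) and are filtered out;
survivors are scored.

Scores
------
For an assembled haplotype with per-base depths ``Xi`` (mean ``X̄``, length
``L``), coverage fraction ``C`` of its exon reference and read count ``N``:

* depth dispersion  ``D = [Σ (Xi − X̄)² / X̄] / (L − 1)``
* reliability       ``R = 1 / (1 + D)``  — 1 iff depth is perfectly uniform
* haplotype score   ``S = C · R · ln(1 + N)``

Both formulas are pluggable through :class:`ScoringConfig`.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .allele_db import AlleleDatabase

__all__ = [
    "RawAssembly",
    "AssembledHaplotype",
    "ExonAssemblySet",
    "ScoringConfig",
    "assemble_exon",
    "bridge_fragments",
    "reliability",
    "hscore",
    "filter_known",
    "assemble_gene",
]


def reliability(depth_profile: Sequence[int]) -> float:
    """Depth-evenness score R in (0, 1]; 1 iff the profile is uniform.

    Profiles shorter than 2 bases have no dispersion to measure and score 1.
    """
    x = np.asarray(depth_profile, dtype=float)
    if x.size < 2:
        return 1.0
    mean = x.mean()
    d = float(((x - mean) ** 2).sum() / mean) / (x.size - 1)
    return 1.0 / (1.0 + d)


def hscore(coverage_fraction: float, reliability_: float, n_reads: int) -> float:
    """Haplotype quality S = C · R · ln(1 + N)."""
    return coverage_fraction * reliability_ * math.log1p(n_reads)


@dataclass(frozen=True)
class ScoringConfig:
    """Pluggable score formulas (reliability from a depth profile; HScore
    from coverage C, reliability R and read count N)."""

    reliability: Callable[[Sequence[int]], float] = reliability
    hscore: Callable[[float, float, int], float] = hscore


@dataclass
class RawAssembly:
    """A maximal perfect-overlap chain before the database filter."""

    sequence: str
    depth_profile: np.ndarray
    n_reads: int


@dataclass
class AssembledHaplotype:
    """A database-confirmed exon haplotype with its quality components."""

    gene: str
    exon_number: int
    sequence: str
    depth_profile: np.ndarray
    n_reads: int
    coverage_fraction: float
    reliability: float
    hscore: float
    compatible_alleles: frozenset[str]
    bridged: bool = False

    def __post_init__(self) -> None:
        assert len(self.depth_profile) == len(self.sequence)
        assert self.n_reads >= 1
        assert 0.0 < self.coverage_fraction <= 1.0
        assert 0.0 < self.reliability <= 1.0
        assert self.hscore >= 0.0


@dataclass
class ExonAssemblySet:
    """Filtered (and possibly gap-bridged) haplotypes for one exon."""

    gene: str
    exon_number: int
    haplotypes: list[AssembledHaplotype] = field(default_factory=list)
    fragments_joined: bool = False


# ---------------------------------------------------------------------------
# maximal-chain enumeration
# ---------------------------------------------------------------------------


def _maximal_sequences(unique: list[str], min_overlap: int, cap: int) -> list[str]:
    """All maximal chain sequences over the perfect-overlap graph.

    A chain grows rightwards: a read extends the assembly when the
    assembly's suffix of length L >= min_overlap equals the read's prefix
    and the read adds new bases.  Future growth depends only on the last
    ``max read length`` bases, so completions are memoised on that suffix
    window; chains started from every read plus a final substring filter
    give left-maximality.  Reads are treated as a set of sequences (chaining
    may revisit a sequence); a cycle guard caps pathological inputs.
    """
    if not unique:
        return []
    maxlen = max(len(u) for u in unique)
    W = maxlen
    pref: dict[str, list[str]] = defaultdict(list)
    for u in unique:
        pref[u[:min_overlap]].append(u)

    def extensions(window: str) -> list[str]:
        out = set()
        lo = max(0, len(window) - maxlen)
        for p in range(lo, len(window) - min_overlap + 1):
            overlap = len(window) - p
            for r in pref.get(window[p : p + min_overlap], ()):
                if len(r) > overlap and r[:overlap] == window[p:]:
                    out.add(r[overlap:])
        return sorted(out)

    memo: dict[str, tuple[str, ...]] = {}

    def complete(window: str, stack: set[str]) -> tuple[tuple[str, ...], bool]:
        """Completion suffixes from this window; bool = result is cacheable."""
        if window in memo:
            return memo[window], True
        if window in stack:
            return ("",), False  # cycle: stop extending along this path
        exts = extensions(window)
        if not exts:
            memo[window] = ("",)
            return memo[window], True
        stack.add(window)
        res: set[str] = set()
        clean = True
        for e in exts:
            sub, ok = complete((window + e)[-W:], stack)
            clean &= ok
            for c in sub:
                res.add(e + c)
                if len(res) >= cap:
                    break
            if len(res) >= cap:
                clean = False
                break
        stack.remove(window)
        out = tuple(sorted(res))
        if clean:
            memo[window] = out
        return out, clean

    results: set[str] = set()
    for u in unique:
        for c in complete(u[-W:], set())[0]:
            # u[-W:] == u since len(u) <= W
            results.add(u + c)
            if len(results) >= cap:
                break
    # drop assemblies contained in another
    ordered = sorted(results, key=lambda s: (-len(s), s))
    kept: list[str] = []
    for s in ordered:
        if not any(s in k and s != k for k in kept):
            kept.append(s)
    return sorted(kept)


def assemble_exon(
    reads,
    min_overlap: int = 10,
    max_chains: int = 10_000,
) -> list[RawAssembly]:
    """Assemble corrected reads of one exon into maximal haplotype chains.

    ``reads`` may be CorrectedRead objects or plain strings.  Each returned
    assembly carries a depth profile (each read instance adds 1 to every
    base it covers, at its leftmost occurrence in the assembly) and the
    count of read instances occurring in it; a read occurring in several
    assemblies counts in each.
    """
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    seqs = [s for s in seqs if s]
    if not seqs:
        return []
    multiplicity = Counter(seqs)
    unique = sorted(multiplicity)
    # every unique read is a node: a read contained in one read can still be
    # the only way to extend a chain through another
    sequences = _maximal_sequences(unique, min_overlap, max_chains)
    out = []
    for asm in sequences:
        depth = np.zeros(len(asm), dtype=np.int64)
        n_reads = 0
        for u, m in multiplicity.items():
            i = asm.find(u)
            if i >= 0:
                depth[i : i + len(u)] += m
                n_reads += m
        out.append(RawAssembly(sequence=asm, depth_profile=depth, n_reads=n_reads))
    return out


def filter_known(
    assemblies: Sequence[RawAssembly],
    db: AlleleDatabase,
    gene: str,
    exon_number: int,
    scoring: ScoringConfig = ScoringConfig(),
) -> ExonAssemblySet:
    """Keep assemblies occurring in the database for this exon; score them.

    An assembly survives when its sequence is a substring of (or equal to)
    some allele's exon sequence.  Coverage C is measured against the
    shortest compatible exon reference, so a full-length match scores C = 1.
    """
    out = ExonAssemblySet(gene=gene, exon_number=exon_number)
    by_allele: dict[str, str] = {
        a.name.raw: a.exons[exon_number - 1]
        for a in db.gene_alleles(gene)
        if exon_number <= a.n_exons
    }
    for raw in assemblies:
        compat = frozenset(n for n, ex in by_allele.items() if raw.sequence in ex)
        if not compat:
            continue
        ref_len = min(len(by_allele[n]) for n in compat)
        c = min(1.0, len(raw.sequence) / ref_len)
        r = scoring.reliability(raw.depth_profile)
        out.haplotypes.append(
            AssembledHaplotype(
                gene=gene,
                exon_number=exon_number,
                sequence=raw.sequence,
                depth_profile=np.asarray(raw.depth_profile),
                n_reads=raw.n_reads,
                coverage_fraction=c,
                reliability=r,
                hscore=scoring.hscore(c, r, raw.n_reads),
                compatible_alleles=compat,
            )
        )
    out.haplotypes.sort(key=lambda h: (-h.hscore, h.sequence))
    return out


def bridge_fragments(
    exon_set: ExonAssemblySet,
    db: AlleleDatabase,
    scoring: ScoringConfig = ScoringConfig(),
) -> ExonAssemblySet:
    """Pair partial fragments across low-depth gaps via the database.

    When an exon is broken into fragments, every database exon sequence on
    which >= 2 fragments place at non-overlapping positions (leftmost
    occurrence each) is emitted as a bridged full-exon candidate; the gap
    bases come from the database exon itself, and candidates matching no
    database exon never arise by construction.  Fragment depths carry over;
    gap bases have depth 0 and reliability is computed over covered bases.
    """
    gene, k = exon_set.gene, exon_set.exon_number
    fragments = [h for h in exon_set.haplotypes if h.coverage_fraction < 1.0]
    if len(fragments) < 2:
        return exon_set
    existing = {h.sequence for h in exon_set.haplotypes}
    by_allele = {
        a.name.raw: a.exons[k - 1] for a in db.gene_alleles(gene) if k <= a.n_exons
    }
    bridged_for: dict[str, AssembledHaplotype] = {}
    for ref in sorted(set(by_allele.values())):
        if ref in existing:
            continue
        placed = []
        for h in sorted(fragments, key=lambda h: (-len(h.sequence), h.sequence)):
            i = ref.find(h.sequence)
            if i < 0:
                continue
            if any(i < e and s < i + len(h.sequence) for s, e in
                   ((p, p + len(g.sequence)) for p, g in placed)):
                continue
            placed.append((i, h))
        if len(placed) < 2:
            continue
        depth = np.zeros(len(ref), dtype=np.int64)
        n_reads = 0
        for i, h in placed:
            depth[i : i + len(h.sequence)] += h.depth_profile
            n_reads += h.n_reads
        covered = int((depth > 0).sum())
        c = covered / len(ref)
        r = scoring.reliability(depth[depth > 0])
        compat = frozenset(n for n, ex in by_allele.items() if ex == ref)
        bridged_for[ref] = AssembledHaplotype(
            gene=gene,
            exon_number=k,
            sequence=ref,
            depth_profile=depth,
            n_reads=n_reads,
            coverage_fraction=c,
            reliability=r,
            hscore=scoring.hscore(c, r, n_reads),
            compatible_alleles=compat,
            bridged=True,
        )
    if bridged_for:
        out = ExonAssemblySet(
            gene=gene,
            exon_number=k,
            haplotypes=sorted(
                exon_set.haplotypes + list(bridged_for.values()),
                key=lambda h: (-h.hscore, h.sequence),
            ),
            fragments_joined=True,
        )
        return out
    return exon_set


def assemble_gene(
    corrected_reads,
    db: AlleleDatabase,
    gene: str,
    min_overlap: int = 10,
    scoring: ScoringConfig = ScoringConfig(),
    bridge: bool = True,
) -> dict[int, ExonAssemblySet]:
    """Assemble, filter and (optionally) bridge every exon of one gene."""
    by_exon: dict[int, list] = defaultdict(list)
    for cr in corrected_reads:
        by_exon[cr.match.exon_number].append(cr)
    out: dict[int, ExonAssemblySet] = {}
    for k in sorted(by_exon):
        raw = assemble_exon(by_exon[k], min_overlap=min_overlap)
        exon_set = filter_known(raw, db, gene, k, scoring)
        if bridge:
            exon_set = bridge_fragments(exon_set, db, scoring)
        out[k] = exon_set
    return out
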