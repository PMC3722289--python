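"""Reference-guided read error correction against the allele database.

Each harvested read is aligned to every allele of its gene and snapped to
the most similar reference.  A *discordance* is one mismatched base or one
insertion/deletion run of any length (gap events counted once regardless of
length).  Reads with more than ``max_discordances`` (default 2) events to
every reference are discarded; retained reads are rewritten to the exact
reference sequence over their aligned span, and every discordance is added
to a per-gene variant ledger that the typing step later mines for novel
SNPs/indels.

Matching uses edlib infix alignment in place of a BLAST search, with the
same contract: the reference with the fewest discordance events wins, ties
broken by longer aligned span, then lexicographic allele name, then lower
exon number.  When alleles carry a full (exon+intron) sequence, reads are
aligned against it and then trimmed to the single exon they overlap most,
so exon-boundary reads contribute their exonic portion; for exon-only
databases an explicit overhang scan covers reads running off an exon end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .allele_db import Allele, AlleleDatabase

__all__ = [
    "MatchConfig",
    "VariantRecord",
    "VariantLedger",
    "ReferenceMatch",
    "CorrectedRead",
    "GeneMatcher",
    "best_reference_match",
    "correct_read",
    "correct_gene_reads",
    "reverse_complement",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class MatchConfig:
    """Tunables of the reference matcher."""

    max_discordances: int = 2  # discard reads beyond this many SNP/indel events
    min_span: int = 30  # bp; reject spurious short matches
    k_cap: int = 6  # edit-distance ceiling handed to edlib
    allow_indels: bool = True  # gapless mode scans substitutions only


@dataclass(frozen=True)
class VariantRecord:
    """One discordance between reads and an allele reference.

    ``position`` is 0-based on the exon reference; an insertion has empty
    ``ref_bases``, a deletion empty ``alt_bases``.
    """

    allele: str
    exon_number: int
    position: int
    ref_bases: str
    alt_bases: str
    support: int = 1

    def __post_init__(self) -> None:
        if not self.ref_bases and not self.alt_bases:
            raise ValueError("variant with neither ref nor alt bases")


class VariantLedger:
    """Accumulates discordances with read-support counts."""

    def __init__(self) -> None:
        self._support: dict[tuple[str, int, int, str, str], int] = {}

    def record(self, allele: str, exon_number: int, position: int, ref: str, alt: str) -> None:
        key = (allele, exon_number, position, ref, alt)
        self._support[key] = self._support.get(key, 0) + 1

    def records(self) -> list[VariantRecord]:
        return [
            VariantRecord(a, e, p, r, alt, support=n)
            for (a, e, p, r, alt), n in sorted(self._support.items())
        ]

    def __len__(self) -> int:
        return len(self._support)

    def to_tsv(self) -> str:
        """VCF-like TSV report (positions 1-based)."""
        lines = ["allele\texon\tpos\tref\talt\tsupport"]
        for v in self.records():
            lines.append(
                f"{v.allele}\t{v.exon_number}\t{v.position + 1}\t"
                f"{v.ref_bases or '-'}\t{v.alt_bases or '-'}\t{v.support}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ReferenceMatch:
    """Best placement of a read on an allele's exon reference."""

    read_id: str
    allele: str
    exon_number: int
    offset: int  # 0-based start on the exon reference
    span: int  # aligned bases on the exon reference
    strand: str  # '+' or '-'
    discordances: tuple[tuple[int, str, str], ...]  # (pos-on-exon, ref, alt)
    events: int  # discordance events over the whole alignment
    score: float  # identity fraction over the aligned span

    @property
    def end(self) -> int:
        return self.offset + self.span


@dataclass(frozen=True)
class CorrectedRead:
    """A read snapped to its matched reference (exact exon substring)."""

    read_id: str
    sequence: str
    match: ReferenceMatch


def _parse_cigar(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def _events_from_path(query: str, target: str, t_start: int, cigar: str):
    """Walk an edlib extended CIGAR; return (t_start, t_end, events, disc).

    Discordance positions are absolute on ``target``.  Each X base is one
    event; each internal I or D run is one event of any length.  Terminal
    insertion runs are canonicalised to per-base substitutions whenever the
    reference continues past the alignment end: an unanchored read tail is
    not one cheap indel event but however many mismatches it really carries
    (this also makes the placement maximal-span and deterministic).
    """
    ops = [(length, op, False) for length, op in _parse_cigar(cigar)]
    if ops and ops[0][1] == "I" and t_start >= ops[0][0]:
        length = ops[0][0]
        t_start -= length
        ops[0] = (length, "C", True)  # compare base-by-base against the reference
    t_len = sum(length for length, op, _ in ops if op in "=XDC")
    if ops and ops[-1][1] == "I" and t_start + t_len + ops[-1][0] <= len(target):
        ops[-1] = (ops[-1][0], "C", True)
    qpos, tpos = 0, t_start
    events = 0
    disc: list[tuple[int, str, str]] = []
    for length, op, _conv in ops:
        if op == "=":
            qpos += length
            tpos += length
        elif op in ("X", "C"):
            for i in range(length):
                if query[qpos + i] != target[tpos + i]:
                    disc.append((tpos + i, target[tpos + i], query[qpos + i]))
                    events += 1
            qpos += length
            tpos += length
        elif op == "I":  # bases present in the read, absent from reference
            disc.append((tpos, "", query[qpos : qpos + length]))
            events += 1
            qpos += length
        elif op == "D":  # reference bases absent from the read
            disc.append((tpos, target[tpos : tpos + length], ""))
            events += 1
            tpos += length
        else:  # pragma: no cover - edlib emits only =XID in extended cigar
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return t_start, tpos, events, disc


@dataclass(frozen=True)
class _Candidate:
    events: int
    span: int
    allele: str
    exon_number: int
    offset: int
    discordances: tuple[tuple[int, str, str], ...]
    strand: str

    @property
    def order(self):
        return (self.events, -self.span, self.allele, self.exon_number, self.offset)


class GeneMatcher:
    """Matches reads against one gene's allele references, with caching."""

    def __init__(self, db: AlleleDatabase, gene: str, config: MatchConfig = MatchConfig()):
        if gene not in db.genes:
            raise ValueError(f"gene {gene!r} not in database")
        self.gene = gene
        self.config = config
        self.alleles: list[Allele] = db.gene_alleles(gene)
        self._cache: dict[tuple[str, str | None], _Candidate | None] = {}

    # -- per-target candidate generation ------------------------------------

    @staticmethod
    def _occurrences(haystack: str, needle: str, limit: int = 8) -> list[int]:
        out = []
        i = haystack.find(needle)
        while i >= 0 and len(out) < limit:
            out.append(i)
            i = haystack.find(needle, i + 1)
        return out

    def _full_candidates(self, seq: str, allele: Allele, strand: str, perfect_only: bool):
        """Align against the full sequence, trim to the best-overlapped exon.

        Perfect placements are plain substring hits (checked first, in C);
        edlib only runs for reads that match no reference exactly.
        """
        occ = self._occurrences(allele.full_sequence, seq)
        if occ:
            best = None
            for t0 in occ:
                cand = self._trim_to_exon(seq, allele, strand, t0, t0 + len(seq), 0, ())
                if cand and (best is None or cand.order < best.order):
                    best = cand
            return best
        if perfect_only:
            return "imperfect"
        res = edlib.align(seq, allele.full_sequence, mode="HW", task="path",
                          k=self.config.k_cap)
        if res["editDistance"] < 0:
            return None
        t0, _t1 = res["locations"][0]
        t0, t1, events, disc = _events_from_path(seq, allele.full_sequence, t0, res["cigar"])
        return self._trim_to_exon(seq, allele, strand, t0, t1, events, tuple(disc))

    def _trim_to_exon(self, seq: str, allele: Allele, strand: str,
                      t0: int, t1: int, events: int, disc: tuple) -> _Candidate | None:
        best_k, best_ov = None, 0
        for k, (s, e) in enumerate(allele.exon_spans, 1):
            ov = min(t1, e) - max(t0, s)
            if ov > best_ov:
                best_k, best_ov = k, ov
        if best_k is None or best_ov < self.config.min_span:
            return None
        s, e = allele.exon_spans[best_k - 1]
        local = tuple(
            (p - s, r, a) for p, r, a in disc if s <= p < e
        )
        return _Candidate(
            events=events,
            span=best_ov,
            allele=allele.name.raw,
            exon_number=best_k,
            offset=max(t0, s) - s,
            discordances=local,
            strand=strand,
        )

    def _exon_candidates(self, seq: str, allele: Allele, strand: str, perfect_only: bool):
        cfg = self.config
        best = None
        saw_imperfect = False
        for k, exon in enumerate(allele.exons, 1):
            if len(seq) <= len(exon):
                t0 = exon.find(seq)
                if t0 >= 0:
                    cand = _Candidate(0, len(seq), allele.name.raw, k, t0, (), strand)
                    if best is None or cand.order < best.order:
                        best = cand
                    continue
                if perfect_only:
                    saw_imperfect = True
                    continue
                res = edlib.align(seq, exon, mode="HW", task="path", k=cfg.k_cap)
                if res["editDistance"] > 0:
                    t0, _t1 = res["locations"][0]
                    t0, t1, events, disc = _events_from_path(seq, exon, t0, res["cigar"])
                    cand = _Candidate(events, t1 - t0, allele.name.raw, k, t0,
                                      tuple(disc), strand)
                    if best is None or cand.order < best.order:
                        best = cand
                    continue
            # no in-exon placement: try running off either exon end
            cand = self._overhang(seq, allele.name.raw, k, exon, strand)
            if cand and (best is None or cand.order < best.order):
                best = cand
        if best is None and saw_imperfect:
            return "imperfect"
        return best

    @staticmethod
    def _best_hamming(seq: str, ref: str) -> tuple[int, int] | None:
        """(mismatches, leftmost best offset) over all gapless placements."""
        if len(ref) < len(seq):
            return None
        q = np.frombuffer(seq.encode(), dtype=np.uint8)
        r = np.frombuffer(ref.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(r, len(seq))
        mism = (windows != q).sum(axis=1)
        off = int(mism.argmin())
        return int(mism[off]), off

    def _gapless_candidates(self, seq: str, allele: Allele, strand: str):
        """Best substitution-only placement (no gap events considered)."""

        def _disc(ref: str, off: int):
            return tuple(
                (off + i, ref[off + i], seq[i])
                for i in range(len(seq))
                if ref[off + i] != seq[i]
            )

        if allele.full_sequence is not None and allele.exon_spans is not None:
            hit = self._best_hamming(seq, allele.full_sequence)
            if hit is None:
                return None
            events, off = hit
            return self._trim_to_exon(
                seq, allele, strand, off, off + len(seq), events,
                _disc(allele.full_sequence, off),
            )
        best = None
        for k, exon in enumerate(allele.exons, 1):
            hit = self._best_hamming(seq, exon)
            if hit is None:
                continue
            events, off = hit
            cand = _Candidate(events, len(seq), allele.name.raw, k, off,
                              _disc(exon, off), strand)
            if best is None or cand.order < best.order:
                best = cand
        return best

    def _overhang(self, seq: str, raw: str, k: int, exon: str, strand: str):
        """Substitution-only scan for reads overhanging an exon boundary."""
        cfg = self.config
        best = None
        max_l = min(len(seq) - 1, len(exon))
        for left in (True, False):
            for ell in range(max_l, cfg.min_span - 1, -1):
                a = seq[-ell:] if left else seq[:ell]
                b = exon[:ell] if left else exon[-ell:]
                mism = [
                    (i, rb, qb) for i, (qb, rb) in enumerate(zip(a, b)) if qb != rb
                ]
                if len(mism) > cfg.max_discordances:
                    continue
                off = 0 if left else len(exon) - ell
                disc = tuple((off + i, rb, qb) for i, rb, qb in mism)
                cand = _Candidate(len(mism), ell, raw, k, off, disc, strand)
                if best is None or cand.order < best.order:
                    best = cand
                break  # longest acceptable overlap on this side
        return best

    # -- public matching -----------------------------------------------------

    def match_sequence(self, seq: str, strand_hint: str | None = None) -> _Candidate | None:
        """Best candidate for a read sequence, or None if unmatchable."""
        key = (seq, strand_hint)
        if key in self._cache:
            return self._cache[key]
        cand = self._match_uncached(seq, strand_hint)
        self._cache[key] = cand
        return cand

    def _match_uncached(self, seq: str, strand_hint: str | None) -> _Candidate | None:
        strands = [strand_hint] if strand_hint else ["+", "-"]
        best = None
        for strand in strands:
            oriented = seq if strand == "+" else reverse_complement(seq)
            # pass 1: perfect full-span matches, lex allele order, early exit
            retry: list[Allele] = []
            for allele in self.alleles:
                if allele.full_sequence is not None and allele.exon_spans is not None:
                    cand = self._full_candidates(oriented, allele, strand, True)
                else:
                    cand = self._exon_candidates(oriented, allele, strand, True)
                if cand == "imperfect":
                    retry.append(allele)
                    continue
                if cand is not None and cand.events == 0 and cand.span == len(seq):
                    return cand  # lex-first perfect full-span match wins outright
                if cand is not None and (best is None or cand.order < best.order):
                    best = cand
            # pass 2: realign the imperfect alleles with full event counting
            for allele in retry:
                if not self.config.allow_indels:
                    cand = self._gapless_candidates(oriented, allele, strand)
                elif allele.full_sequence is not None and allele.exon_spans is not None:
                    cand = self._full_candidates(oriented, allele, strand, False)
                else:
                    cand = self._exon_candidates(oriented, allele, strand, False)
                if cand is not None and cand != "imperfect" and (
                    best is None or cand.order < best.order
                ):
                    best = cand
                    if best.events == 1 and best.span == len(seq):
                        break  # unbeatable once no perfect match exists
            if best is not None and best.events == 0 and best.span == len(seq):
                break  # no need to try the other strand
        if best is None or best.events > self.config.max_discordances:
            return None
        if best.span < self.config.min_span:
            return None
        return best


def best_reference_match(
    read,
    db: AlleleDatabase,
    gene: str,
    config: MatchConfig = MatchConfig(),
    matcher: GeneMatcher | None = None,
) -> ReferenceMatch | None:
    """Match one read (``SequenceRead`` or str) to its closest allele reference.

    Returns None when the best alignment exceeds the discordance budget or
    spans fewer than ``config.min_span`` reference bases.
    """
    seq = read if isinstance(read, str) else read.sequence
    read_id = getattr(read, "id", "read")
    if not seq:
        raise ValueError("empty read sequence")
    m = matcher or GeneMatcher(db, gene, config)
    cand = m.match_sequence(seq)
    if cand is None:
        return None
    return ReferenceMatch(
        read_id=read_id,
        allele=cand.allele,
        exon_number=cand.exon_number,
        offset=cand.offset,
        span=cand.span,
        strand=cand.strand,
        discordances=cand.discordances,
        events=cand.events,
        score=1.0 - cand.events / cand.span,
    )


def correct_read(
    read,
    match: ReferenceMatch,
    db: AlleleDatabase,
    ledger: VariantLedger | None = None,
) -> CorrectedRead:
    """Snap a read to its matched reference; log its discordances.

    The corrected sequence is the exact reference substring over the aligned
    span, so downstream overlap assembly sees error-free sequence.
    """
    if match is None:
        raise ValueError("cannot correct a read without a retained match")
    exon = db.alleles[match.allele].exons[match.exon_number - 1]
    seq = exon[match.offset : match.offset + match.span]
    if ledger is not None:
        for pos, ref, alt in match.discordances:
            ledger.record(match.allele, match.exon_number, pos, ref, alt)
    return CorrectedRead(read_id=match.read_id, sequence=seq, match=match)


def correct_gene_reads(
    reads,
    db: AlleleDatabase,
    gene: str,
    config: MatchConfig = MatchConfig(),
    strand_hints: dict[str, str] | None = None,
):
    """Match and correct a gene's read pool.

    Returns ``(corrected, ledger, stats)`` with ``stats`` counting input,
    retained and discarded reads (conservation: input = retained + discarded).
    """
    matcher = GeneMatcher(db, gene, config)
    ledger = VariantLedger()
    corrected: list[CorrectedRead] = []
    stats = {"input": 0, "retained": 0, "discarded": 0}
    for read in reads:
        stats["input"] += 1
        hint = (strand_hints or {}).get(read.id)
        cand = matcher.match_sequence(read.sequence, hint)
        if cand is None:
            stats["discarded"] += 1
            continue
        match = ReferenceMatch(
            read_id=read.id,
            allele=cand.allele,
            exon_number=cand.exon_number,
            offset=cand.offset,
            span=cand.span,
            strand=cand.strand,
            discordances=cand.discordances,
            events=cand.events,
            score=1.0 - cand.events / cand.span,
        )
        corrected.append(correct_read(read, match, db, ledger))
        stats["retained"] += 1
    return corrected, ledger, stats
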