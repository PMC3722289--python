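"""Candidate scoring, pair selection, zygosity, confidence, novel variants."""

import random

import numpy as np
import pytest

from hlacall.assembly import AssembledHaplotype, ExonAssemblySet, assemble_gene
from hlacall.correction import MatchConfig, VariantRecord, correct_gene_reads
from hlacall.genotyping import (
    CandidateType,
    TypingConfig,
    ascore,
    call_gene,
    call_zygosity,
    enumerate_candidates,
    judge_novel_variants,
    select_pair,
    tscore,
)
from hlacall.read_prep import SequenceRead
from tests.conftest import B1, B2, E1, F, F2

_CFG = MatchConfig(min_span=10)


def _hap(gene="A", exon=1, seq="ACGTACGTACGT", n_reads=10, hs=1.0, compat=("A*01:01",)):
    return AssembledHaplotype(
        gene=gene,
        exon_number=exon,
        sequence=seq,
        depth_profile=np.ones(len(seq), int),
        n_reads=n_reads,
        coverage_fraction=1.0,
        reliability=1.0,
        hscore=hs,
        compatible_alleles=frozenset(compat),
    )


def _cand(allele, ts=0.0, support=frozenset(), exon_support=None):
    c = CandidateType(allele=allele, exon_support=exon_support or {})
    c.support_ids = frozenset(support)
    c.n_support = len(c.support_ids)
    c.tscore = ts
    return c


# -- candidate enumeration ---------------------------------------------------


def _reads(seqs, prefix="r"):
    return [
        SequenceRead(id=f"{prefix}{i}", sequence=s, qualities=(30,) * len(s))
        for i, s in enumerate(seqs)
    ]


def test_enumerate_candidates_fixture(toy_db):
    """Full-exon assemblies of A*01:01 list it (and exon-sharing alleles)."""
    reads = _reads([E1[i : i + 20] for i in range(0, 21, 5)]
                   + [F[i : i + 20] for i in range(0, 21, 5)])
    corrected, _l, _s = correct_gene_reads(reads, toy_db, "A", _CFG)
    exon_sets = assemble_gene(corrected, toy_db, "A", bridge=False)
    cands = enumerate_candidates(exon_sets, toy_db, "A")
    names = {c.allele for c in cands}
    assert "A*01:01" in names
    assert "A*01:02" in names  # shares exon 1 (E1) with A*01:01
    assert "A*02:01" not in names  # no assembly touches its private exons
    by_name = {c.allele: c for c in cands}
    assert set(by_name["A*01:01"].exon_support) == {1, 2}
    assert set(by_name["A*01:02"].exon_support) == {1}


def test_tscore_is_sum_of_support_times_score():
    c1 = CandidateType(allele="A*01:01", exon_support={1: _hap(n_reads=10, hs=2.0)})
    assert tscore(c1) == pytest.approx(20.0)
    c2 = CandidateType(allele="A*01:01", exon_support={})
    assert tscore(c2) == 0.0
    c3 = CandidateType(
        allele="A*01:01",
        exon_support={1: _hap(n_reads=10, hs=2.0), 2: _hap(exon=2, n_reads=5, hs=1.0)},
    )
    assert tscore(c3) == pytest.approx(25.0)


def test_tscore_monotone_in_added_support():
    base = {1: _hap(n_reads=10, hs=2.0), 2: _hap(exon=2, n_reads=5, hs=1.0)}
    more = {1: _hap(n_reads=11, hs=2.0), 2: base[2]}
    assert tscore(CandidateType("X", exon_support=more)) > tscore(
        CandidateType("X", exon_support=base)
    )


# -- pair selection and zygosity ---------------------------------------------


def test_select_pair_orders_by_tscore():
    cands = [_cand("C*03", 5.0), _cand("C*01", 30.0), _cand("C*02", 20.0)]
    cfg = TypingConfig(tscore=lambda c: c.tscore)
    best, sub = select_pair(cands, cfg)
    assert (best.allele, sub.allele) == ("C*01", "C*02")


def test_select_pair_tie_breaks_on_support_then_name():
    cands = [
        _cand("C*02", 30.0, support=range(40)),
        _cand("C*01", 30.0, support=range(35)),
    ]
    cfg = TypingConfig(tscore=lambda c: c.tscore)
    best, sub = select_pair(cands, cfg)
    assert best.allele == "C*02"  # higher support wins the TScore tie
    cands = [_cand("C*02", 30.0, support=range(40)), _cand("C*01", 30.0, support=range(40))]
    best, _ = select_pair(cands, cfg)
    assert best.allele == "C*01"  # then lexicographic name


def test_select_pair_single_candidate():
    best, sub = select_pair([_cand("C*01", 10.0, support={1, 2})],
                            TypingConfig(tscore=lambda c: c.tscore))
    assert sub is None


def test_shared_reads_count_in_both_supports_but_no_unique():
    shared = set(range(30))
    cands = [
        _cand("C*01", 30.0, support=shared | {100, 101}),
        _cand("C*02", 20.0, support=shared | {200}),
    ]
    best, sub = select_pair(cands, TypingConfig(tscore=lambda c: c.tscore))
    assert best.n_support == 32 and sub.n_support == 31
    assert sub.n_unique_support == 1  # only read 200 is unique to the runner-up


@pytest.mark.parametrize(
    "unique, best_support, zygosity",
    [
        (4, 100, "homozygote"),  # ratio 0.04 < 0.1
        (10, 100, "heterozygote"),  # boundary ratio 0.10 counts heterozygous
        (11, 100, "heterozygote"),
        (0, 50, "homozygote"),
    ],
)
def test_zygosity_threshold(unique, best_support, zygosity):
    best = _cand("C*01", 30.0, support=range(best_support))
    sub = _cand("C*02", 20.0)
    sub.n_unique_support = unique
    zyg, ratio = call_zygosity(best, sub)
    assert zyg == zygosity
    assert ratio == pytest.approx(unique / best_support)


def test_no_suboptimal_is_homozygote():
    zyg, ratio = call_zygosity(_cand("C*01", 30.0, support={1}), None)
    assert (zyg, ratio) == ("homozygote", 0.0)


def test_zygosity_rule_on_randomized_tables():
    """homozygote <=> ratio < 0.1 over random support configurations."""
    rng = random.Random(77)
    for _ in range(300):
        n_best = rng.randint(1, 200)
        n_unique = rng.randint(0, 60)
        best = _cand("C*01", 30.0, support=range(n_best))
        sub = _cand("C*02", 20.0)
        sub.n_unique_support = n_unique
        zyg, ratio = call_zygosity(best, sub)
        assert (zyg == "homozygote") == (ratio < 0.1)
        assert ratio == pytest.approx(n_unique / n_best)


def test_permutation_invariance_of_selection():
    rng = random.Random(13)
    cands = [
        _cand(f"C*{i:02d}", rng.choice([5.0, 20.0, 30.0]), support=range(rng.randint(1, 50)))
        for i in range(1, 8)
    ]
    cfg = TypingConfig(tscore=lambda c: c.tscore)
    expected = None
    for _ in range(5):
        rng.shuffle(cands)
        best, sub = select_pair(cands, cfg)
        key = (best.allele, sub.allele if sub else None)
        expected = expected or key
        assert key == expected


# -- AScore ------------------------------------------------------------------


@pytest.mark.parametrize(
    "s0, s1, s2, expected",
    [
        (100.0, 40.0, 40.0, 0.0),  # no separation
        (100.0, 20.0, 60.0, 0.4),
        (100.0, 0.0, 100.0, 1.0),  # maximal separation
    ],
)
def test_ascore_values(s0, s1, s2, expected):
    assert ascore(s0, s1, s2) == pytest.approx(expected)


def test_ascore_undefined_when_no_score_mass():
    assert np.isnan(ascore(0.0, 0.0, 0.0))


# -- novel variants ----------------------------------------------------------


def test_novel_snp_requires_support_and_absence_from_panel(toy_db):
    recs = [
        VariantRecord("A*01:01", 2, 20, F[20], "A" if F[20] != "A" else "C", support=10),
        VariantRecord("A*01:01", 2, 30, F[30], "A" if F[30] != "A" else "C", support=2),
    ]
    out = judge_novel_variants(recs, ["A*01:01"], toy_db, "A", min_support=4)
    assert len(out) == 1
    assert out[0].variant.position == 20
    assert out[0].linked_allele == "A*01:01"


def test_discordance_matching_another_allele_is_not_novel(toy_db):
    """The F2 base at the F/F2 SNP site is evidence of A*01:02, not novelty."""
    rec = VariantRecord("A*01:01", 2, 10, F[10], F2[10], support=10)
    assert judge_novel_variants([rec], ["A*01:01"], toy_db, "A") == []


def test_untypeable_gene_reported_not_raised(toy_db):
    result = call_gene({}, [], [], toy_db, "B")
    assert result.status == "untypeable"
    assert result.alleles == ()


def test_call_gene_homozygote_end_to_end(toy_db):
    """Reads purely from B*05:01 call it homozygous with confidence."""
    reads = _reads(
        [B1[i : i + 20] for i in range(0, 21, 4)] + [B2[i : i + 20] for i in range(0, 21, 4)]
    )
    corrected, ledger, _ = correct_gene_reads(reads, toy_db, "B", _CFG)
    exon_sets = assemble_gene(corrected, toy_db, "B", bridge=False)
    result = call_gene(exon_sets, corrected, ledger.records(), toy_db, "B")
    assert result.status == "ok"
    assert result.zygosity == "homozygote"
    assert result.alleles == ("B*05:01",)
    assert result.ratio < 0.1
    assert 0.0 <= result.ascore <= 1.0
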