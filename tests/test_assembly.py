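"""Perfect-overlap assembly, database filtering, bridging and scores."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlacall.assembly import (
    ScoringConfig,
    assemble_exon,
    bridge_fragments,
    filter_known,
    hscore,
    reliability,
)
from tests.conftest import E1, F, F2


def _sequences(assemblies):
    return sorted(a.sequence for a in assemblies)


# -- worked overlap-boundary fixtures ---------------------------------------


def _pair_with_overlap(rng, left_len, right_len, overlap):
    """Two reads sharing exactly `overlap` bases (no incidental repeats)."""
    while True:
        merged = "".join(rng.choice("ACGT") for _ in range(left_len + right_len - overlap))
        a, b = merged[:left_len], merged[left_len - overlap :]
        # exactly one suffix/prefix overlap >= 1 between a and b, of length `overlap`
        overlaps = [L for L in range(1, min(len(a), len(b)) + 1) if a[-L:] == b[:L]]
        if overlaps == [overlap]:
            return a, b, merged


def test_ten_base_perfect_overlap_merges():
    rng = random.Random(1)
    a, b, merged = _pair_with_overlap(rng, 14, 14, 10)
    assert _sequences(assemble_exon([a, b])) == [merged]
    assert len(merged) == 18


def test_nine_base_overlap_stays_fragmented():
    rng = random.Random(2)
    a, b, _ = _pair_with_overlap(rng, 14, 14, 9)
    assert _sequences(assemble_exon([a, b])) == sorted([a, b])


def test_mismatch_in_overlap_region_blocks_merging():
    rng = random.Random(3)
    a, b, _ = _pair_with_overlap(rng, 20, 20, 12)
    bad = list(b)
    bad[5] = "G" if bad[5] != "G" else "C"  # one difference inside the overlap
    bad = "".join(bad)
    out = _sequences(assemble_exon([a, bad]))
    assert a in out and bad in out and len(out) == 2


def test_depth_profile_and_read_counts():
    rng = random.Random(4)
    a, b, merged = _pair_with_overlap(rng, 14, 14, 10)
    (asm,) = assemble_exon([a, a, b])  # first read duplicated
    assert asm.sequence == merged
    assert asm.n_reads == 3
    expected = np.zeros(18, int)
    expected[:14] += 2
    expected[4:] += 1
    assert (asm.depth_profile == expected).all()
    # conservation: one assembly containing every read
    assert asm.depth_profile.sum() == 2 * 14 + 14


# -- brute-force oracle ------------------------------------------------------


def _oracle_assemble(reads, min_overlap=10):
    """Merge-closure by BFS over assembled strings; maximal under substring."""
    reads = sorted(set(reads))
    seen = set(reads)
    frontier = list(reads)
    limit = sum(map(len, reads)) + 1
    while frontier:
        s = frontier.pop()
        for r in reads:
            for L in range(min_overlap, min(len(s), len(r)) + 1):
                if len(r) > L and s[-L:] == r[:L]:  # r extends s rightwards
                    t = s + r[L:]
                    if len(t) <= limit and t not in seen:
                        seen.add(t)
                        frontier.append(t)
                if len(r) > L and r[-L:] == s[:L]:  # r extends s leftwards
                    t = r[: len(r) - L] + s
                    if len(t) <= limit and t not in seen:
                        seen.add(t)
                        frontier.append(t)
    return sorted(s for s in seen if not any(s != t and s in t for t in seen))


def _random_instance(rng):
    template = "".join(rng.choice("ACGT") for _ in range(rng.randint(40, 90)))
    reads = []
    for _ in range(rng.randint(2, 8)):
        ln = rng.randint(12, 30)
        off = rng.randrange(max(1, len(template) - ln + 1))
        reads.append(template[off : off + ln])
    return reads


@pytest.mark.parametrize("trial", range(60))
def test_assembly_equals_brute_force_on_random_instances(trial):
    rng = random.Random(5000 + trial)
    reads = _random_instance(rng)
    assert _sequences(assemble_exon(reads)) == _oracle_assemble(reads)


def test_assembly_order_invariance():
    rng = random.Random(99)
    reads = _random_instance(rng)
    baseline = _sequences(assemble_exon(reads))
    for _ in range(5):
        rng.shuffle(reads)
        assert _sequences(assemble_exon(reads)) == baseline


def test_two_haplotypes_give_two_maximal_assemblies():
    """Reads from F and F2 (1 SNP apart) assemble into both haplotypes."""
    reads = [F[i : i + 20] for i in range(0, 21, 5)] + [
        F2[i : i + 20] for i in range(0, 21, 5)
    ]
    out = _sequences(assemble_exon(reads))
    assert F in out and F2 in out


# -- reliability & HScore ----------------------------------------------------


def test_reliability_uniform_depth_is_one():
    assert reliability([20, 20, 20, 20]) == 1.0


def test_reliability_hand_value():
    # Xi=[10,20,30]: mean 20, ssq 200, D = 200/20/2 = 5 -> R = 1/6
    assert reliability([10, 20, 30]) == pytest.approx(1 / 6)


def test_reliability_spreadsheet_value():
    xi = np.array([5.0, 5.0, 5.0, 50.0])
    d = float(((xi - xi.mean()) ** 2).sum() / xi.mean()) / (len(xi) - 1)
    assert reliability([5, 5, 5, 50]) == pytest.approx(1 / (1 + d))


def test_reliability_degenerate_length_is_one():
    assert reliability([7]) == 1.0


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.integers(1, 60), min_size=2, max_size=12), st.randoms())
def test_reliability_permutation_invariant(xi, rnd):
    shuffled = list(xi)
    rnd.shuffle(shuffled)
    assert reliability(shuffled) == pytest.approx(reliability(xi))


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.integers(2, 40), min_size=3, max_size=10), st.integers(1, 20))
def test_reliability_decreases_with_added_dispersion(xi, bump):
    """Moving one depth away from the mean strictly lowers R."""
    x = np.array(xi, dtype=float)
    i = int(np.argmax(x))  # already >= mean; push it further out
    perturbed = x.copy()
    perturbed[i] += bump
    if np.allclose(x, x.mean()):
        assert reliability(perturbed) < reliability(x) == 1.0
    else:
        assert reliability(perturbed) < reliability(x)


@pytest.mark.parametrize(
    "c, r, n, expected",
    [
        (1.0, 1.0, 0, 0.0),  # no reads -> zero score
        (1.0, 1.0, math.e - 1, 1.0),
        (0.9, 0.5, 30, 0.9 * 0.5 * math.log(31)),
    ],
)
def test_hscore_values(c, r, n, expected):
    assert hscore(c, r, n) == pytest.approx(expected)


# -- database filter and bridging -------------------------------------------


def test_filter_retains_known_and_drops_chimeras(toy_db):
    reads_f = [F[i : i + 20] for i in range(0, 21, 4)]
    chimera = F[:25] + E1[:15]  # exists in no allele
    raw = assemble_exon(reads_f + [chimera])
    out = filter_known(raw, toy_db, "A", 2)
    assert _sequences(out.haplotypes) == [F]
    (h,) = out.haplotypes
    assert h.coverage_fraction == 1.0
    assert h.compatible_alleles == {"A*01:01"}


def test_partial_assembly_compatible_with_two_alleles(toy_db):
    fragment = F[15:40]  # downstream of the F/F2 SNP at position 10
    out = filter_known(assemble_exon([fragment]), toy_db, "A", 2)
    (h,) = out.haplotypes
    assert h.compatible_alleles == {"A*01:01", "A*01:02"}
    assert h.coverage_fraction == pytest.approx(25 / 40)


def test_refilter_is_idempotent(toy_db):
    raw = assemble_exon([F[i : i + 20] for i in range(0, 21, 4)])
    once = filter_known(raw, toy_db, "A", 2)
    again = filter_known(
        [type("R", (), {"sequence": h.sequence, "depth_profile": h.depth_profile,
                        "n_reads": h.n_reads})() for h in once.haplotypes],
        toy_db, "A", 2,
    )
    assert _sequences(again.haplotypes) == _sequences(once.haplotypes)


def test_bridging_unique_gap_yields_one_candidate(toy_db):
    """Fragments flanking a gap bridge through the only consistent exon."""
    left = F2[:15]  # carries the F2 SNP at position 10 -> only F2 is consistent
    right = F[26:]  # shared between F and F2 downstream of the SNP
    exon_set = filter_known(assemble_exon([left, right]), toy_db, "A", 2)
    bridged = bridge_fragments(exon_set, toy_db)
    full = [h for h in bridged.haplotypes if h.bridged]
    assert [h.sequence for h in full] == [F2]
    assert bridged.fragments_joined
    (h,) = full
    assert h.n_reads == 2
    assert h.coverage_fraction == pytest.approx((15 + 14) / 40)


def test_bridging_ambiguous_gap_yields_both_candidates(toy_db):
    left, right = F[:8], F[26:]  # both fragments avoid the SNP at position 10
    exon_set = filter_known(assemble_exon([left, right]), toy_db, "A", 2)
    bridged = bridge_fragments(exon_set, toy_db)
    assert sorted(h.sequence for h in bridged.haplotypes if h.bridged) == sorted([F, F2])


def test_bridging_without_consistent_exon_adds_nothing(toy_db):
    """Fragments from different genes place on no single exon."""
    exon_set = filter_known(assemble_exon([F[:15]]), toy_db, "A", 2)
    out = bridge_fragments(exon_set, toy_db)  # a single fragment cannot bridge
    assert not any(h.bridged for h in out.haplotypes)
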