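"""Shared fixtures: a hand-built toy allele panel and the synthetic panel."""

from __future__ import annotations

import pytest

from hlacall.allele_db import Allele, AlleleDatabase, parse_allele_name
from hlacall.simulate import generate_synthetic_db

# 40 bp exon references for the toy panel (hand-designed, no accidental
# 10-mer repeats across genes)
E1 = "ACGTACGTAAGGCCTTACGTGGATCCAAGGTTCCGGAATT"
F = "TTGACCGGTTAACCGGATATCGCGATCGATCCGGAATTCC"
F2 = F[:10] + "G" + F[11:]  # one SNP at exon-2 position 10 (A->G)
E1M = E1[:5] + "T" + E1[6:20] + "C" + E1[21:]  # two SNPs vs E1
FM = F[:2] + "A" + F[3:15] + "T" + F[16:30] + "A" + F[31:]  # three SNPs vs F

B1 = "GGATTCCAGGCTTAAGGCCAATTGGCCATGCATGGCATTA"
B2 = "CCTTAGGATCAGTCAGGATCCATGGATCCTTGGCCAATGG"
B2V = B2[:20] + "A" + B2[21:]  # one SNP at exon-2 position 20 (C->A)


def _allele(label: str, exons) -> Allele:
    return Allele(name=parse_allele_name(label), exons=tuple(exons))


@pytest.fixture(scope="session")
def toy_db() -> AlleleDatabase:
    """Two genes, five alleles, two 40 bp exons each; no full sequences."""
    db = AlleleDatabase()
    db.add(_allele("A*01:01", [E1, F]))
    db.add(_allele("A*01:02", [E1, F2]))
    db.add(_allele("A*02:01", [E1M, FM]))
    db.add(_allele("B*05:01", [B1, B2]))
    db.add(_allele("B*05:02", [B1, B2V]))
    return db


@pytest.fixture(scope="session")
def default_panel() -> AlleleDatabase:
    """The default synthetic study panel: 3 genes x 8 alleles x 8 exons, 1%."""
    return generate_synthetic_db(n_genes=3, alleles_per_gene=8, exons_per_gene=8,
                                 divergence=0.01, seed=7)
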