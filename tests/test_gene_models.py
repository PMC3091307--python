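"""Region arithmetic: exon classes, specific regions, translation, projection."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from isofunc.gene_models import (
    CdsError,
    CodingExon,
    ExonClass,
    GeneModel,
    GenomicInterval,
    InternalStopError,
    Isoform,
    RegionClass,
    SPECIFIC_REGION_CLASSES,
    classify_exons,
    collapse_utr_duplicates,
    find_specific_regions,
    protein_to_genome,
    translate_cds,
)
from isofunc.synthetic_data import SimulationConfig, random_gene_model

from conftest import base_coverage, make_isoform

# independent codon table, indexed by base-4 digits over TCAG
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


def oracle_translate(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - 2, 3):
        idx = 16 * _BASES.index(nt[i]) + 4 * _BASES.index(nt[i + 1]) + _BASES.index(nt[i + 2])
        out.append(_AAS[idx])
    return "".join(out)


def revcomp(nt: str) -> str:
    return nt.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# interval / model validation


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10, "+")
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 5, "+")
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 5, "x")
    iv = GenomicInterval("chr1", 100, 200, "+")
    assert iv.length == 100
    assert iv.overlaps(GenomicInterval("chr1", 150, 250, "-"))
    assert not iv.overlaps(GenomicInterval("chr1", 200, 250, "+"))
    assert not iv.overlaps(GenomicInterval("chr2", 150, 250, "+"))


def test_isoform_rejects_overlapping_exons():
    with pytest.raises(ValueError):
        make_isoform("t1", "g", [(0, 30), (20, 60)])


# ---------------------------------------------------------------------------
# UTR-duplicate collapse


def test_collapse_identical_cds_keeps_smallest_id():
    a = make_isoform("t_b", "g", [(0, 30), (100, 130)])
    b = make_isoform("t_a", "g", [(0, 30), (100, 130)])
    c = make_isoform("t_c", "g", [(0, 30)])
    out = collapse_utr_duplicates(GeneModel("g", [a, b, c]))
    assert sorted(i.isoform_id for i in out.isoforms) == ["t_a", "t_c"]


def test_collapse_noop_when_cds_differ():
    a = make_isoform("t1", "g", [(0, 30), (100, 130)])
    b = make_isoform("t2", "g", [(0, 30), (200, 230)])
    out = collapse_utr_duplicates(GeneModel("g", [a, b]))
    assert len(out.isoforms) == 2


def test_collapse_matches_signature_dedup_oracle(rng):
    # random CDS structures, some duplicated across isoforms
    pool = [[(0, 30), (100, 130)], [(0, 30), (200, 230)], [(0, 30)], [(50, 80), (100, 130)]]
    for _ in range(25):
        n = int(rng.integers(2, 9))
        picks = [pool[int(rng.integers(len(pool)))] for _ in range(n)]
        isoforms = [make_isoform(f"t{i:02d}", "g", ex) for i, ex in enumerate(picks)]
        out = collapse_utr_duplicates(GeneModel("g", isoforms))
        expected = len({tuple(sorted(map(tuple, ex))) for ex in picks})
        assert len(out.isoforms) == expected


# ---------------------------------------------------------------------------
# exon classification


def test_classify_constitutive_and_specific():
    i1 = make_isoform("t1", "g", [(0, 30), (100, 130)])
    i2 = make_isoform("t2", "g", [(0, 30)])
    classes = classify_exons(GeneModel("g", [i1, i2]))
    assert classes["t1.e0"] is ExonClass.CONSTITUTIVE
    assert classes["t2.e0"] is ExonClass.CONSTITUTIVE
    assert classes["t1.e1"] is ExonClass.SPECIFIC


def test_classify_partial_overlap_both_sides():
    i1 = make_isoform("t1", "g", [(100, 200)])
    i2 = make_isoform("t2", "g", [(150, 250)])
    classes = classify_exons(GeneModel("g", [i1, i2]))
    assert classes["t1.e0"] is ExonClass.PARTIALLY_OVERLAPPING
    assert classes["t2.e0"] is ExonClass.PARTIALLY_OVERLAPPING


def test_classify_requires_multiple_isoforms():
    lone = make_isoform("t1", "g", [(0, 30)])
    with pytest.raises(ValueError):
        classify_exons(GeneModel("g", [lone]))


def _oracle_classify(gene: GeneModel):
    """Brute-force membership/overlap scan, independent of the sweep code."""
    n = len(gene.isoforms)
    exons = [
        (iso.isoform_id, e.exon_id, e.interval) for iso in gene.isoforms for e in iso.cds_exons
    ]
    out = {}
    for iso_id, exon_id, iv in exons:
        same = {o_iso for o_iso, _, o_iv in exons if o_iv.key == iv.key}
        partial = any(
            o_iso != iso_id and o_iv.key != iv.key and iv.overlaps(o_iv)
            for o_iso, _, o_iv in exons
        )
        if len(same) == n:
            out[exon_id] = ExonClass.CONSTITUTIVE
        elif partial:
            out[exon_id] = ExonClass.PARTIALLY_OVERLAPPING
        elif len(same) > 1:
            out[exon_id] = ExonClass.SEMI_CONSTITUTIVE
        else:
            out[exon_id] = ExonClass.SPECIFIC
    return out


def test_classify_matches_bruteforce_on_random_genes(rng):
    cfg = SimulationConfig(p_third_isoform=0.6, p_partial_overlap=0.6)
    seen = set()
    for i in range(40):
        gene, _ = random_gene_model(rng, cfg, index=i)
        classes = classify_exons(gene)
        assert classes == _oracle_classify(gene)
        seen |= set(classes.values())
    # the generator exercises every class
    assert seen == set(ExonClass)


# ---------------------------------------------------------------------------
# specific regions


def test_no_specific_regions_when_all_exons_shared():
    i1 = make_isoform("t1", "g", [(0, 30), (100, 130)])
    i2 = make_isoform("t2", "g", [(0, 30), (100, 130)])
    rc = find_specific_regions(GeneModel("g", [i1, i2]))
    assert all(r.region_class not in SPECIFIC_REGION_CLASSES for r in rc.regions)


def test_specific_exon_becomes_specific_region():
    i1 = make_isoform("t1", "g", [(0, 30), (100, 200)])
    i2 = make_isoform("t2", "g", [(0, 30)])
    rc = find_specific_regions(GeneModel("g", [i1, i2]))
    assert rc.specific_intervals("t1") == [GenomicInterval("chr1", 100, 200, "+")]
    assert rc.specific_intervals("t2") == []


def test_partial_overlap_yields_two_private_parts():
    i1 = make_isoform("t1", "g", [(100, 200)])
    i2 = make_isoform("t2", "g", [(150, 250)])
    rc = find_specific_regions(GeneModel("g", [i1, i2]))
    assert rc.specific_intervals("t1") == [GenomicInterval("chr1", 100, 150, "+")]
    assert rc.specific_intervals("t2") == [GenomicInterval("chr1", 200, 250, "+")]
    shared = [r for r in rc.regions if r.region_class is RegionClass.PO_SHARED_PART]
    assert [r.interval for r in shared] == [GenomicInterval("chr1", 150, 200, "+")]


def test_regions_partition_exonic_bases(rng):
    cfg = SimulationConfig(p_third_isoform=0.5, p_partial_overlap=0.5)
    for i in range(30):
        gene, _ = random_gene_model(rng, cfg, index=i)
        rc = find_specific_regions(gene)
        cover = base_coverage(gene)
        # disjoint and exhaustive
        claimed = defaultdict(int)
        for r in rc.regions:
            for p in range(r.interval.start, r.interval.end):
                claimed[p] += 1
                assert set(r.owners) == cover[p]
                assert (len(cover[p]) == 1) == (r.region_class in SPECIFIC_REGION_CLASSES)
        assert set(claimed) == set(cover)
        assert all(v == 1 for v in claimed.values())
        # specific regions of distinct isoforms are pairwise disjoint
        spec = [
            (iso, iv)
            for iso in [i.isoform_id for i in gene.isoforms]
            for iv in rc.specific_intervals(iso)
        ]
        for a, (iso_a, iv_a) in enumerate(spec):
            for iso_b, iv_b in spec[a + 1 :]:
                if iso_a != iso_b:
                    assert not iv_a.overlaps(iv_b)


def test_specific_exons_agree_with_specific_regions(rng):
    cfg = SimulationConfig(p_third_isoform=0.5, p_partial_overlap=0.5)
    for i in range(20):
        gene, _ = random_gene_model(rng, cfg, index=100 + i)
        classes = classify_exons(gene)
        rc = find_specific_regions(gene)
        for iso in gene.isoforms:
            own = rc.specific_intervals(iso.isoform_id)
            for exon in iso.cds_exons:
                if classes[exon.exon_id] is ExonClass.SPECIFIC:
                    assert any(iv.contains(exon.interval) for iv in own)


# ---------------------------------------------------------------------------
# translation


def test_translate_plus_strand():
    iso = make_isoform("t1", "g", [(3, 12)])
    assert translate_cds(iso, {"chr1": "NNNATGAAATAANN"}) == "MK"


def test_translate_minus_strand_symmetry():
    # same CDS, reverse-complemented in the genome
    iso = make_isoform("t1", "g", [(2, 11)], strand="-")
    genome = {"chr1": "NN" + revcomp("ATGAAATAA") + "NNN"}
    assert translate_cds(iso, genome) == "MK"


def test_translate_error_flags():
    iso = make_isoform("t1", "g", [(0, 10)])
    with pytest.raises(CdsError):
        translate_cds(iso, {"chr1": "ATGAAATAAT"})
    iso2 = make_isoform("t2", "g", [(0, 9)])
    with pytest.raises(InternalStopError):
        translate_cds(iso2, {"chr1": "TAAATGAAA"})


def test_translate_matches_independent_codon_table(rng):
    # random 300-codon CDS split over three exons, both strands
    for strand in "+-":
        nt = "ATG" + "".join(
            rng.choice([c for c in _codon_pool() if oracle_translate(c) != "*"])
            for _ in range(299)
        )
        genome_fwd = "NNNNN" + nt[:300] + "NN" + nt[300:600] + "NNN" + nt[600:] + "NNNN"
        if strand == "+":
            genome = {"chr1": genome_fwd}
            spans = [(5, 305), (307, 607), (610, 910)]
        else:
            L = len(genome_fwd)
            genome = {"chr1": revcomp(genome_fwd)}
            spans = [(L - e, L - s) for s, e in [(5, 305), (307, 607), (610, 910)]]
        iso = make_isoform("t1", "g", spans, strand=strand)
        assert translate_cds(iso, genome) == oracle_translate(nt)


def _codon_pool():
    return ["".join((a, b, c)) for a in _BASES for b in _BASES for c in _BASES]


# ---------------------------------------------------------------------------
# protein -> genome projection


def test_projection_single_exon():
    iso = make_isoform("t1", "g", [(100, 130)])
    iso.protein_seq = "X" * 10
    assert protein_to_genome(iso, 1, 2) == [GenomicInterval("chr1", 100, 106, "+")]


def test_projection_codon_straddles_junction():
    # exon1 has 10 bases, so residue 4 uses bases 9..12 across the junction
    iso = make_isoform("t1", "g", [(0, 10), (50, 60)])
    iso.protein_seq = "X" * 6
    fp = protein_to_genome(iso, 4, 4)
    assert [iv.key for iv in fp] == [("chr1", 9, 10, "+"), ("chr1", 50, 52, "+")]
    assert sum(iv.length for iv in fp) == 3


def test_projection_out_of_range():
    iso = make_isoform("t1", "g", [(0, 30)])
    iso.protein_seq = "X" * 10
    with pytest.raises(ValueError):
        protein_to_genome(iso, 0, 2)
    with pytest.raises(ValueError):
        protein_to_genome(iso, 9, 11)


def test_projection_length_and_composition(rng):
    cfg = SimulationConfig()
    for i in range(10):
        gene, _ = random_gene_model(rng, cfg, index=200 + i)
        for iso in gene.isoforms:
            n = iso.n_residues
            a = int(rng.integers(1, n))
            b = int(rng.integers(a, n + 1))
            fp = protein_to_genome(iso, a, b)
            assert sum(iv.length for iv in fp) == 3 * (b - a + 1)
            # composing over all residues reproduces the CDS exon set
            whole = protein_to_genome(iso, 1, n)
            assert sorted(iv.key for iv in whole) == sorted(
                iv.key for iv in iso.exon_intervals
            )
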