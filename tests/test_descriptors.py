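"""Domain coverage, threshold calibration, structural rules, SASA, active sites."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isofunc.descriptors import (
    DomainHit,
    StructuralAssessment,
    Thresholds,
    Verdict,
    active_site_verdict,
    compute_sasa,
    derive_threshold,
    domain_coverage,
    pfam_verdict,
    structure_verdict,
)
from isofunc.gene_models import GeneModel

from conftest import make_isoform


def _hit(cov_states: int, length: int = 100, name: str = "PF00001", ev: float = 1e-10):
    return DomainHit(
        isoform_id="iso1",
        hmm_name=name,
        hmm_length=length,
        hmm_from=1,
        hmm_to=cov_states,
        seq_from=1,
        seq_to=cov_states,
        evalue=ev,
    )


# ---------------------------------------------------------------------------
# domain integrity


def test_domain_coverage_values_and_boundary():
    assert domain_coverage(_hit(70)) == 0.70
    assert domain_coverage(_hit(69)) == 0.69
    assert domain_coverage(_hit(100)) == 1.0


def test_domain_hit_validates_coordinates():
    with pytest.raises(ValueError):
        DomainHit("i", "PF", 100, 50, 40, 1, 10, 1e-9)
    with pytest.raises(ValueError):
        DomainHit("i", "PF", 100, 0, 40, 1, 10, 1e-9)


def test_coverage_equals_matched_state_count(rng):
    for _ in range(50):
        length = int(rng.integers(30, 500))
        a = int(rng.integers(1, length + 1))
        b = int(rng.integers(a, length + 1))
        h = DomainHit("i", "PF", length, a, b, 1, b - a + 1, 1e-9)
        matched_states = len(range(a, b + 1))  # counting oracle
        assert domain_coverage(h) == matched_states / length


def test_pfam_verdict_cases():
    assert pfam_verdict([]).verdict is Verdict.NOT_APPLICABLE
    ok = pfam_verdict([_hit(95), _hit(80, name="PF00002")])
    assert ok.verdict is Verdict.CONSISTENT
    bad = pfam_verdict([_hit(95), _hit(40, name="PF00002")])
    assert bad.verdict is Verdict.LOSS
    assert any("PF00002" in e for e in bad.evidence)


def test_pfam_exact_70_percent_is_complete():
    assert pfam_verdict([_hit(70)]).verdict is Verdict.CONSISTENT
    assert pfam_verdict([_hit(69)]).verdict is Verdict.LOSS


def test_pfam_evalue_filter():
    assert pfam_verdict([_hit(40, ev=1.0)]).verdict is Verdict.NOT_APPLICABLE
    # threshold is inclusive
    assert pfam_verdict([_hit(40, ev=1e-5)]).verdict is Verdict.LOSS


def test_split_hits_of_one_domain_use_best_coverage():
    # two partial hits of the same HMM: the better one represents the domain
    hits = [_hit(75), _hit(30)]
    assert pfam_verdict(hits).verdict is Verdict.CONSISTENT


def test_pfam_monotone_in_matched_states(rng):
    """Removing matched HMM states never flips loss -> consistent."""
    for _ in range(30):
        length = int(rng.integers(50, 300))
        b = int(rng.integers(1, length + 1))
        full = pfam_verdict([_hit(b, length=length)]).verdict
        shrunk = pfam_verdict([_hit(max(1, b - int(rng.integers(1, 20))), length=length)]).verdict
        if full is Verdict.LOSS:
            assert shrunk is Verdict.LOSS


# ---------------------------------------------------------------------------
# threshold calibration


def test_constant_scores_give_threshold_at_constant():
    assert derive_threshold([0.6, 0.6, 0.6], "lower") == pytest.approx(0.6)
    assert derive_threshold([0.6, 0.6, 0.6], "upper") == pytest.approx(0.6)


def test_threshold_requires_two_scores():
    with pytest.raises(ValueError):
        derive_threshold([0.6], "lower")
    with pytest.raises(ValueError):
        derive_threshold([0.6, 0.7], "sideways")


def test_reference_set_calibration_recovers_operating_point():
    """A N(0.60, 0.03^2) packing-score population at the reference-set size
    puts the lower 2-SD threshold at ~0.54 (within Monte-Carlo error)."""
    rng = np.random.default_rng(4122)
    scores = rng.normal(0.60, 0.03, size=4122)
    thr = derive_threshold(scores, "lower")
    assert thr == pytest.approx(0.54, abs=0.003)


def test_threshold_matches_two_pass_oracle(rng):
    scores = list(rng.normal(25, 3, size=200))
    mean = sum(scores) / len(scores)
    var = sum((s - mean) ** 2 for s in scores) / (len(scores) - 1)
    assert derive_threshold(scores, "lower") == pytest.approx(mean - 2 * math.sqrt(var))
    assert derive_threshold(scores, "upper") == pytest.approx(mean + 2 * math.sqrt(var))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    scores=st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=40),
    shift=st.floats(min_value=-10, max_value=10),
)
def test_threshold_translation_equivariance(scores, shift):
    base = derive_threshold(scores, "lower")
    shifted = derive_threshold([s + shift for s in scores], "lower")
    assert shifted == pytest.approx(base + shift, abs=1e-7)


# ---------------------------------------------------------------------------
# structural plausibility rules


def _assessment(
    deletion_gap_A=None,
    insertion_len=0,
    insertion_flank_sasa=(50.0, 50.0),
    model_os=0.60,
    template_os=0.60,
    model_packeff=28.0,
    template_packeff=28.0,
    coverage=0.95,
):
    """30-residue template; optional deletion at residues 10-11 and optional
    insertion between residues 19 and 20."""
    n = 30
    tgt, tpl = [], []
    for i in range(n):
        if deletion_gap_A is not None and i in (10, 11):
            tgt.append("-")
        else:
            tgt.append("A")
        tpl.append("A")
        if i == 19 and insertion_len:
            tgt.extend("G" * insertion_len)
            tpl.extend("-" * insertion_len)
    coords = np.column_stack((3.8 * np.arange(n), np.zeros(n), np.zeros(n)))
    if deletion_gap_A is not None:
        # flanks of the deletion are residues 9 and 12
        coords[12] = coords[9] + np.array([deletion_gap_A, 0.0, 0.0])
    sasa = np.full(n, 50.0)
    sasa[19], sasa[20] = insertion_flank_sasa
    return StructuralAssessment(
        isoform_id="iso1",
        target_aln="".join(tgt),
        template_aln="".join(tpl),
        template_calpha=coords,
        residue_sasa=sasa,
        model_os=model_os,
        template_os=template_os,
        model_packeff=model_packeff,
        template_packeff=template_packeff,
        model_coverage=coverage,
    )


def test_deletion_with_distant_flanks_fires():
    out = structure_verdict(_assessment(deletion_gap_A=16.0))
    assert out.verdict is Verdict.LOSS
    assert any("deletion" in e for e in out.evidence)
    assert structure_verdict(_assessment(deletion_gap_A=14.0)).verdict is Verdict.CONSISTENT
    # boundary: "larger than 15 A" is strict
    assert structure_verdict(_assessment(deletion_gap_A=15.0)).verdict is Verdict.CONSISTENT


def test_core_insertion_fires():
    out = structure_verdict(_assessment(insertion_len=4, insertion_flank_sasa=(2.0, 3.0)))
    assert out.verdict is Verdict.LOSS
    assert any("insertion" in e for e in out.evidence)
    # three residues are tolerated even in the core
    assert (
        structure_verdict(_assessment(insertion_len=3, insertion_flank_sasa=(2.0, 3.0))).verdict
        is Verdict.CONSISTENT
    )
    # exposed flanks tolerate any length
    assert (
        structure_verdict(_assessment(insertion_len=6, insertion_flank_sasa=(20.0, 3.0))).verdict
        is Verdict.CONSISTENT
    )


def test_packing_rules_require_template_above_threshold():
    assert (
        structure_verdict(_assessment(model_os=0.50, template_os=0.60)).verdict is Verdict.LOSS
    )
    # template also below threshold: rule does not fire
    assert (
        structure_verdict(_assessment(model_os=0.50, template_os=0.50)).verdict
        is Verdict.CONSISTENT
    )
    assert (
        structure_verdict(_assessment(model_packeff=20.0, template_packeff=26.0)).verdict
        is Verdict.LOSS
    )
    assert (
        structure_verdict(_assessment(model_packeff=20.0, template_packeff=20.0)).verdict
        is Verdict.CONSISTENT
    )


def test_low_coverage_is_not_applicable():
    out = structure_verdict(_assessment(coverage=0.85))
    assert out.verdict is Verdict.NOT_APPLICABLE


def test_missing_coordinates_skip_rule_with_warning():
    a = _assessment(deletion_gap_A=16.0)
    a.template_calpha = None
    with pytest.warns(UserWarning):
        out = structure_verdict(a)
    assert out.verdict is Verdict.CONSISTENT


# ---------------------------------------------------------------------------
# solvent accessibility


def test_single_atom_closed_form():
    sasa = compute_sasa(np.array([[0.0, 0.0, 0.0]]), ["C"], [1])
    r = 1.70 + 1.4
    assert sasa[1] == pytest.approx(4 * math.pi * r * r, rel=1e-9)


def test_occlusion_monotonicity():
    lone = compute_sasa(np.array([[0.0, 0.0, 0.0]]), ["C"], [1])[1]
    pair = compute_sasa(
        np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]), ["C", "C"], [1, 2]
    )
    assert pair[1] < lone and pair[2] < lone


def _oracle_sasa(coords, radii, probe, n_theta=240):
    """Dense latitude-band quadrature, independent of the Fibonacci sampler."""
    out = []
    for i, (c, r0) in enumerate(zip(coords, radii)):
        r = r0 + probe
        acc_area = 0.0
        thetas = (np.arange(n_theta) + 0.5) * math.pi / n_theta
        for theta in thetas:
            n_phi = max(8, int(round(2 * n_theta * math.sin(theta))))
            phis = (np.arange(n_phi) + 0.5) * 2 * math.pi / n_phi
            pts = c + r * np.column_stack(
                (
                    np.sin(theta) * np.cos(phis),
                    np.sin(theta) * np.sin(phis),
                    np.full(n_phi, math.cos(theta)),
                )
            )
            free = np.ones(n_phi, dtype=bool)
            for j, (cj, rj) in enumerate(zip(coords, radii)):
                if j == i:
                    continue
                free &= ((pts - cj) ** 2).sum(axis=1) >= (rj + probe) ** 2
            band = 2 * math.pi * r * r * math.sin(theta) * (math.pi / n_theta)
            acc_area += band * free.mean()
        out.append(acc_area)
    return out


def test_sasa_matches_dense_sampling_oracle(rng):
    coords = rng.uniform(0, 4.0, size=(5, 3))
    elements = ["C", "N", "O", "S", "C"]
    radii = [1.70, 1.55, 1.52, 1.80, 1.70]
    got = compute_sasa(coords, elements, list(range(5)), n_points=5000)
    expected = _oracle_sasa(coords, radii, probe=1.4)
    for i in range(5):
        assert got[i] == pytest.approx(expected[i], rel=0.02)


def test_sasa_rejects_empty_input():
    with pytest.raises(ValueError):
        compute_sasa(np.zeros((0, 3)), [], [])


# ---------------------------------------------------------------------------
# active sites


def _site_gene():
    """Three-exon reference; candidate skips the middle exon."""
    ref = make_isoform("ref", "g", [(0, 30), (100, 130), (200, 230)])
    ref.protein_seq = "A" * 30
    cand = make_isoform("cand", "g", [(0, 30), (200, 230)])
    cand.protein_seq = "A" * 20
    return ref, cand


def test_reference_is_reflexively_consistent():
    ref, _ = _site_gene()
    out = active_site_verdict(ref, ref, [5, 15, 25])
    assert out.verdict is Verdict.CONSISTENT


def test_site_in_skipped_exon_is_lost():
    ref, cand = _site_gene()
    # residue 15 sits in the skipped middle exon
    out = active_site_verdict(cand, ref, [15])
    assert out.verdict is Verdict.LOSS
    # residues in retained exons are kept (frames align: exon lengths % 3 == 0)
    assert active_site_verdict(cand, ref, [5, 25]).verdict is Verdict.CONSISTENT


def test_no_sites_is_not_applicable():
    ref, cand = _site_gene()
    assert active_site_verdict(cand, ref, []).verdict is Verdict.NOT_APPLICABLE


def test_site_beyond_reference_length_errors():
    ref, cand = _site_gene()
    with pytest.raises(ValueError):
        active_site_verdict(cand, ref, [31])


def test_retained_codon_shifted_out_of_frame_is_lost():
    # candidate keeps the exon with the site but an upstream exon is 1 nt
    # longer, shifting the shared codons out of frame
    ref = make_isoform("ref", "g", [(0, 30), (100, 130)])
    ref.protein_seq = "A" * 20
    cand = make_isoform("cand", "g", [(0, 31), (99, 130)], protein="A" * 20)
    out = active_site_verdict(cand, ref, [15])
    assert out.verdict is Verdict.LOSS


def test_divergent_tail_site_lost_in_positive():
    """Two isoforms share an N-terminus and then use disjoint exons; a site
    annotated downstream of the divergence on one isoform is absent from
    the other (the descriptor can flag a positive isoform)."""
    unknown_like = make_isoform("u", "g", [(0, 300), (400, 700)], protein="A" * 200)
    positive_like = make_isoform("p", "g", [(0, 300), (800, 1100)], protein="A" * 200)
    out = active_site_verdict(positive_like, unknown_like, [150])
    assert out.verdict is Verdict.LOSS
    # a site in the shared N-terminal portion is retained by both
    assert active_site_verdict(positive_like, unknown_like, [50]).verdict is Verdict.CONSISTENT
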