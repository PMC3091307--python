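"""The three functionality descriptors.

Each descriptor inspects one isoform and returns a tri-state verdict:

* ``consistent`` — the evidence is consistent with a functional product;
* ``loss`` — the evidence suggests loss of function (a truncated domain,
  an implausible homology model, a missing active site);
* ``not_applicable`` — the descriptor's inputs are absent for this isoform
  (no domain hits, no structural model, no annotated sites).

**Domain integrity (Pfam).**  A domain hit is truncated when it covers less
than 70% of the match states of its profile HMM; an isoform carrying at
least one truncated domain (after E-value filtering at 1e-5) is called
``loss``.

**Structural plausibility (St).**  A homology model (coverage >= 90% of the
target) is implausible if any of four rules fires: (R1) a deletion relative
to the template whose flanking template residues are more than 15 A apart
(C-alpha distance); (R2) an insertion of more than three residues between
two buried template residues (solvent accessibility below 5 A^2 each);
(R3) the model's occluded-surface packing score falls below 0.54 while the
template's does not; (R4) the model's packing efficiency falls below 25.9
while the template's does not.  The packing thresholds sit two standard
deviations below the mean of a reference set of high-resolution monomeric
crystal structures; :func:`derive_threshold` reproduces that calibration.

**Active-site retention (AS).**  Catalytic residues annotated on a
reference isoform are mapped through shared genomic codon coordinates; a
site is retained in a candidate isoform only when its codon's genomic
footprint is fully present in the candidate's CDS *and* in frame (a codon
shifted out of frame destroys the residue and counts as lost).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .gene_models import Isoform, cds_offset_map, genomic_codon_positions

AS_SITES = "AS_sites"
STRUCTURE = "Structure"
PFAM = "Pfam"
DESCRIPTOR_NAMES = (AS_SITES, STRUCTURE, PFAM)


class Verdict(str, Enum):
    CONSISTENT = "consistent"
    LOSS = "loss"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class Thresholds:
    """Operating points of the three descriptors.

    ``pops_value`` (25.5) is the calibrated operating point of the
    solvent-accessibility tool on the reference structure set; it is kept
    for completeness but is not wired to any rule — the insertion rule uses
    the 5 A^2 per-residue burial criterion (``core_sasa_max_A2``).
    """

    hmm_coverage_min: float = 0.70
    evalue_max: float = 1e-5
    deletion_gap_max_A: float = 15.0
    insertion_core_len: int = 3
    core_sasa_max_A2: float = 5.0
    os_min: float = 0.54
    packeff_min: float = 25.9
    model_coverage_min: float = 0.90
    sd_multiplier: float = 2.0
    pops_value: float = 25.5  # unused by the rules; see docstring


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit on an isoform (1-based coordinates)."""

    isoform_id: str
    hmm_name: str
    hmm_length: int
    hmm_from: int
    hmm_to: int
    seq_from: int
    seq_to: int
    evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"malformed HMM coordinates {self.hmm_from}-{self.hmm_to}"
                f"/{self.hmm_length} for {self.hmm_name}"
            )
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class StructuralAssessment:
    """Inputs to the structural plausibility rules for one isoform.

    ``target_aln``/``template_aln`` are the gapped rows of the pairwise
    target-template alignment.  ``template_calpha`` holds one C-alpha
    coordinate per *template* residue (template numbering, 0-based row
    index) and ``residue_sasa`` one solvent-accessible surface value per
    template residue.  Packing scores are per structure.
    """

    isoform_id: str
    target_aln: str
    template_aln: str
    template_calpha: Optional[np.ndarray] = None  # (n_template_residues, 3)
    residue_sasa: Optional[np.ndarray] = None  # (n_template_residues,)
    model_os: Optional[float] = None
    template_os: Optional[float] = None
    model_packeff: Optional[float] = None
    template_packeff: Optional[float] = None
    model_coverage: float = 1.0

    def __post_init__(self) -> None:
        if len(self.target_aln) != len(self.template_aln):
            raise ValueError("alignment rows differ in length")
        if not (0.0 <= self.model_coverage <= 1.0):
            raise ValueError("model_coverage must be in [0, 1]")


@dataclass
class DescriptorOutcome:
    isoform_id: str
    descriptor: str  # AS_sites | Structure | Pfam
    verdict: Verdict
    evidence: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class ActiveSiteAnnotation:
    """Catalytic residues annotated on a reference isoform of a gene."""

    gene_id: str
    reference_isoform_id: str
    sites: Tuple[int, ...]


# ---------------------------------------------------------------------------
# domain integrity


def domain_coverage(hit: DomainHit) -> float:
    """Fraction of the profile HMM's match states covered by a hit."""
    return (hit.hmm_to - hit.hmm_from + 1) / hit.hmm_length


def pfam_verdict(
    hits: Sequence[DomainHit], thresholds: Thresholds = Thresholds()
) -> DescriptorOutcome:
    """Domain-integrity verdict for one isoform.

    Hits are filtered at ``evalue_max`` and grouped by HMM name; each
    domain is represented by its best (maximum) single-hit coverage, so a
    domain split over several hits is not chained into a spuriously
    complete one.  The isoform is ``loss`` when any domain's coverage is
    strictly below ``hmm_coverage_min`` and ``not_applicable`` when no hit
    survives the E-value filter.
    """
    kept = [h for h in hits if h.evalue <= thresholds.evalue_max]
    if not kept:
        iso = hits[0].isoform_id if hits else ""
        return DescriptorOutcome(iso, PFAM, Verdict.NOT_APPLICABLE)
    iso = kept[0].isoform_id
    best: Dict[str, float] = {}
    for h in kept:
        c = domain_coverage(h)
        best[h.hmm_name] = max(best.get(h.hmm_name, 0.0), c)
    truncated = {name: c for name, c in sorted(best.items()) if c < thresholds.hmm_coverage_min}
    if truncated:
        evidence = [f"truncated domain {name}: coverage {c:.3f}" for name, c in truncated.items()]
        return DescriptorOutcome(iso, PFAM, Verdict.LOSS, evidence)
    return DescriptorOutcome(iso, PFAM, Verdict.CONSISTENT)


# ---------------------------------------------------------------------------
# threshold calibration


def derive_threshold(scores: Sequence[float], direction: str, sd_multiplier: float = 2.0) -> float:
    """Mean +/- ``sd_multiplier`` sample standard deviations of a score set.

    ``direction='lower'`` returns mean - k*SD (scores where low values are
    suspicious, e.g. packing); ``'upper'`` returns mean + k*SD.
    """
    if len(scores) < 2:
        raise ValueError("threshold calibration needs at least 2 scores")
    if direction not in ("lower", "upper"):
        raise ValueError("direction must be 'lower' or 'upper'")
    arr = np.asarray(scores, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return mean - sd_multiplier * sd if direction == "lower" else mean + sd_multiplier * sd


# ---------------------------------------------------------------------------
# structural plausibility


def _gap_runs(row: str) -> List[Tuple[int, int]]:
    """Half-open column spans of '-' runs."""
    return [(m.start(), m.end()) for m in re.finditer(r"-+", row)]


def _template_residue_index(template_aln: str) -> List[Optional[int]]:
    idx: List[Optional[int]] = []
    k = 0
    for c in template_aln:
        if c == "-":
            idx.append(None)
        else:
            idx.append(k)
            k += 1
    return idx


def structure_verdict(
    a: StructuralAssessment, thresholds: Thresholds = Thresholds()
) -> DescriptorOutcome:
    """Apply the four structural plausibility rules to one model.

    Models covering less than ``model_coverage_min`` of the target are
    ``not_applicable``.  A rule whose inputs are missing (no coordinates
    for a flanking residue, no packing score) is skipped with a warning;
    the verdict is ``loss`` when any evaluable rule fires, listing every
    fired rule as evidence.
    """
    if a.model_coverage < thresholds.model_coverage_min:
        return DescriptorOutcome(
            a.isoform_id,
            STRUCTURE,
            Verdict.NOT_APPLICABLE,
            [f"model coverage {a.model_coverage:.2f} below {thresholds.model_coverage_min:.2f}"],
        )
    evidence: List[str] = []
    tgt, tpl = a.target_aln, a.template_aln
    tpl_idx = _template_residue_index(tpl)

    # R1: deletions (gap in the target row) with distant template flanks
    for start, end in _gap_runs(tgt):
        if all(tpl[c] == "-" for c in range(start, end)):
            continue  # opposing gaps, not a deletion
        left = _nearest_paired_residue(tgt, tpl_idx, start - 1, -1)
        right = _nearest_paired_residue(tgt, tpl_idx, end, +1)
        if left is None or right is None:
            warnings.warn(
                f"{a.isoform_id}: deletion at columns {start}-{end} lacks a flanking "
                "aligned residue; deletion rule skipped for this gap"
            )
            continue
        dist = _calpha_distance(a, left, right)
        if dist is None:
            warnings.warn(
                f"{a.isoform_id}: missing C-alpha coordinates for deletion flanks "
                f"{left}/{right}; deletion rule skipped"
            )
            continue
        if dist > thresholds.deletion_gap_max_A:
            evidence.append(
                f"deletion at columns {start}-{end}: flank C-alpha distance "
                f"{dist:.1f} A > {thresholds.deletion_gap_max_A:.0f} A"
            )

    # R2: long insertions (gap in the template row) between buried residues
    for start, end in _gap_runs(tpl):
        ins_len = sum(1 for c in range(start, end) if tgt[c] != "-")
        if ins_len <= thresholds.insertion_core_len:
            continue
        left = _nearest_template_residue(tpl_idx, start - 1, -1)
        right = _nearest_template_residue(tpl_idx, end, +1)
        if left is None or right is None:
            warnings.warn(
                f"{a.isoform_id}: insertion at columns {start}-{end} lacks a flanking "
                "template residue; insertion rule skipped for this gap"
            )
            continue
        sasa = _flank_sasa(a, left, right)
        if sasa is None:
            warnings.warn(
                f"{a.isoform_id}: missing SASA for insertion flanks {left}/{right}; "
                "insertion rule skipped"
            )
            continue
        if sasa[0] < thresholds.core_sasa_max_A2 and sasa[1] < thresholds.core_sasa_max_A2:
            evidence.append(
                f"insertion of {ins_len} residues at columns {start}-{end} in the core "
                f"(flank SASA {sasa[0]:.1f}/{sasa[1]:.1f} A^2 < {thresholds.core_sasa_max_A2:.0f})"
            )

    # R3: occluded-surface packing below threshold while the template is not
    if a.model_os is not None and a.template_os is not None:
        if a.model_os < thresholds.os_min <= a.template_os:
            evidence.append(
                f"model OS {a.model_os:.2f} < {thresholds.os_min} while template OS "
                f"{a.template_os:.2f} is not"
            )

    # R4: packing efficiency below threshold while the template is not
    if a.model_packeff is not None and a.template_packeff is not None:
        if a.model_packeff < thresholds.packeff_min <= a.template_packeff:
            evidence.append(
                f"model packing-eff {a.model_packeff:.1f} < {thresholds.packeff_min} "
                f"while template packing-eff {a.template_packeff:.1f} is not"
            )

    verdict = Verdict.LOSS if evidence else Verdict.CONSISTENT
    return DescriptorOutcome(a.isoform_id, STRUCTURE, verdict, evidence)


def _nearest_paired_residue(
    tgt: str, tpl_idx: List[Optional[int]], col: int, step: int
) -> Optional[int]:
    """Template residue index at the nearest column aligned in both rows."""
    while 0 <= col < len(tgt):
        if tgt[col] != "-" and tpl_idx[col] is not None:
            return tpl_idx[col]
        col += step
    return None


def _nearest_template_residue(
    tpl_idx: List[Optional[int]], col: int, step: int
) -> Optional[int]:
    while 0 <= col < len(tpl_idx):
        if tpl_idx[col] is not None:
            return tpl_idx[col]
        col += step
    return None


def _calpha_distance(a: StructuralAssessment, i: int, j: int) -> Optional[float]:
    if a.template_calpha is None:
        return None
    coords = np.asarray(a.template_calpha, dtype=float)
    if i >= len(coords) or j >= len(coords):
        return None
    if np.isnan(coords[i]).any() or np.isnan(coords[j]).any():
        return None
    return float(np.linalg.norm(coords[i] - coords[j]))


def _flank_sasa(a: StructuralAssessment, i: int, j: int) -> Optional[Tuple[float, float]]:
    if a.residue_sasa is None:
        return None
    sasa = np.asarray(a.residue_sasa, dtype=float)
    if i >= len(sasa) or j >= len(sasa) or math.isnan(sasa[i]) or math.isnan(sasa[j]):
        return None
    return float(sasa[i]), float(sasa[j])


# ---------------------------------------------------------------------------
# solvent accessibility (used only when SASA is not supplied externally)

#: Van der Waals radii (A) by element; unknown elements fall back to carbon.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * i
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def compute_sasa(
    coords: np.ndarray,
    elements: Sequence[str],
    residue_ids: Sequence[int],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> Dict[int, float]:
    """Shrake-Rupley-style per-residue solvent-accessible surface (A^2).

    Each heavy (or hydrogen) atom is expanded by the probe radius and
    sampled with a deterministic Fibonacci point set; points falling inside
    any neighbouring expanded sphere are occluded.  Per-atom areas are
    summed per residue id.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    if len(elements) != len(coords) or len(residue_ids) != len(coords):
        raise ValueError("elements/residue_ids must match coords")
    radii = np.array(
        [VDW_RADII.get(str(e).upper(), DEFAULT_VDW_RADIUS) for e in elements]
    ) + probe_radius
    unit = _fibonacci_sphere(n_points)

    out: Dict[int, float] = {}
    for i in range(len(coords)):
        # neighbours whose expanded spheres can intersect this one
        d = np.linalg.norm(coords - coords[i], axis=1)
        nb = np.where((d < radii + radii[i]) & (np.arange(len(coords)) != i))[0]
        pts = coords[i] + radii[i] * unit
        if len(nb):
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        area = 4.0 * math.pi * radii[i] ** 2 * accessible / n_points
        rid = int(residue_ids[i])
        out[rid] = out.get(rid, 0.0) + area
    return out


# ---------------------------------------------------------------------------
# active-site retention


def active_site_verdict(
    candidate: Isoform,
    reference: Isoform,
    sites: Sequence[int],
) -> DescriptorOutcome:
    """Check retention of reference-annotated catalytic residues.

    Sites are 1-based residue positions on the reference protein; both
    isoforms must come from the same gene.  A site is retained when the
    genomic footprint of its codon is fully present in the candidate's CDS,
    contiguous in the candidate's spliced coordinates, and in frame.
    """
    if not sites:
        return DescriptorOutcome(candidate.isoform_id, AS_SITES, Verdict.NOT_APPLICABLE)
    if candidate.gene_id != reference.gene_id:
        raise ValueError("candidate and reference must belong to the same gene")
    n_ref = reference.n_residues
    cand_offsets = cds_offset_map(candidate)
    lost: List[int] = []
    for site in sorted(sites):
        if not (1 <= site <= n_ref):
            raise ValueError(
                f"site {site} beyond reference protein length {n_ref} "
                f"({reference.isoform_id})"
            )
        positions = genomic_codon_positions(reference, site)
        offs = [cand_offsets.get(p) for p in positions]
        retained = (
            None not in offs
            and offs[1] == offs[0] + 1
            and offs[2] == offs[0] + 2
            and offs[0] % 3 == 0
        )
        if not retained:
            lost.append(site)
    if lost:
        evidence = [f"site {s} lost (codon absent or out of frame)" for s in lost]
        return DescriptorOutcome(candidate.isoform_id, AS_SITES, Verdict.LOSS, evidence)
    return DescriptorOutcome(candidate.isoform_id, AS_SITES, Verdict.CONSISTENT)


def active_site_outcome(
    isoform: Isoform,
    gene_isoforms: Mapping[str, Isoform],
    annotations: Sequence[ActiveSiteAnnotation],
) -> DescriptorOutcome:
    """Aggregate the active-site verdict over all annotation rows of a gene.

    Each row carries its own reference isoform; the isoform under
    evaluation is ``loss`` if any annotated site of its gene is lost and
    ``not_applicable`` when no row annotates the gene.
    """
    rows = [r for r in annotations if r.gene_id == isoform.gene_id]
    if not rows:
        return DescriptorOutcome(isoform.isoform_id, AS_SITES, Verdict.NOT_APPLICABLE)
    evidence: List[str] = []
    any_loss = False
    for row in rows:
        ref = gene_isoforms[row.reference_isoform_id]
        res = active_site_verdict(isoform, ref, row.sites)
        if res.verdict is Verdict.LOSS:
            any_loss = True
            evidence.extend(f"ref {row.reference_isoform_id}: {e}" for e in res.evidence)
    verdict = Verdict.LOSS if any_loss else Verdict.CONSISTENT
    return DescriptorOutcome(isoform.isoform_id, AS_SITES, verdict, evidence)
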