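"""Peptide-to-isoform mapping, specificity calls and MS detectability.

Peptides (observed in an MS experiment or generated in silico) are located
in isoform proteins by exact substring match, projected onto the genome
through the isoform's CDS exons, and called *specific* when the footprint
lies entirely within regions owned by exactly one isoform.  Isoforms with
specific regions but no observed specific peptide can still be judged
*detectable* if at least one tryptic peptide from those regions scores at
or above the detectability threshold (default 0.5) under a pluggable
peptide-observability scorer.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

from pyteomics import parser as _parser

from .gene_models import (
    GeneModel,
    GenomicInterval,
    Isoform,
    RegionClassification,
    intervals_contain,
    merge_intervals,
    protein_to_genome,
)

#: Cleave C-terminal to K or R, except when the next residue is proline.
TRYPTIC_RULE = r"[KR](?!P)"

#: Observed tryptic peptides are expected in this length range.
PEPTIDE_LENGTH_RANGE = (7, 66)

#: Default decision threshold on detectability scores.
DETECTABILITY_THRESHOLD = 0.5

Scorer = Callable[[str], float]


@dataclass(frozen=True)
class Peptide:
    sequence: str
    source: str = "observed"  # or "in_silico"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if not self.sequence.isupper() or not self.sequence.isalpha():
            raise ValueError(f"peptide must be uppercase amino acids: {self.sequence!r}")


@dataclass(frozen=True)
class DigestedPeptide:
    """A tryptic peptide with its 0-based start position in the protein."""

    sequence: str
    start: int

    @property
    def aa_start(self) -> int:
        return self.start + 1

    @property
    def aa_end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class PeptideMatch:
    peptide: str
    isoform_id: str
    aa_start: int
    aa_end: int
    footprint: List[GenomicInterval]
    exon_spanning: bool
    specificity: str  # "specific" | "unspecific"


@dataclass
class DetectabilityResult:
    isoform_id: str
    best_score: float
    detectable: bool
    applicable: bool = True  # False when the isoform has no specific regions


def digest(protein: str, missed_cleavages: int = 0) -> List[DigestedPeptide]:
    """In silico tryptic digestion.

    Cleaves C-terminal to K/R except before P, producing all products with
    up to ``missed_cleavages`` internal cleavage sites, deduplicated by
    (sequence, position).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not protein:
        return []
    seen = set()
    out: List[DigestedPeptide] = []
    for pos, seq in _parser.icleave(
        protein, TRYPTIC_RULE, missed_cleavages=missed_cleavages
    ):
        key = (pos, seq)
        if seq and key not in seen:
            seen.add(key)
            out.append(DigestedPeptide(seq, pos))
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def map_peptide(
    peptide: Union[str, Peptide],
    gene: GeneModel,
    regions: RegionClassification,
) -> List[PeptideMatch]:
    """Locate all occurrences of a peptide in the proteins of a gene.

    Each occurrence is projected onto the genome; ``exon_spanning`` is true
    when the footprint covers more than one CDS exon.  The occurrence is
    *specific* when its footprint lies entirely within regions owned by the
    matched isoform alone (whole specific exons or the private parts of
    partially overlapping exons); otherwise it is *unspecific*.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    matches: List[PeptideMatch] = []
    for iso in gene.isoforms:
        prot = iso.protein_seq
        if not prot:
            continue
        own_specific = merge_intervals(regions.specific_intervals(iso.isoform_id))
        i = prot.find(seq)
        while i != -1:
            aa_start, aa_end = i + 1, i + len(seq)
            footprint = protein_to_genome(iso, aa_start, aa_end)
            specific = bool(own_specific) and intervals_contain(own_specific, footprint)
            matches.append(
                PeptideMatch(
                    peptide=seq,
                    isoform_id=iso.isoform_id,
                    aa_start=aa_start,
                    aa_end=aa_end,
                    footprint=footprint,
                    exon_spanning=len(footprint) > 1,
                    specificity="specific" if specific else "unspecific",
                )
            )
            i = prot.find(seq, i + 1)
    return matches


def identify_isoforms(
    gene: GeneModel,
    observed: Iterable[Union[str, Peptide]],
    regions: RegionClassification,
    min_specific_peptides: int = 1,
) -> Set[str]:
    """Isoforms identified by at least ``min_specific_peptides`` specific peptides.

    Exon-spanning matches are discarded (the peptide evidence used here is
    restricted to non-exon-spanning peptides); a peptide occurring more than
    once within one isoform counts once.
    """
    per_iso: Dict[str, Set[str]] = defaultdict(set)
    for pep in observed:
        for m in map_peptide(pep, gene, regions):
            if not m.exon_spanning and m.specificity == "specific":
                per_iso[m.isoform_id].add(m.peptide)
    return {iso for iso, peps in per_iso.items() if len(peps) >= min_specific_peptides}


#: Residues counted as hydrophobic by the bundled stand-in scorer.
_HYDROPHOBIC = frozenset("AVILMFWYC")


def default_scorer(sequence: str) -> float:
    """Bundled peptide-observability stand-in.

    Scores 0 for peptides outside the expected 7-66 residue range and
    otherwise a fixed logistic of length and hydrophobic fraction.  This is
    a documented stand-in for a proteotypicity classifier; externally
    computed per-peptide scores can be supplied via :func:`table_scorer`.
    """
    n = len(sequence)
    lo, hi = PEPTIDE_LENGTH_RANGE
    if n < lo or n > hi:
        return 0.0
    hyd = sum(c in _HYDROPHOBIC for c in sequence) / n
    z = 0.25 * (n - 12) + 4.0 * (hyd - 0.4)
    return 1.0 / (1.0 + math.exp(-z))


def table_scorer(scores: Mapping[str, float], default: float = 0.0) -> Scorer:
    """Scorer backed by an external per-peptide score table."""

    def score(sequence: str) -> float:
        return float(scores.get(sequence, default))

    return score


def detectability(
    isoform: Isoform,
    regions: RegionClassification,
    scorer: Optional[Scorer] = None,
    threshold: float = DETECTABILITY_THRESHOLD,
    missed_cleavages: int = 0,
) -> DetectabilityResult:
    """Decide whether an isoform is detectable through its specific regions.

    The isoform is digested in silico; tryptic peptides whose genomic
    footprint lies wholly within the isoform's specific regions are scored,
    and the isoform is detectable when the best score is at least the
    threshold (boundary inclusive).  Isoforms without specific regions are
    flagged not applicable.
    """
    scorer = scorer or default_scorer
    specific = merge_intervals(regions.specific_intervals(isoform.isoform_id))
    if not specific:
        return DetectabilityResult(isoform.isoform_id, 0.0, False, applicable=False)
    best = 0.0
    for dp in digest(isoform.protein_seq, missed_cleavages=missed_cleavages):
        footprint = protein_to_genome(isoform, dp.aa_start, dp.aa_end)
        if intervals_contain(specific, footprint):
            best = max(best, float(scorer(dp.sequence)))
    return DetectabilityResult(isoform.isoform_id, best, best >= threshold)
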