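"""Construction of the four evaluation datasets and expression summaries.

Datasets:

* **ASPos** — alternatively spliced isoforms unambiguously identified by at
  least one specific peptide (per gene, the shortest identified candidate).
* **unknown** — isoforms of the same genes with specific regions but no
  specific peptide, predicted detectable by the peptide-observability
  scorer (per gene, the longest such candidate).
* **noASPos** — products of single-isoform genes identified by at least one
  peptide.
* **negative** — ORFs translated from non-coding transcripts, starting at
  the first AUG and running to the first stop, at least ``min_orf_len``
  residues long (the longest ``n`` are kept).

Only genes contributing both an ASPos and an unknown member enter the
paired positive/comparison analysis; all other isoforms are recorded as
excluded with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .gene_models import (
    GeneModel,
    GenomicInterval,
    Isoform,
    RegionClassification,
    merge_intervals,
)
from .peptide_mapping import DetectabilityResult

DEFAULT_MIN_ORF_LEN = 100
DEFAULT_NEGATIVE_SIZE = 555

ASPOS = "ASPos"
UNKNOWN = "unknown"
NOASPOS = "noASPos"
NEGATIVE = "negative"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class DatasetAssignment:
    isoform_id: str
    gene_id: str
    dataset: str
    reason: str
    length_aa: int


@dataclass(frozen=True)
class NegativeORF:
    transcript_id: str
    protein_seq: str

    @property
    def length_aa(self) -> int:
        return len(self.protein_seq)


@dataclass
class ExpressionSummary:
    isoform_id: str
    probe_set_medians: List[float]
    isoform_expression: Optional[float]  # None when no probe set falls inside

    @property
    def defined(self) -> bool:
        return self.isoform_expression is not None


def assign_datasets(
    genes: Sequence[GeneModel],
    identified: Set[str],
    detect: Mapping[str, DetectabilityResult],
    peptide_matched: Set[str],
) -> List[DatasetAssignment]:
    """Assign every isoform to ASPos / unknown / noASPos / excluded.

    ``identified`` holds isoforms with at least the required number of
    specific peptide matches; ``detect`` the detectability decisions for
    alternatively spliced isoforms; ``peptide_matched`` the isoforms with at
    least one peptide match of any specificity (used for single-isoform
    genes).  Per gene, the shortest identified candidate becomes the ASPos
    member and the longest detectable unidentified candidate the unknown
    member; genes lacking either candidate contribute nothing to the paired
    analysis.  Ties on protein length break by lexicographic isoform id.
    """
    out: List[DatasetAssignment] = []
    for gene in genes:
        if len(gene.isoforms) == 1:
            iso = gene.isoforms[0]
            if iso.isoform_id in peptide_matched:
                out.append(
                    _assign(iso, NOASPOS, "single-isoform gene with peptide evidence")
                )
            else:
                out.append(_assign(iso, EXCLUDED, "single-isoform gene, no peptide"))
            continue

        aspos_cands = [i for i in gene.isoforms if i.isoform_id in identified]
        unk_cands = [
            i
            for i in gene.isoforms
            if i.isoform_id not in identified
            and (d := detect.get(i.isoform_id)) is not None
            and d.applicable
            and d.detectable
        ]
        if aspos_cands and unk_cands:
            aspos = min(aspos_cands, key=lambda i: (i.n_residues, i.isoform_id))
            unknown = min(unk_cands, key=lambda i: (-i.n_residues, i.isoform_id))
            for iso in gene.isoforms:
                if iso.isoform_id == aspos.isoform_id:
                    out.append(_assign(iso, ASPOS, "shortest identified candidate"))
                elif iso.isoform_id == unknown.isoform_id:
                    out.append(
                        _assign(iso, UNKNOWN, "longest detectable unidentified candidate")
                    )
                elif iso.isoform_id in identified:
                    out.append(_assign(iso, EXCLUDED, "identified but not shortest"))
                else:
                    out.append(_assign(iso, EXCLUDED, "not selected for the pair"))
        else:
            missing = "no identified isoform" if not aspos_cands else "no unknown candidate"
            for iso in gene.isoforms:
                out.append(_assign(iso, EXCLUDED, f"unpaired gene ({missing})"))
    return out


def _assign(iso: Isoform, dataset: str, reason: str) -> DatasetAssignment:
    return DatasetAssignment(iso.isoform_id, iso.gene_id, dataset, reason, iso.n_residues)


def members(assignments: Iterable[DatasetAssignment], dataset: str) -> List[str]:
    return [a.isoform_id for a in assignments if a.dataset == dataset]


def build_negative(
    noncoding_transcripts: Sequence[Tuple[str, str]],
    n: int = DEFAULT_NEGATIVE_SIZE,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
) -> List[NegativeORF]:
    """Translate non-coding transcripts into the negative ORF set.

    For each transcript the first AUG is located and translation proceeds
    to the first stop codon (or the transcript end).  ORFs shorter than
    ``min_orf_len`` residues are discarded; the longest ``n`` survivors are
    returned (ties by transcript id).
    """
    orfs: List[NegativeORF] = []
    for transcript_id, seq in noncoding_transcripts:
        rna = seq.upper().replace("U", "T")
        start = rna.find("ATG")
        if start == -1:
            continue
        sub = rna[start:]
        sub = sub[: len(sub) - len(sub) % 3]
        protein = str(Seq(sub).translate(to_stop=True))
        if len(protein) >= min_orf_len:
            orfs.append(NegativeORF(transcript_id, protein))
    orfs.sort(key=lambda o: (-o.length_aa, o.transcript_id))
    return orfs[:n]


def summarize_expression(
    isoform: Isoform,
    regions: RegionClassification,
    probe_sets: Sequence[Tuple[GenomicInterval, Sequence[float]]],
) -> ExpressionSummary:
    """Median-of-medians expression over probe sets in specific regions.

    Each probe set's expression is the median of its per-tissue values;
    probe sets whose genomic interval lies wholly within the isoform's
    specific regions are selected, and the isoform expression is the median
    of their medians (even counts take the midpoint of the central pair).
    Probe sets partially overlapping a specific-region boundary are
    excluded.
    """
    specific = merge_intervals(regions.specific_intervals(isoform.isoform_id))
    selected: List[float] = []
    for interval, values in probe_sets:
        if not values:
            raise ValueError("probe set without tissue values")
        if any(c.contains(interval) for c in specific):
            selected.append(float(median(values)))
    expression = float(median(selected)) if selected else None
    return ExpressionSummary(isoform.isoform_id, selected, expression)
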