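"""End-to-end orchestration: cohort in, metric tables out.

A :class:`Cohort` bundles everything the analysis consumes: gene models
with their genome sequence, observed peptides, per-isoform domain hit
tables, structural assessments, active-site annotations, non-coding
transcripts for the negative set and an exon-level expression panel.
:func:`run_pipeline` then

1. collapses isoforms differing only in their UTRs,
2. computes isoform-specific regions per multi-isoform gene,
3. maps observed peptides, identifies isoforms by specific peptides and
   scores detectability of the unidentified candidates,
4. assigns the ASPos / unknown / noASPos datasets and translates the
   negative ORF set,
5. evaluates the three descriptors on every dataset member,
6. counts confusion matrices for every descriptor combination against the
   unknown and the negative comparison sets, and summarizes isoform
   expression.

Peptide lookup assumes fully tryptic observed peptides: each isoform is
digested in silico and its peptides intersected with the observed set,
after which full substring/projection semantics are applied per gene via
:func:`isofunc.peptide_mapping.map_peptide`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .config import PipelineConfig
from .dataset_builder import (
    ASPOS,
    NOASPOS,
    UNKNOWN,
    DatasetAssignment,
    ExpressionSummary,
    NegativeORF,
    assign_datasets,
    build_negative,
    members,
    summarize_expression,
)
from .descriptors import (
    AS_SITES,
    PFAM,
    STRUCTURE,
    ActiveSiteAnnotation,
    DescriptorOutcome,
    DomainHit,
    StructuralAssessment,
    Verdict,
    active_site_outcome,
    pfam_verdict,
    structure_verdict,
)
from .evaluation import (
    CombinationSpec,
    ConfusionCounts,
    evaluate_combinations,
    metrics_table,
    standard_combinations,
)
from .gene_models import (
    GeneModel,
    GenomicInterval,
    Isoform,
    RegionClassification,
    collapse_utr_duplicates,
    find_specific_regions,
)
from .peptide_mapping import (
    DetectabilityResult,
    Peptide,
    Scorer,
    default_scorer,
    detectability,
    digest,
    identify_isoforms,
)


@dataclass
class Cohort:
    """All inputs of one analysis run."""

    genes: List[GeneModel]
    genome: Dict[str, str]
    observed_peptides: List[Peptide] = field(default_factory=list)
    domain_hits: Dict[str, List[DomainHit]] = field(default_factory=dict)
    structures: Dict[str, StructuralAssessment] = field(default_factory=dict)
    active_sites: List[ActiveSiteAnnotation] = field(default_factory=list)
    noncoding_transcripts: List[Tuple[str, str]] = field(default_factory=list)
    expression_probes: List[Tuple[GenomicInterval, List[float]]] = field(
        default_factory=list
    )
    peptide_scores: Dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineResult:
    assignments: List[DatasetAssignment]
    identified: Set[str]
    detect: Dict[str, DetectabilityResult]
    regions: Dict[str, RegionClassification]
    negatives: List[NegativeORF]
    outcomes: Dict[str, Dict[str, Verdict]]
    counts_unknown: Dict[str, ConfusionCounts]
    counts_negative: Dict[str, ConfusionCounts]
    expression: List[ExpressionSummary]

    @property
    def unknown_table(self) -> pd.DataFrame:
        return metrics_table(self.counts_unknown)

    @property
    def negative_table(self) -> pd.DataFrame:
        return metrics_table(self.counts_negative)

    def dataset_members(self, dataset: str) -> List[str]:
        return members(self.assignments, dataset)


def descriptor_outcomes(
    isoform_ids: Sequence[str],
    cohort: Cohort,
    cfg: PipelineConfig,
    gene_of: Optional[Mapping[str, GeneModel]] = None,
) -> Dict[str, Dict[str, Verdict]]:
    """Tri-state verdicts of the three descriptors for the given ids.

    ``gene_of`` maps isoform id to its gene model for the active-site
    descriptor; ids without a gene (negative ORFs) are not applicable
    there.
    """
    iso_index: Dict[str, Isoform] = {}
    if gene_of:
        for gene in gene_of.values():
            for iso in gene.isoforms:
                iso_index.setdefault(iso.isoform_id, iso)
    out: Dict[str, Dict[str, Verdict]] = {}
    for iso_id in isoform_ids:
        per: Dict[str, Verdict] = {}
        per[PFAM] = pfam_verdict(
            cohort.domain_hits.get(iso_id, []), cfg.thresholds
        ).verdict
        sa = cohort.structures.get(iso_id)
        per[STRUCTURE] = (
            structure_verdict(sa, cfg.thresholds).verdict
            if sa is not None
            else Verdict.NOT_APPLICABLE
        )
        if gene_of and iso_id in gene_of:
            per[AS_SITES] = active_site_outcome(
                iso_index[iso_id], iso_index, cohort.active_sites
            ).verdict
        else:
            per[AS_SITES] = Verdict.NOT_APPLICABLE
        out[iso_id] = per
    return out


def run_pipeline(
    cohort: Cohort,
    cfg: Optional[PipelineConfig] = None,
    scorer: Optional[Scorer] = None,
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    if scorer is None:
        if cohort.peptide_scores:
            from .peptide_mapping import table_scorer

            scorer = table_scorer(cohort.peptide_scores)
        else:
            scorer = default_scorer

    genes = [collapse_utr_duplicates(g) for g in cohort.genes]
    observed_seqs = {p.sequence for p in cohort.observed_peptides}

    regions: Dict[str, RegionClassification] = {}
    identified: Set[str] = set()
    detect: Dict[str, DetectabilityResult] = {}
    peptide_matched: Set[str] = set()

    for gene in genes:
        # observed peptides attributable to this gene (tryptic lookup)
        candidates: Set[str] = set()
        for iso in gene.isoforms:
            for dp in digest(iso.protein_seq, cfg.missed_cleavages):
                if dp.sequence in observed_seqs:
                    candidates.add(dp.sequence)
                    peptide_matched.add(iso.isoform_id)
        if len(gene.isoforms) < 2:
            continue
        reg = find_specific_regions(gene)
        regions[gene.gene_id] = reg
        identified |= identify_isoforms(
            gene, sorted(candidates), reg, cfg.min_specific_peptides
        )
        for iso in gene.isoforms:
            if iso.isoform_id not in identified:
                detect[iso.isoform_id] = detectability(
                    iso,
                    reg,
                    scorer,
                    cfg.detectability_threshold,
                    cfg.missed_cleavages,
                )

    assignments = assign_datasets(genes, identified, detect, peptide_matched)
    negatives = build_negative(
        cohort.noncoding_transcripts, cfg.n_negative, cfg.min_orf_len
    )

    gene_of: Dict[str, GeneModel] = {
        iso.isoform_id: gene for gene in genes for iso in gene.isoforms
    }
    aspos = members(assignments, ASPOS)
    unknown = members(assignments, UNKNOWN)
    noaspos = members(assignments, NOASPOS)
    negative_ids = [o.transcript_id for o in negatives]

    outcomes = descriptor_outcomes(
        aspos + unknown + noaspos, cohort, cfg, gene_of
    )
    outcomes.update(descriptor_outcomes(negative_ids, cohort, cfg, gene_of=None))

    pos_out = {i: outcomes[i] for i in aspos}
    unk_out = {i: outcomes[i] for i in unknown}
    neg_out = {i: outcomes[i] for i in negative_ids}

    counts_unknown = evaluate_combinations(pos_out, unk_out)
    # the negative set carries no site annotations: report St/Pfam combinations
    neg_specs: List[CombinationSpec] = standard_combinations((STRUCTURE, PFAM))
    counts_negative = evaluate_combinations(pos_out, neg_out, neg_specs)

    expression: List[ExpressionSummary] = []
    for iso_id in aspos + unknown:
        gene = gene_of[iso_id]
        summary = summarize_expression(
            gene.isoform(iso_id), regions[gene.gene_id], cohort.expression_probes
        )
        if summary.defined:
            expression.append(summary)

    return PipelineResult(
        assignments=assignments,
        identified=identified,
        detect=detect,
        regions=regions,
        negatives=negatives,
        outcomes=outcomes,
        counts_unknown=counts_unknown,
        counts_negative=counts_negative,
        expression=expression,
    )
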