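"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure of the real analysis
without any downloads: multi-isoform genes with constitutive,
semi-constitutive, specific and partially overlapping exons; tryptic
peptide observation with configurable sampling depth; domain placements
that are intact or splice-truncated; structural score distributions for
plausible and implausible homology models; active sites retained or lost
by splicing; non-coding transcripts carrying ORFs for the negative set;
and an exon-array-style expression panel whose unknown-isoform
distribution sits lower than the positive ones.

Gene geometry keeps every exon length a multiple of three, so any exon
subset stays in frame and codons never straddle junctions; frameshift
cases are exercised by hand-built fixtures in the test-suite instead.
Each *pair gene* contributes one MS-identified isoform (all exons except
one) and one undetected partner (all exons except another), so each has a
private exon and hence a specific region.  Optionally a third isoform
(creating semi-constitutive exons) and a 3'-extended exon copy (creating
partially overlapping exons) are added.

Descriptor states are planted per dataset at configured loss rates; the
defaults are the rates observed in the benchmark tables (see
``docs/methods.md``).  ``fraction_functional_unknown`` optionally labels a
fraction of the unknown partners as genuinely functional, in which case
their descriptor states are drawn with the positive-set rates instead.

One pseudo-random stream per artifact class (genes, peptides, domains,
structures, sites, expression, negatives), each spawned from the master
seed, keeps the classes independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .dataset_builder import ASPOS, NEGATIVE, NOASPOS, UNKNOWN, build_negative
from .descriptors import (
    AS_SITES,
    PFAM,
    STRUCTURE,
    ActiveSiteAnnotation,
    DomainHit,
    StructuralAssessment,
    Verdict,
)
from .gene_models import (
    CodingExon,
    GeneModel,
    GenomicInterval,
    Isoform,
    find_specific_regions,
    merge_intervals,
    translate_cds,
)
from .peptide_mapping import (
    PEPTIDE_LENGTH_RANGE,
    Peptide,
    default_scorer,
    detectability,
    digest,
    intervals_contain,
    protein_to_genome,
)
from .pipeline import Cohort

_TABLE = unambiguous_dna_by_id[1]
_CODONS_BY_AA: Dict[str, List[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_AA_ORDER = "".join(sorted(_CODONS_BY_AA))
_STOP = "TAA"
_NT = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    Defaults reproduce the shape of the benchmark study: 555 paired
    positive/unknown isoforms, 865 single-isoform positives, 555 negative
    ORFs of at least 100 residues; descriptor applicability and planted
    loss rates per dataset taken from the benchmark tables.
    """

    seed: int = 0
    n_pairs: int = 555
    n_noaspos: int = 865
    n_negative: int = 555
    n_noncoding_transcripts: int = 900

    # gene geometry
    exons_per_gene: Tuple[int, int] = (5, 9)
    exon_codons: Tuple[int, int] = (15, 50)
    intron_length: Tuple[int, int] = (60, 300)
    p_minus_strand: float = 0.3
    p_third_isoform: float = 0.25
    p_partial_overlap: float = 0.3
    partial_overlap_codons: Tuple[int, int] = (3, 7)

    # peptide observation model
    peptide_sampling_depth: float = 0.35  # per-peptide observation probability

    # descriptor applicability (fraction of isoforms with inputs)
    site_gene_fraction: float = 80 / 555
    struct_fraction: Dict[str, float] = field(
        default_factory=lambda: {
            ASPOS: 147 / 555,
            UNKNOWN: 145 / 555,
            NOASPOS: 230 / 865,
            NEGATIVE: 84 / 555,
        }
    )
    pfam_fraction: Dict[str, float] = field(
        default_factory=lambda: {
            ASPOS: 503 / 555,
            UNKNOWN: 392 / 555,
            NOASPOS: 0.88,
            NEGATIVE: 397 / 555,
        }
    )

    # planted per-descriptor loss probabilities, per dataset
    site_loss: Dict[str, float] = field(
        default_factory=lambda: {ASPOS: 1 / 80, UNKNOWN: 31 / 79}
    )
    struct_loss: Dict[str, float] = field(
        default_factory=lambda: {
            ASPOS: 13 / 147,
            UNKNOWN: 76 / 145,
            NOASPOS: 0.12,
            NEGATIVE: 44 / 84,
        }
    )
    pfam_loss: Dict[str, float] = field(
        default_factory=lambda: {
            ASPOS: 23 / 503,
            UNKNOWN: 165 / 392,
            NOASPOS: 5 / 88,
            NEGATIVE: 117 / 397,
        }
    )
    structure_rule_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    fraction_functional_unknown: float = 0.0

    # domain counts (1 + Poisson(mean - 1)); positives carry more domains
    pfam_domains_mean: Dict[str, float] = field(
        default_factory=lambda: {ASPOS: 2.4, UNKNOWN: 1.6, NOASPOS: 2.0, NEGATIVE: 1.5}
    )

    # expression panel (log-scale normal; 0.8 shift at sd 1.0 -> ~69% overlap)
    n_tissues: int = 11
    expr_fraction: Dict[str, float] = field(
        default_factory=lambda: {ASPOS: 532 / 555, UNKNOWN: 264 / 555}
    )
    expr_location: Dict[str, float] = field(
        default_factory=lambda: {ASPOS: 6.0, UNKNOWN: 5.2}
    )
    expr_isoform_sd: float = 0.9
    expr_tissue_sd: float = 0.45

    # negative-set transcripts
    orf_length_aa: Tuple[int, int] = (80, 700)

    max_gene_attempts: int = 200


@dataclass
class GroundTruth:
    """Planted truth for every generated isoform / ORF."""

    labels: Dict[str, str]  # id -> translated_functional | non_functional
    datasets: Dict[str, str]  # id -> expected dataset
    planted: Dict[str, Dict[str, Verdict]]  # id -> descriptor -> verdict
    diagnostics: Dict[str, int] = field(default_factory=dict)


def full_applicability_config(seed: int, n_pairs: int = 500) -> SimulationConfig:
    """Conditions for parameter-recovery runs: every descriptor applies
    to every paired isoform, loss rates at their defaults."""
    return SimulationConfig(
        seed=seed,
        n_pairs=n_pairs,
        n_noaspos=0,
        n_negative=0,
        n_noncoding_transcripts=0,
        site_gene_fraction=1.0,
        struct_fraction={ASPOS: 1.0, UNKNOWN: 1.0, NOASPOS: 1.0, NEGATIVE: 1.0},
        pfam_fraction={ASPOS: 1.0, UNKNOWN: 1.0, NOASPOS: 1.0, NEGATIVE: 1.0},
    )


# ---------------------------------------------------------------------------
# low-level builders


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA_ORDER), size=n))


def _aa_to_nt(rng: np.random.Generator, aa: str) -> str:
    return "".join(rng.choice(_CODONS_BY_AA[a]) for a in aa)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NT), size=n))


@dataclass
class _PairGene:
    gene: GeneModel
    chrom_seq: str
    pos_id: str
    unk_id: str
    # exon index -> (aa offset in that isoform, codon count), per isoform
    pos_exons: List[int]
    unk_exons: List[int]
    codons: List[int]
    skip_pos: int  # exon private to the partner (absent from the positive)
    skip_unk: int  # exon private to the positive (absent from the partner)
    shared_pool: List[int]  # exons present in every isoform, site-safe


def _build_pair_gene(
    rng: np.random.Generator, cfg: SimulationConfig, index: int
) -> Tuple[_PairGene, Dict[str, str]]:
    gene_id = f"G{index:05d}"
    chrom = f"chr_{gene_id}"
    e_lo, e_hi = cfg.exons_per_gene
    n_exons = int(rng.integers(max(4, e_lo), e_hi + 1))
    codons = [int(c) for c in rng.integers(*cfg.exon_codons, size=n_exons) ]
    internal = list(range(1, n_exons))
    skip_pos, skip_unk = rng.choice(internal, size=2, replace=False)
    skip_pos, skip_unk = int(skip_pos), int(skip_unk)
    pool = [i for i in internal if i not in (skip_pos, skip_unk)]

    third_skip: Optional[int] = None
    if pool and n_exons >= 5 and rng.random() < cfg.p_third_isoform:
        third_skip = int(rng.choice(pool))
        pool = [i for i in pool if i != third_skip]

    extended: Optional[int] = None
    ext_codons = 0
    if pool and rng.random() < cfg.p_partial_overlap:
        extended = int(rng.choice(pool))
        pool = [i for i in pool if i != extended]
        ext_codons = int(rng.integers(*cfg.partial_overlap_codons))

    aa_blocks = ["M" + _random_aa(rng, codons[0] - 1)] + [
        _random_aa(rng, c) for c in codons[1:]
    ]
    nt_blocks = [_aa_to_nt(rng, aa) for aa in aa_blocks]
    ext_nt = _aa_to_nt(rng, _random_aa(rng, ext_codons)) if ext_codons else ""

    # sense-strand layout with room reserved for the exon extension
    min_intron = max(cfg.intron_length[0], 3 * ext_codons + 10)
    pos = int(rng.integers(min_intron, cfg.intron_length[1] + 1))
    sense: List[Tuple[int, int]] = []
    for i in range(n_exons):
        start = pos
        end = start + 3 * codons[i]
        sense.append((start, end))
        pos = end + (3 * ext_codons if i == extended else 0)
        pos += int(rng.integers(min_intron, cfg.intron_length[1] + 1))
    length = pos

    seq = list(_random_nt(rng, length))
    for (start, end), nt in zip(sense, nt_blocks):
        seq[start:end] = nt
        if extended is not None and (start, end) == sense[extended]:
            seq[end : end + len(ext_nt)] = ext_nt
    chrom_seq = "".join(seq)

    strand = "-" if rng.random() < cfg.p_minus_strand else "+"
    if strand == "-":
        chrom_seq = str(Seq(chrom_seq).reverse_complement())
        sense_flipped = [(length - e, length - s) for s, e in sense]
        intervals = [
            GenomicInterval(chrom, s, e, "-") for s, e in sense_flipped
        ]
    else:
        intervals = [GenomicInterval(chrom, s, e, "+") for s, e in sense]

    def make_exon(i: int, ext: bool = False) -> CodingExon:
        iv = intervals[i]
        if ext:
            if strand == "+":
                iv = GenomicInterval(chrom, iv.start, iv.end + 3 * ext_codons, "+")
            else:
                iv = GenomicInterval(chrom, iv.start - 3 * ext_codons, iv.end, "-")
            return CodingExon(f"{gene_id}.e{i}x", iv)
        return CodingExon(f"{gene_id}.e{i}", iv)

    pos_list = [i for i in range(n_exons) if i != skip_pos]
    unk_list = [i for i in range(n_exons) if i != skip_unk]
    pos_iso = Isoform(
        f"{gene_id}.t1", gene_id, [make_exon(i) for i in pos_list]
    )
    unk_iso = Isoform(
        f"{gene_id}.t2",
        gene_id,
        [make_exon(i, ext=(i == extended)) for i in unk_list],
    )
    isoforms = [pos_iso, unk_iso]
    if third_skip is not None:
        skip3 = {skip_pos, skip_unk, third_skip}
        isoforms.append(
            Isoform(
                f"{gene_id}.t3",
                gene_id,
                [make_exon(i) for i in range(n_exons) if i not in skip3],
            )
        )

    genome = {chrom: chrom_seq}
    for iso in isoforms:
        iso.protein_seq = translate_cds(iso, genome)

    shared = [
        i
        for i in range(n_exons)
        if i not in {skip_pos, skip_unk, extended}
        and (third_skip is None or i != third_skip)
    ]
    gene = GeneModel(gene_id, isoforms)
    pg = _PairGene(
        gene=gene,
        chrom_seq=chrom_seq,
        pos_id=pos_iso.isoform_id,
        unk_id=unk_iso.isoform_id,
        pos_exons=pos_list,
        unk_exons=unk_list,
        codons=codons,
        skip_pos=skip_pos,
        skip_unk=skip_unk,
        shared_pool=shared,
    )
    return pg, genome


def _specific_nonspanning_peptides(iso: Isoform, regions) -> List[str]:
    specific = merge_intervals(regions.specific_intervals(iso.isoform_id))
    if not specific:
        return []
    lo, hi = PEPTIDE_LENGTH_RANGE
    out = []
    for dp in digest(iso.protein_seq):
        if not (lo <= len(dp.sequence) <= hi):
            continue
        fp = protein_to_genome(iso, dp.aa_start, dp.aa_end)
        if len(fp) == 1 and intervals_contain(specific, fp):
            out.append(dp.sequence)
    return out


def _residue_in_exon(
    iso_exon_order: Sequence[int], codons: Sequence[int], exon: int, offset: int
) -> int:
    """1-based residue index of ``offset`` (0-based codon) within ``exon``."""
    acc = 0
    for i in iso_exon_order:
        if i == exon:
            return acc + offset + 1
        acc += codons[i]
    raise ValueError(f"exon {exon} not in isoform exon order")


def _make_assessment(
    rng: np.random.Generator,
    iso_id: str,
    planted_loss: bool,
    rule_probs: Sequence[float],
) -> StructuralAssessment:
    n = int(rng.integers(100, 201))
    tgt = list(_random_aa(rng, n))
    tpl = list(tgt)  # same length; residues differ but identity is irrelevant
    sasa = rng.uniform(15.0, 90.0, size=n)
    coords = np.column_stack(
        (3.8 * np.arange(n), rng.uniform(-0.3, 0.3, n), rng.uniform(-0.3, 0.3, n))
    )
    model_os = float(rng.uniform(0.55, 0.66))
    template_os = float(rng.uniform(0.56, 0.66))
    model_pe = float(rng.uniform(26.0, 30.0))
    template_pe = float(rng.uniform(26.5, 30.0))

    def cut(pos: int, k: int, row: List[str]) -> None:
        for c in range(pos, pos + k):
            row[c] = "-"

    # benign indels in the first half: short deletion (close flanks)
    # and/or short insertion; planted defects go in the second half so the
    # two never interact
    half = n // 2
    if rng.random() < 0.5:
        k = int(rng.integers(1, 3))
        p = int(rng.integers(5, half - k - 5))
        cut(p, k, tgt)
    if rng.random() < 0.3:
        k = int(rng.integers(1, 4))
        p = int(rng.integers(5, half - k - 5))
        if all(tgt[c] != "-" for c in range(p - 1, p + k + 1)):
            for c in range(p, p + k):
                tpl[c] = "-"
                tgt[c] = rng.choice(list(_AA_ORDER))

    if planted_loss:
        rule = int(rng.choice(4, p=np.asarray(rule_probs) / np.sum(rule_probs)))
        if rule == 0:  # distant-flank deletion: 3.8*(k+1) > 15 A for k >= 4
            k = int(rng.integers(4, 7))
            p = int(rng.integers(half, n - k - 10))
            cut(p, k, tgt)
        elif rule == 1:  # long insertion between buried residues
            k = int(rng.integers(4, 8))
            p = int(rng.integers(half, n - k - 10))
            for c in range(p, p + k):
                tpl[c] = "-"
                tgt[c] = rng.choice(list(_AA_ORDER))
            # flanking *template* residues are buried
            left = p - 1
            while tpl[left] == "-":
                left -= 1
            right = p + k
            while tpl[right] == "-":
                right += 1
            tpl_index = [i for i, c in enumerate(tpl) if c != "-"]
            sasa[tpl_index.index(left)] = rng.uniform(0.5, 4.5)
            sasa[tpl_index.index(right)] = rng.uniform(0.5, 4.5)
        elif rule == 2:
            model_os = float(rng.uniform(0.42, 0.53))
        else:
            model_pe = float(rng.uniform(21.0, 25.5))

    target_aln = "".join(tgt)
    template_aln = "".join(tpl)
    n_target = sum(1 for c in target_aln if c != "-")
    aligned = sum(1 for a, b in zip(target_aln, template_aln) if a != "-" and b != "-")
    return StructuralAssessment(
        isoform_id=iso_id,
        target_aln=target_aln,
        template_aln=template_aln,
        template_calpha=coords,
        residue_sasa=sasa,
        model_os=model_os,
        template_os=template_os,
        model_packeff=model_pe,
        template_packeff=template_pe,
        model_coverage=aligned / n_target,
    )


def _make_domain_hits(
    rng: np.random.Generator,
    iso_id: str,
    n_residues: int,
    planted_loss: bool,
    mean_domains: float,
) -> List[DomainHit]:
    n_dom = 1 + int(rng.poisson(max(mean_domains - 1.0, 0.0)))
    truncated_at = int(rng.integers(n_dom)) if planted_loss else -1
    hits = []
    for d in range(n_dom):
        hmm_len = int(rng.integers(80, 301))
        if d == truncated_at:
            hi = int(np.ceil(0.70 * hmm_len)) - 1
            span = int(rng.integers(max(1, int(0.25 * hmm_len)), max(2, hi + 1)))
        else:
            span = int(rng.integers(int(np.ceil(0.70 * hmm_len)), hmm_len + 1))
        hmm_from = int(rng.integers(1, hmm_len - span + 2))
        seq_from = int(rng.integers(1, max(2, n_residues - 10)))
        seq_to = min(n_residues, seq_from + span - 1)
        hits.append(
            DomainHit(
                isoform_id=iso_id,
                hmm_name=f"PF{rng.integers(10000, 99999):05d}",
                hmm_length=hmm_len,
                hmm_from=hmm_from,
                hmm_to=hmm_from + span - 1,
                seq_from=seq_from,
                seq_to=max(seq_from, seq_to),
                evalue=float(10.0 ** rng.uniform(-30, -6)),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(cfg: SimulationConfig) -> Tuple[Cohort, GroundTruth]:
    """Generate a complete synthetic cohort; deterministic given the seed."""
    ss = np.random.SeedSequence(cfg.seed)
    streams = ("genes", "peptides", "domains", "structures", "sites", "expression", "negatives")
    rng = {name: np.random.default_rng(s) for name, s in zip(streams, ss.spawn(len(streams)))}

    genes: List[GeneModel] = []
    genome: Dict[str, str] = {}
    observed: List[Peptide] = []
    domain_hits: Dict[str, List[DomainHit]] = {}
    structures: Dict[str, StructuralAssessment] = {}
    annotations: List[ActiveSiteAnnotation] = []
    probes: List[Tuple[GenomicInterval, List[float]]] = []

    labels: Dict[str, str] = {}
    datasets: Dict[str, str] = {}
    planted: Dict[str, Dict[str, Verdict]] = {}
    regenerated = 0

    # ---- paired AS genes -------------------------------------------------
    pair_index = 0
    pairs: List[_PairGene] = []
    while len(pairs) < cfg.n_pairs:
        pg, gene_genome = _build_pair_gene(rng["genes"], cfg, pair_index)
        pair_index += 1
        if pair_index > cfg.max_gene_attempts * max(cfg.n_pairs, 1):
            raise RuntimeError(
                f"could not realise {cfg.n_pairs} paired genes after "
                f"{pair_index} attempts ({regenerated} regenerations)"
            )
        regions = find_specific_regions(pg.gene)
        pos_specific = _specific_nonspanning_peptides(
            pg.gene.isoform(pg.pos_id), regions
        )
        unk_detect = detectability(pg.gene.isoform(pg.unk_id), regions, default_scorer)
        if not pos_specific or not (unk_detect.applicable and unk_detect.detectable):
            regenerated += 1
            continue
        pairs.append(pg)
        genes.append(pg.gene)
        genome.update(gene_genome)

        # observed peptides: one guaranteed specific, the rest sampled
        prng = rng["peptides"]
        forced = pos_specific[int(prng.integers(len(pos_specific)))]
        chosen = {forced}
        lo, hi = PEPTIDE_LENGTH_RANGE
        for dp in digest(pg.gene.isoform(pg.pos_id).protein_seq):
            if lo <= len(dp.sequence) <= hi and prng.random() < cfg.peptide_sampling_depth:
                chosen.add(dp.sequence)
        observed.extend(Peptide(s) for s in sorted(chosen))

        labels[pg.pos_id] = "translated_functional"
        datasets[pg.pos_id] = ASPOS
        datasets[pg.unk_id] = UNKNOWN
        for iso in pg.gene.isoforms:
            if iso.isoform_id not in datasets:
                datasets[iso.isoform_id] = "excluded"
                labels[iso.isoform_id] = "non_functional"
        functional_unknown = rng["genes"].random() < cfg.fraction_functional_unknown
        labels[pg.unk_id] = (
            "translated_functional" if functional_unknown else "non_functional"
        )
        unk_rates = ASPOS if functional_unknown else UNKNOWN
        planted[pg.pos_id] = {}
        planted[pg.unk_id] = {}

        # --- active sites (gene-level applicability) ---
        srng = rng["sites"]
        if srng.random() < cfg.site_gene_fraction:
            pos_loss = srng.random() < cfg.site_loss[ASPOS]
            unk_loss = srng.random() < cfg.site_loss.get(unk_rates, cfg.site_loss[UNKNOWN])
            rows: List[ActiveSiteAnnotation] = []
            if unk_loss:
                # site in the positive's private exon, annotated on the positive
                off = int(srng.integers(pg.codons[pg.skip_unk]))
                res = _residue_in_exon(pg.pos_exons, pg.codons, pg.skip_unk, off)
                rows.append(ActiveSiteAnnotation(pg.gene.gene_id, pg.pos_id, (res,)))
            if pos_loss:
                off = int(srng.integers(pg.codons[pg.skip_pos]))
                res = _residue_in_exon(pg.unk_exons, pg.codons, pg.skip_pos, off)
                rows.append(ActiveSiteAnnotation(pg.gene.gene_id, pg.unk_id, (res,)))
            if not rows:
                exon = int(pg.shared_pool[int(srng.integers(len(pg.shared_pool)))])
                off = int(srng.integers(pg.codons[exon]))
                res = _residue_in_exon(pg.pos_exons, pg.codons, exon, off)
                rows.append(ActiveSiteAnnotation(pg.gene.gene_id, pg.pos_id, (res,)))
            annotations.extend(rows)
            planted[pg.pos_id][AS_SITES] = Verdict.LOSS if pos_loss else Verdict.CONSISTENT
            planted[pg.unk_id][AS_SITES] = Verdict.LOSS if unk_loss else Verdict.CONSISTENT
        else:
            planted[pg.pos_id][AS_SITES] = Verdict.NOT_APPLICABLE
            planted[pg.unk_id][AS_SITES] = Verdict.NOT_APPLICABLE

        # --- structures and domains per member ---
        for iso_id, dataset_key in ((pg.pos_id, ASPOS), (pg.unk_id, unk_rates)):
            frac_key = ASPOS if iso_id == pg.pos_id else UNKNOWN
            strng, drng = rng["structures"], rng["domains"]
            if strng.random() < cfg.struct_fraction[frac_key]:
                loss = strng.random() < cfg.struct_loss[dataset_key]
                structures[iso_id] = _make_assessment(
                    strng, iso_id, loss, cfg.structure_rule_probs
                )
                planted[iso_id][STRUCTURE] = Verdict.LOSS if loss else Verdict.CONSISTENT
            else:
                planted[iso_id][STRUCTURE] = Verdict.NOT_APPLICABLE
            if drng.random() < cfg.pfam_fraction[frac_key]:
                loss = drng.random() < cfg.pfam_loss[dataset_key]
                n_res = pg.gene.isoform(iso_id).n_residues
                domain_hits[iso_id] = _make_domain_hits(
                    drng, iso_id, n_res, loss, cfg.pfam_domains_mean[frac_key]
                )
                planted[iso_id][PFAM] = Verdict.LOSS if loss else Verdict.CONSISTENT
            else:
                planted[iso_id][PFAM] = Verdict.NOT_APPLICABLE

        # --- expression probes in specific regions ---
        erng = rng["expression"]
        for iso_id, cls in ((pg.pos_id, ASPOS), (pg.unk_id, UNKNOWN)):
            if erng.random() >= cfg.expr_fraction[cls]:
                continue
            specific = [
                iv
                for iv in merge_intervals(regions.specific_intervals(iso_id))
                if iv.length >= 20
            ]
            if not specific:
                continue
            level = erng.normal(cfg.expr_location[cls], cfg.expr_isoform_sd)
            for _ in range(int(erng.integers(1, 4))):
                iv = specific[int(erng.integers(len(specific)))]
                width = int(erng.integers(20, min(41, iv.length + 1)))
                start = int(erng.integers(iv.start, iv.end - width + 1))
                values = list(
                    level + erng.normal(0.0, cfg.expr_tissue_sd, cfg.n_tissues)
                )
                probes.append(
                    (GenomicInterval(iv.chrom, start, start + width, iv.strand), values)
                )

    # ---- non-AS positive genes ------------------------------------------
    grng = rng["genes"]
    for i in range(cfg.n_noaspos):
        gene_id = f"N{i:05d}"
        chrom = f"chr_{gene_id}"
        n_exons = int(grng.integers(*cfg.exons_per_gene))
        codons = [int(c) for c in grng.integers(*cfg.exon_codons, size=n_exons)]
        aa = "M" + _random_aa(grng, sum(codons) - 1)
        blocks = []
        acc = 0
        for c in codons:
            blocks.append(aa[acc : acc + c])
            acc += c
        pos = int(grng.integers(*cfg.intron_length))
        parts: List[str] = [_random_nt(grng, pos)]
        intervals = []
        for b in blocks:
            nt = _aa_to_nt(grng, b)
            intervals.append((pos, pos + len(nt)))
            parts.append(nt)
            gap = int(grng.integers(*cfg.intron_length))
            parts.append(_random_nt(grng, gap))
            pos += len(nt) + gap
        chrom_seq = "".join(parts)
        iso = Isoform(
            f"{gene_id}.t1",
            gene_id,
            [
                CodingExon(f"{gene_id}.e{j}", GenomicInterval(chrom, s, e, "+"))
                for j, (s, e) in enumerate(intervals)
            ],
        )
        iso.protein_seq = translate_cds(iso, {chrom: chrom_seq})
        genes.append(GeneModel(gene_id, [iso]))
        genome[chrom] = chrom_seq

        prng = rng["peptides"]
        lo, hi = PEPTIDE_LENGTH_RANGE
        cands = [
            dp.sequence
            for dp in digest(iso.protein_seq)
            if lo <= len(dp.sequence) <= hi
        ]
        chosen = {c for c in cands if prng.random() < cfg.peptide_sampling_depth}
        if cands and not chosen:
            chosen = {cands[int(prng.integers(len(cands)))]}
        observed.extend(Peptide(s) for s in sorted(chosen))

        iso_id = iso.isoform_id
        labels[iso_id] = "translated_functional"
        datasets[iso_id] = NOASPOS
        planted[iso_id] = {AS_SITES: Verdict.NOT_APPLICABLE}
        strng, drng = rng["structures"], rng["domains"]
        if strng.random() < cfg.struct_fraction[NOASPOS]:
            loss = strng.random() < cfg.struct_loss[NOASPOS]
            structures[iso_id] = _make_assessment(
                strng, iso_id, loss, cfg.structure_rule_probs
            )
            planted[iso_id][STRUCTURE] = Verdict.LOSS if loss else Verdict.CONSISTENT
        else:
            planted[iso_id][STRUCTURE] = Verdict.NOT_APPLICABLE
        if drng.random() < cfg.pfam_fraction[NOASPOS]:
            loss = drng.random() < cfg.pfam_loss[NOASPOS]
            domain_hits[iso_id] = _make_domain_hits(
                drng, iso_id, iso.n_residues, loss, cfg.pfam_domains_mean[NOASPOS]
            )
            planted[iso_id][PFAM] = Verdict.LOSS if loss else Verdict.CONSISTENT
        else:
            planted[iso_id][PFAM] = Verdict.NOT_APPLICABLE

    # ---- negative transcripts -------------------------------------------
    nrng = rng["negatives"]
    transcripts: List[Tuple[str, str]] = []
    for i in range(cfg.n_noncoding_transcripts):
        n_aa = int(nrng.integers(*cfg.orf_length_aa))
        aa = _random_aa(nrng, n_aa - 1)
        # 5' leader without adenine so the planted AUG is the first one
        leader = "".join(nrng.choice(list("CGT"), size=int(nrng.integers(5, 31))))
        tail = _random_nt(nrng, int(nrng.integers(0, 61)))
        transcripts.append(
            (f"T{i:05d}", leader + "ATG" + _aa_to_nt(nrng, aa) + _STOP + tail)
        )
    selected = build_negative(transcripts, cfg.n_negative) if transcripts else []
    for orf in selected:
        tid = orf.transcript_id
        labels[tid] = "non_functional"
        datasets[tid] = NEGATIVE
        planted[tid] = {AS_SITES: Verdict.NOT_APPLICABLE}
        strng, drng = rng["structures"], rng["domains"]
        if strng.random() < cfg.struct_fraction[NEGATIVE]:
            loss = strng.random() < cfg.struct_loss[NEGATIVE]
            structures[tid] = _make_assessment(
                strng, tid, loss, cfg.structure_rule_probs
            )
            planted[tid][STRUCTURE] = Verdict.LOSS if loss else Verdict.CONSISTENT
        else:
            planted[tid][STRUCTURE] = Verdict.NOT_APPLICABLE
        if drng.random() < cfg.pfam_fraction[NEGATIVE]:
            loss = drng.random() < cfg.pfam_loss[NEGATIVE]
            domain_hits[tid] = _make_domain_hits(
                drng, tid, orf.length_aa, loss, cfg.pfam_domains_mean[NEGATIVE]
            )
            planted[tid][PFAM] = Verdict.LOSS if loss else Verdict.CONSISTENT
        else:
            planted[tid][PFAM] = Verdict.NOT_APPLICABLE

    cohort = Cohort(
        genes=genes,
        genome=genome,
        observed_peptides=observed,
        domain_hits=domain_hits,
        structures=structures,
        active_sites=annotations,
        noncoding_transcripts=transcripts,
        expression_probes=probes,
    )
    truth = GroundTruth(
        labels=labels,
        datasets=datasets,
        planted=planted,
        diagnostics={"regenerated_genes": regenerated},
    )
    return cohort, truth


def benchmark_scenario(seed: int = 0) -> Tuple[Cohort, GroundTruth]:
    """A cohort sized and parameterised like the benchmark study."""
    return generate_cohort(SimulationConfig(seed=seed))


def random_gene_model(
    rng: np.random.Generator,
    cfg: Optional[SimulationConfig] = None,
    index: Optional[int] = None,
) -> Tuple[GeneModel, Dict[str, str]]:
    """One random multi-isoform gene (with its chromosome sequence).

    Unlike :func:`generate_cohort`, no peptide-observability acceptance is
    applied, so the gene geometry is an unbiased draw; useful for
    exercising region arithmetic against brute-force oracles.
    """
    cfg = cfg or SimulationConfig()
    if index is None:
        index = int(rng.integers(10**6))
    pg, genome = _build_pair_gene(rng, cfg, index)
    return pg.gene, genome
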