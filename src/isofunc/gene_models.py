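"""Gene models, exon classification and isoform-specific coding regions.

A gene is represented by its coding isoforms; each isoform by an ordered
list of coding (CDS) exons on one chromosome and strand.  Exons of a gene
are classified as *constitutive* (identical genomic interval present in
every isoform), *semi-constitutive* (identical interval in more than one
but not all isoforms), *specific* (interval in exactly one isoform, no
partial overlap with exons of other isoforms) or *partially overlapping*
(shares at least one base but not both boundaries with an exon of another
isoform).  The per-base refinement of this classification yields the
*specific regions* of each isoform: maximal stretches of coding genomic
sequence covered by exactly one isoform.  A peptide whose genomic footprint
falls entirely within such a region identifies that isoform unambiguously.

Coordinates are 0-based, half-open throughout.  GFF/GTF input (1-based,
inclusive) is converted at parse time by :mod:`isofunc.io`.  Exon identity
for the constitutive/semi-constitutive calls is by genomic interval
(chrom, start, end, strand), not by exon identifier, since identifiers may
differ across annotation sources.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from Bio.Seq import Seq


class CdsError(ValueError):
    """Malformed coding sequence (length not a multiple of three, ...)."""


class InternalStopError(CdsError):
    """The coding sequence translates with an internal stop codon."""


class ExonClass(str, Enum):
    CONSTITUTIVE = "constitutive"
    SEMI_CONSTITUTIVE = "semi_constitutive"
    SPECIFIC = "specific"
    PARTIALLY_OVERLAPPING = "partially_overlapping"


class RegionClass(str, Enum):
    CONSTITUTIVE = "constitutive"
    SEMI_CONSTITUTIVE = "semi_constitutive"
    SPECIFIC = "specific"
    PO_SPECIFIC_PART = "partially_overlapping_specific_part"
    PO_SHARED_PART = "partially_overlapping_shared_part"


#: Region classes whose bases belong to exactly one isoform.
SPECIFIC_REGION_CLASSES = frozenset({RegionClass.SPECIFIC, RegionClass.PO_SPECIFIC_PART})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval on a strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class CodingExon:
    """One coding exon of an isoform.

    ``phase`` is the codon offset (0, 1 or 2) at which the exon starts
    relative to the reading frame of its isoform.
    """

    exon_id: str
    interval: GenomicInterval
    phase: int = 0

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase}")


@dataclass
class Isoform:
    """One coding splice variant of a gene.

    ``cds_exons`` are in transcription order: ascending genomic start for
    '+' strand isoforms, descending for '-' strand.  ``protein_seq`` is the
    translation of the concatenated CDS without the terminal stop.
    """

    isoform_id: str
    gene_id: str
    cds_exons: List[CodingExon]
    protein_seq: str = ""
    annotation_status: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.cds_exons:
            raise ValueError(f"isoform {self.isoform_id} has no CDS exons")
        chroms = {e.interval.chrom for e in self.cds_exons}
        strands = {e.interval.strand for e in self.cds_exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"isoform {self.isoform_id} spans chromosomes/strands")
        ivs = sorted((e.interval.start, e.interval.end) for e in self.cds_exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS exons within isoform {self.isoform_id}")

    @property
    def chrom(self) -> str:
        return self.cds_exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.cds_exons[0].interval.strand

    @property
    def cds_length(self) -> int:
        return sum(e.interval.length for e in self.cds_exons)

    @property
    def n_residues(self) -> int:
        """Protein length in residues (from the protein if present)."""
        if self.protein_seq:
            return len(self.protein_seq)
        return self.cds_length // 3

    @property
    def exon_intervals(self) -> List[GenomicInterval]:
        return [e.interval for e in self.cds_exons]

    def cds_signature(self) -> Tuple[Tuple[str, int, int, str], ...]:
        """Order-independent identity of the CDS exon interval set."""
        return tuple(sorted(e.interval.key for e in self.cds_exons))


@dataclass
class GeneModel:
    """A gene with its coding isoforms."""

    gene_id: str
    isoforms: List[Isoform]

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id} has no isoforms")
        if {i.chrom for i in self.isoforms} != {self.isoforms[0].chrom} or {
            i.strand for i in self.isoforms
        } != {self.isoforms[0].strand}:
            raise ValueError(f"gene {self.gene_id}: isoforms disagree on chrom/strand")

    @property
    def chrom(self) -> str:
        return self.isoforms[0].chrom

    @property
    def strand(self) -> str:
        return self.isoforms[0].strand

    def isoform(self, isoform_id: str) -> Isoform:
        for iso in self.isoforms:
            if iso.isoform_id == isoform_id:
                return iso
        raise KeyError(isoform_id)


@dataclass(frozen=True)
class Region:
    interval: GenomicInterval
    region_class: RegionClass
    owners: Tuple[str, ...]


@dataclass
class RegionClassification:
    """Disjoint labelling of all coding exonic bases of one gene."""

    gene_id: str
    regions: List[Region] = field(default_factory=list)

    def specific_intervals(self, isoform_id: str) -> List[GenomicInterval]:
        """Intervals covered by *only* the given isoform."""
        return [
            r.interval
            for r in self.regions
            if r.region_class in SPECIFIC_REGION_CLASSES and r.owners == (isoform_id,)
        ]

    def isoforms_with_specific_regions(self) -> set:
        return {
            r.owners[0]
            for r in self.regions
            if r.region_class in SPECIFIC_REGION_CLASSES
        }


# ---------------------------------------------------------------------------
# operations


def collapse_utr_duplicates(gene: GeneModel) -> GeneModel:
    """Drop isoforms that differ only outside their coding sequence.

    Among isoforms whose CDS exon interval sets are identical, exactly one
    representative (the lexicographically smallest isoform id) is retained.
    """
    best: Dict[tuple, str] = {}
    for iso in gene.isoforms:
        sig = iso.cds_signature()
        if sig not in best or iso.isoform_id < best[sig]:
            best[sig] = iso.isoform_id
    keep = set(best.values())
    return GeneModel(gene.gene_id, [i for i in gene.isoforms if i.isoform_id in keep])


def classify_exons(gene: GeneModel) -> Dict[str, ExonClass]:
    """Assign each exon of a multi-isoform gene to one of the four classes.

    Returns a map from exon id to class.  Exons sharing the same genomic
    interval receive the same class.  ``partially_overlapping`` is evaluated
    against exons of *other* isoforms only: it requires at least one shared
    base with a non-identical exon interval of another isoform (an exon
    cannot overlap a distinct exon of its own isoform by construction).
    """
    if len(gene.isoforms) < 2:
        raise ValueError(f"gene {gene.gene_id}: exon classification needs >= 2 isoforms")

    members: Dict[tuple, set] = defaultdict(set)
    interval_of: Dict[tuple, GenomicInterval] = {}
    for iso in gene.isoforms:
        for exon in iso.cds_exons:
            members[exon.interval.key].add(iso.isoform_id)
            interval_of[exon.interval.key] = exon.interval

    n = len(gene.isoforms)
    keys = sorted(interval_of)
    class_of: Dict[tuple, ExonClass] = {}
    for key in keys:
        iv = interval_of[key]
        if len(members[key]) == n:
            class_of[key] = ExonClass.CONSTITUTIVE
            continue
        # a distinct overlapping interval necessarily belongs to other isoforms
        overlapping = any(
            other != key and iv.overlaps(interval_of[other]) for other in keys
        )
        if overlapping:
            class_of[key] = ExonClass.PARTIALLY_OVERLAPPING
        elif len(members[key]) > 1:
            class_of[key] = ExonClass.SEMI_CONSTITUTIVE
        else:
            class_of[key] = ExonClass.SPECIFIC

    out: Dict[str, ExonClass] = {}
    for iso in gene.isoforms:
        for exon in iso.cds_exons:
            out[exon.exon_id] = class_of[exon.interval.key]
    return out


def find_specific_regions(gene: GeneModel) -> RegionClassification:
    """Per-base refinement of the exon classification.

    Maximal intervals covered by exactly one isoform are emitted as class
    ``specific`` (whole specific exons) or
    ``partially_overlapping_specific_part`` (the private part of a partially
    overlapping exon), with that isoform as sole owner.  The remaining
    exonic bases are labelled by the class of the exon(s) containing them.
    """
    if len(gene.isoforms) < 2:
        raise ValueError(f"gene {gene.gene_id}: specific regions need >= 2 isoforms")

    exon_class = _classes_by_interval(gene)
    n = len(gene.isoforms)
    chrom, strand = gene.chrom, gene.strand

    bounds = sorted(
        {e.interval.start for iso in gene.isoforms for e in iso.cds_exons}
        | {e.interval.end for iso in gene.isoforms for e in iso.cds_exons}
    )
    # exon lists sorted by start, per isoform, for segment lookup
    per_iso = {
        iso.isoform_id: sorted(iso.exon_intervals, key=lambda iv: iv.start)
        for iso in gene.isoforms
    }

    raw: List[Tuple[int, int, RegionClass, Tuple[str, ...]]] = []
    for seg_start, seg_end in zip(bounds, bounds[1:]):
        covering: List[Tuple[str, GenomicInterval]] = []
        for iso_id, ivs in per_iso.items():
            for iv in ivs:
                if iv.start <= seg_start and iv.end >= seg_end:
                    covering.append((iso_id, iv))
                    break
        if not covering:
            continue
        owners = tuple(sorted(iso_id for iso_id, _ in covering))
        distinct = {iv.key for _, iv in covering}
        if len(owners) == 1:
            ec = exon_class[next(iter(distinct))]
            cls = (
                RegionClass.SPECIFIC
                if ec is ExonClass.SPECIFIC
                else RegionClass.PO_SPECIFIC_PART
            )
        elif len(distinct) == 1:
            ec = exon_class[next(iter(distinct))]
            if ec is ExonClass.CONSTITUTIVE:
                cls = RegionClass.CONSTITUTIVE
            elif ec is ExonClass.PARTIALLY_OVERLAPPING:
                cls = RegionClass.PO_SHARED_PART
            else:
                cls = RegionClass.SEMI_CONSTITUTIVE
        else:
            cls = RegionClass.PO_SHARED_PART
        raw.append((seg_start, seg_end, cls, owners))

    merged: List[Region] = []
    for seg_start, seg_end, cls, owners in raw:
        if (
            merged
            and merged[-1].interval.end == seg_start
            and merged[-1].region_class is cls
            and merged[-1].owners == owners
        ):
            prev = merged.pop()
            merged.append(
                Region(
                    GenomicInterval(chrom, prev.interval.start, seg_end, strand),
                    cls,
                    owners,
                )
            )
        else:
            merged.append(
                Region(GenomicInterval(chrom, seg_start, seg_end, strand), cls, owners)
            )
    return RegionClassification(gene.gene_id, merged)


def _classes_by_interval(gene: GeneModel) -> Dict[tuple, ExonClass]:
    classes = classify_exons(gene)
    out: Dict[tuple, ExonClass] = {}
    for iso in gene.isoforms:
        for exon in iso.cds_exons:
            out[exon.interval.key] = classes[exon.exon_id]
    return out


def cds_nucleotides(isoform: Isoform, genome: Mapping[str, str]) -> str:
    """Spliced coding sequence of an isoform, in reading orientation."""
    chrom_seq = genome[isoform.chrom]
    parts = []
    for exon in isoform.cds_exons:
        s = str(chrom_seq[exon.interval.start : exon.interval.end]).upper()
        if isoform.strand == "-":
            s = str(Seq(s).reverse_complement())
        parts.append(s)
    return "".join(parts)


def translate_cds(isoform: Isoform, genome: Mapping[str, str]) -> str:
    """Translate an isoform's CDS with the standard genetic code.

    The reverse complement is applied for '-' strand isoforms; a terminal
    stop codon, if present, is stripped.  Raises :class:`CdsError` if the
    CDS length is not a multiple of three and :class:`InternalStopError`
    on a premature stop codon.
    """
    nt = cds_nucleotides(isoform, genome)
    if len(nt) % 3 != 0:
        raise CdsError(
            f"isoform {isoform.isoform_id}: CDS length {len(nt)} not a multiple of 3"
        )
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise InternalStopError(
            f"isoform {isoform.isoform_id}: internal stop codon at residue {aa.index('*') + 1}"
        )
    return aa


def protein_to_genome(
    isoform: Isoform, aa_from: int, aa_to: int
) -> List[GenomicInterval]:
    """Genomic footprint of residues ``aa_from..aa_to`` (1-based, inclusive).

    Returns one interval per CDS exon touched, in transcription order; the
    total footprint length is always ``3 * (aa_to - aa_from + 1)`` bases.
    """
    n_aa = isoform.n_residues
    if not (1 <= aa_from <= aa_to <= n_aa):
        raise ValueError(
            f"residue span {aa_from}..{aa_to} out of range 1..{n_aa} "
            f"for isoform {isoform.isoform_id}"
        )
    lo, hi = 3 * (aa_from - 1), 3 * aa_to
    out: List[GenomicInterval] = []
    acc = 0
    for exon in isoform.cds_exons:
        iv = exon.interval
        a, b = max(lo, acc), min(hi, acc + iv.length)
        if a < b:
            if isoform.strand == "+":
                out.append(
                    GenomicInterval(iv.chrom, iv.start + (a - acc), iv.start + (b - acc), "+")
                )
            else:
                out.append(
                    GenomicInterval(iv.chrom, iv.end - (b - acc), iv.end - (a - acc), "-")
                )
        acc += iv.length
    return out


def genomic_codon_positions(isoform: Isoform, residue: int) -> List[int]:
    """The three genomic base positions of one codon, in transcription order."""
    positions: List[int] = []
    for iv in protein_to_genome(isoform, residue, residue):
        if iv.strand == "+":
            positions.extend(range(iv.start, iv.end))
        else:
            positions.extend(range(iv.end - 1, iv.start - 1, -1))
    return positions


def cds_offset_map(isoform: Isoform) -> Dict[int, int]:
    """Map from genomic base position to 0-based CDS offset."""
    out: Dict[int, int] = {}
    off = 0
    for exon in isoform.cds_exons:
        iv = exon.interval
        if isoform.strand == "+":
            rng: Iterable[int] = range(iv.start, iv.end)
        else:
            rng = range(iv.end - 1, iv.start - 1, -1)
        for pos in rng:
            out[pos] = off
            off += 1
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals as a sorted list of maximal disjoint intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    out: List[GenomicInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.chrom == last.chrom and iv.start <= last.end:
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            out.append(iv)
    return out


def intervals_contain(
    container: Sequence[GenomicInterval], intervals: Sequence[GenomicInterval]
) -> bool:
    """True if every query interval lies within the (merged) container union."""
    merged = merge_intervals(container)
    for iv in intervals:
        if not any(c.contains(iv) for c in merged):
            return False
    return True
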