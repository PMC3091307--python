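"""Readers and writers for the pipeline's file formats.

Gene models travel as GFF3 (CDS features with ``gene_id``,
``transcript_id`` and ``exon_id`` attributes; 1-based inclusive
coordinates converted to the package's 0-based half-open convention on
read), sequences as FASTA, tabular data as TSV and structural coordinates
either as bundled TSVs (synthetic cohorts) or real PDB files.  A whole
cohort round-trips through :func:`write_cohort` / :func:`read_cohort`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .descriptors import (
    ActiveSiteAnnotation,
    DescriptorOutcome,
    DomainHit,
    StructuralAssessment,
)
from .gene_models import (
    CodingExon,
    GeneModel,
    GenomicInterval,
    Isoform,
    RegionClassification,
    translate_cds,
)
from .peptide_mapping import DetectabilityResult, Peptide, PeptideMatch
from .pipeline import Cohort

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# gene models


def write_gff3(genes: Sequence[GeneModel], path: PathLike) -> None:
    lines = ["##gff-version 3"]
    for gene in genes:
        for iso in gene.isoforms:
            for exon in iso.cds_exons:
                iv = exon.interval
                attrs = (
                    f"gene_id={gene.gene_id};transcript_id={iso.isoform_id};"
                    f"exon_id={exon.exon_id}"
                )
                lines.append(
                    "\t".join(
                        [
                            iv.chrom,
                            "isofunc",
                            "CDS",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            str(exon.phase),
                            attrs,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: PathLike, genome: Optional[Dict[str, str]] = None) -> List[GeneModel]:
    """Load gene models from a CDS-level GFF3.

    When a genome is supplied, isoform proteins are translated in place.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    per_tx: Dict[str, List[CodingExon]] = {}
    tx_gene: Dict[str, str] = {}
    for f in db.features_of_type("CDS"):
        gene_id = f.attributes["gene_id"][0]
        tx_id = f.attributes["transcript_id"][0]
        exon_id = f.attributes["exon_id"][0]
        phase = int(f.frame) if f.frame not in (None, ".") else 0
        iv = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        per_tx.setdefault(tx_id, []).append(CodingExon(exon_id, iv, phase))
        tx_gene[tx_id] = gene_id

    by_gene: Dict[str, List[Isoform]] = {}
    for tx_id in sorted(per_tx):
        exons = per_tx[tx_id]
        reverse = exons[0].interval.strand == "-"
        exons.sort(key=lambda e: e.interval.start, reverse=reverse)
        iso = Isoform(tx_id, tx_gene[tx_id], exons)
        by_gene.setdefault(tx_gene[tx_id], []).append(iso)

    genes = [GeneModel(gid, isos) for gid, isos in sorted(by_gene.items())]
    if genome is not None:
        for gene in genes:
            for iso in gene.isoforms:
                iso.protein_seq = translate_cds(iso, genome)
    return genes


def write_fasta(records: Dict[str, str], path: PathLike) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_regions_bed(regions: Sequence[RegionClassification], path: PathLike) -> None:
    """BED6 with name = class:owner_isoform(s)."""
    lines = []
    for rc in regions:
        for r in rc.regions:
            iv = r.interval
            name = f"{r.region_class.value}:{'|'.join(r.owners)}"
            lines.append(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# peptides


def write_peptides_tsv(peptides: Sequence[Peptide], path: PathLike) -> None:
    pd.DataFrame({"peptide": [p.sequence for p in peptides]}).to_csv(
        path, sep="\t", index=False
    )


def read_peptides_tsv(path: PathLike) -> Tuple[List[Peptide], Dict[str, float]]:
    """Peptide list plus optional per-peptide scores (column ``score``)."""
    df = pd.read_csv(path, sep="\t")
    peptides = [Peptide(s) for s in df["peptide"].astype(str)]
    scores: Dict[str, float] = {}
    if "score" in df.columns:
        scores = {
            str(row["peptide"]): float(row["score"])
            for _, row in df.iterrows()
            if pd.notna(row["score"])
        }
    return peptides, scores


def write_matches_tsv(matches: Sequence[PeptideMatch], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "peptide": m.peptide,
                "isoform_id": m.isoform_id,
                "aa_start": m.aa_start,
                "aa_end": m.aa_end,
                "specificity": m.specificity,
                "exon_spanning": m.exon_spanning,
            }
            for m in matches
        ]
    ).to_csv(path, sep="\t", index=False)


def write_detectability_tsv(
    results: Sequence[DetectabilityResult], path: PathLike
) -> None:
    pd.DataFrame(
        [
            {
                "isoform_id": r.isoform_id,
                "best_score": r.best_score,
                "detectable": r.detectable,
                "applicable": r.applicable,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# domain hits

_DOMAIN_COLUMNS = [
    "isoform_id",
    "hmm_name",
    "hmm_length",
    "hmm_from",
    "hmm_to",
    "seq_from",
    "seq_to",
    "evalue",
]


def write_domain_hits_tsv(hits: Dict[str, List[DomainHit]], path: PathLike) -> None:
    rows = [
        {c: getattr(h, c) for c in _DOMAIN_COLUMNS}
        for iso in sorted(hits)
        for h in hits[iso]
    ]
    pd.DataFrame(rows, columns=_DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domain_hits_tsv(path: PathLike) -> Dict[str, List[DomainHit]]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, List[DomainHit]] = {}
    for _, row in df.iterrows():
        hit = DomainHit(
            isoform_id=str(row["isoform_id"]),
            hmm_name=str(row["hmm_name"]),
            hmm_length=int(row["hmm_length"]),
            hmm_from=int(row["hmm_from"]),
            hmm_to=int(row["hmm_to"]),
            seq_from=int(row["seq_from"]),
            seq_to=int(row["seq_to"]),
            evalue=float(row["evalue"]),
        )
        out.setdefault(hit.isoform_id, []).append(hit)
    return out


def read_domtblout(path: PathLike) -> Dict[str, List[DomainHit]]:
    """Parse hmmscan ``--domtblout`` output into domain hits.

    In hmmscan the query is the protein and the target the profile HMM;
    the per-domain independent E-value and the hmm/ali coordinate pairs are
    taken from the standard column layout.
    """
    names = [
        "target_name", "target_acc", "tlen", "query_name", "query_acc", "qlen",
        "full_evalue", "full_score", "full_bias", "dom_num", "dom_of",
        "c_evalue", "i_evalue", "dom_score", "dom_bias",
        "hmm_from", "hmm_to", "ali_from", "ali_to", "env_from", "env_to",
        "acc",
    ]
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            rows.append(parts[: len(names)])
    out: Dict[str, List[DomainHit]] = {}
    for parts in rows:
        rec = dict(zip(names, parts))
        hit = DomainHit(
            isoform_id=rec["query_name"],
            hmm_name=rec["target_name"],
            hmm_length=int(rec["tlen"]),
            hmm_from=int(rec["hmm_from"]),
            hmm_to=int(rec["hmm_to"]),
            seq_from=int(rec["ali_from"]),
            seq_to=int(rec["ali_to"]),
            evalue=float(rec["i_evalue"]),
        )
        out.setdefault(hit.isoform_id, []).append(hit)
    return out


# ---------------------------------------------------------------------------
# structural assessments


def write_structures(structures: Dict[str, StructuralAssessment], out_dir: PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln_lines: List[str] = []
    coord_rows, sasa_rows, score_rows = [], [], []
    for iso in sorted(structures):
        a = structures[iso]
        aln_lines += [f">{iso}|target", a.target_aln, f">{iso}|template", a.template_aln]
        if a.template_calpha is not None:
            for i, (x, y, z) in enumerate(np.asarray(a.template_calpha, dtype=float)):
                coord_rows.append(
                    {"isoform_id": iso, "residue": i + 1, "x": x, "y": y, "z": z}
                )
        if a.residue_sasa is not None:
            for i, s in enumerate(np.asarray(a.residue_sasa, dtype=float)):
                sasa_rows.append({"isoform_id": iso, "residue": i + 1, "sasa": s})
        score_rows.append(
            {
                "isoform_id": iso,
                "model_os": a.model_os,
                "template_os": a.template_os,
                "model_packeff": a.model_packeff,
                "template_packeff": a.template_packeff,
                "model_coverage": a.model_coverage,
            }
        )
    (out / "alignments.fasta").write_text("\n".join(aln_lines) + "\n")
    pd.DataFrame(coord_rows).to_csv(out / "template_calpha.tsv", sep="\t", index=False)
    pd.DataFrame(sasa_rows).to_csv(out / "residue_sasa.tsv", sep="\t", index=False)
    pd.DataFrame(score_rows).to_csv(out / "packing_scores.tsv", sep="\t", index=False)


def read_structures(in_dir: PathLike) -> Dict[str, StructuralAssessment]:
    src = Path(in_dir)
    aln: Dict[str, Dict[str, str]] = {}
    for rec in SeqIO.parse(str(src / "alignments.fasta"), "fasta"):
        iso, row = rec.id.rsplit("|", 1)
        aln.setdefault(iso, {})[row] = str(rec.seq)
    coords = pd.read_csv(src / "template_calpha.tsv", sep="\t")
    sasa = pd.read_csv(src / "residue_sasa.tsv", sep="\t")
    scores = pd.read_csv(src / "packing_scores.tsv", sep="\t").set_index("isoform_id")
    out: Dict[str, StructuralAssessment] = {}
    for iso, rows in aln.items():
        c = coords[coords["isoform_id"] == iso].sort_values("residue")
        s = sasa[sasa["isoform_id"] == iso].sort_values("residue")
        sc = scores.loc[iso]
        out[iso] = StructuralAssessment(
            isoform_id=iso,
            target_aln=rows["target"],
            template_aln=rows["template"],
            template_calpha=c[["x", "y", "z"]].to_numpy() if len(c) else None,
            residue_sasa=s["sasa"].to_numpy() if len(s) else None,
            model_os=_opt(sc["model_os"]),
            template_os=_opt(sc["template_os"]),
            model_packeff=_opt(sc["model_packeff"]),
            template_packeff=_opt(sc["template_packeff"]),
            model_coverage=float(sc["model_coverage"]),
        )
    return out


def _opt(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def read_pdb_atoms(path: PathLike) -> Tuple[np.ndarray, List[str], List[int]]:
    """Atom coordinates, elements and residue ids from a PDB file."""
    import biotite.structure.io.pdb as pdb

    structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
    coords = np.asarray(structure.coord)
    elements = [str(e) for e in structure.element]
    res_ids = [int(r) for r in structure.res_id]
    return coords, elements, res_ids


def read_pdb_calpha(path: PathLike) -> np.ndarray:
    """C-alpha coordinates per residue, in residue order."""
    import biotite.structure.io.pdb as pdb

    structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
    ca = structure[structure.atom_name == "CA"]
    order = np.argsort(ca.res_id, kind="stable")
    return np.asarray(ca.coord)[order]


# ---------------------------------------------------------------------------
# active sites / expression / outcomes


def write_active_sites_tsv(rows: Sequence[ActiveSiteAnnotation], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "reference_isoform": r.reference_isoform_id,
                "sites": ",".join(map(str, r.sites)),
            }
            for r in rows
        ],
        columns=["gene_id", "reference_isoform", "sites"],
    ).to_csv(path, sep="\t", index=False)


def read_active_sites_tsv(path: PathLike) -> List[ActiveSiteAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        ActiveSiteAnnotation(
            str(row["gene_id"]),
            str(row["reference_isoform"]),
            tuple(int(s) for s in str(row["sites"]).split(",")),
        )
        for _, row in df.iterrows()
    ]


def write_expression_tsv(
    probes: Sequence[Tuple[GenomicInterval, List[float]]], path: PathLike
) -> None:
    rows = []
    for iv, values in probes:
        row = {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "strand": iv.strand}
        row.update({f"tissue_{i + 1}": v for i, v in enumerate(values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: PathLike) -> List[Tuple[GenomicInterval, List[float]]]:
    df = pd.read_csv(path, sep="\t")
    tissue_cols = [c for c in df.columns if c.startswith("tissue_")]
    return [
        (
            GenomicInterval(str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["strand"])),
            [float(r[c]) for c in tissue_cols],
        )
        for _, r in df.iterrows()
    ]


def write_outcomes_tsv(
    outcomes: Dict[str, Dict[str, "object"]], path: PathLike
) -> None:
    rows = [
        {"isoform_id": iso, "descriptor": d, "verdict": getattr(v, "value", str(v))}
        for iso in sorted(outcomes)
        for d, v in sorted(outcomes[iso].items())
    ]
    pd.DataFrame(rows, columns=["isoform_id", "descriptor", "verdict"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# cohort bundle


def write_cohort(cohort: Cohort, out_dir: PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gff3(cohort.genes, out / "genes.gff3")
    write_fasta(cohort.genome, out / "genome.fa")
    write_peptides_tsv(cohort.observed_peptides, out / "peptides.tsv")
    write_domain_hits_tsv(cohort.domain_hits, out / "domain_hits.tsv")
    write_structures(cohort.structures, out / "structures")
    write_active_sites_tsv(cohort.active_sites, out / "active_sites.tsv")
    write_fasta(dict(cohort.noncoding_transcripts), out / "noncoding.fa")
    write_expression_tsv(cohort.expression_probes, out / "expression.tsv")


def read_cohort(in_dir: PathLike) -> Cohort:
    src = Path(in_dir)
    genome = read_fasta(src / "genome.fa")
    genes = read_gff3(src / "genes.gff3", genome)
    peptides, scores = read_peptides_tsv(src / "peptides.tsv")
    return Cohort(
        genes=genes,
        genome=genome,
        observed_peptides=peptides,
        domain_hits=read_domain_hits_tsv(src / "domain_hits.tsv"),
        structures=read_structures(src / "structures"),
        active_sites=read_active_sites_tsv(src / "active_sites.tsv"),
        noncoding_transcripts=sorted(read_fasta(src / "noncoding.fa").items()),
        expression_probes=read_expression_tsv(src / "expression.tsv"),
        peptide_scores=scores,
    )


def write_ground_truth_json(truth, path: PathLike) -> None:
    data = {
        "labels": truth.labels,
        "datasets": truth.datasets,
        "planted": {
            iso: {d: getattr(v, "value", str(v)) for d, v in per.items()}
            for iso, per in truth.planted.items()
        },
        "diagnostics": truth.diagnostics,
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))
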