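"""Shared fixtures: hand-built gene models and per-base coverage oracles."""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from isofunc.config import PipelineConfig
from isofunc.gene_models import (
    CodingExon,
    GeneModel,
    GenomicInterval,
    Isoform,
)
from isofunc.pipeline import run_pipeline
from isofunc.synthetic_data import full_applicability_config, generate_cohort


def make_isoform(
    iso_id: str,
    gene_id: str,
    exons: Sequence[Tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
    protein: str = "",
) -> Isoform:
    order = sorted(exons, key=lambda se: se[0], reverse=(strand == "-"))
    iso = Isoform(
        iso_id,
        gene_id,
        [
            CodingExon(f"{iso_id}.e{i}", GenomicInterval(chrom, s, e, strand))
            for i, (s, e) in enumerate(order)
        ],
    )
    iso.protein_seq = protein
    return iso


def base_coverage(gene: GeneModel) -> Dict[int, set]:
    """Brute-force per-base isoform coverage of a gene's exonic bases."""
    cover: Dict[int, set] = defaultdict(set)
    for iso in gene.isoforms:
        for iv in iso.exon_intervals:
            for p in range(iv.start, iv.end):
                cover[p].add(iso.isoform_id)
    return dict(cover)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def recovery_run():
    """A 500-pair cohort with every descriptor applicable, plus its
    pipeline result — shared by the parameter-recovery and identity tests."""
    cfg = full_applicability_config(seed=101, n_pairs=500)
    cohort, truth = generate_cohort(cfg)
    result = run_pipeline(cohort, PipelineConfig(n_negative=0))
    return cfg, cohort, truth, result
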