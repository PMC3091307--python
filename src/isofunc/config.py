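"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .descriptors import Thresholds


@dataclass
class PipelineConfig:
    """Tunable knobs of the end-to-end analysis.

    ``min_specific_peptides`` — specific peptides required to call an
    isoform identified (default 1).  ``missed_cleavages`` — internal
    cleavage sites allowed in the in silico digestion (default 0).
    ``detectability_threshold`` — minimum peptide-observability score for
    an unknown candidate to count as detectable (default 0.5, boundary
    inclusive).  ``min_orf_len`` / ``n_negative`` — negative-set ORF floor
    (residues) and size.  ``thresholds`` — descriptor operating points.
    """

    min_specific_peptides: int = 1
    missed_cleavages: int = 0
    detectability_threshold: float = 0.5
    min_orf_len: int = 100
    n_negative: int = 555
    thresholds: Thresholds = field(default_factory=Thresholds)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        thr = data.pop("thresholds", None)
        cfg = cls(**data)
        if thr:
            cfg.thresholds = Thresholds(**thr)
        return cfg
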