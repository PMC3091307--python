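"""Descriptor combination, confusion counting and metric tables.

For a combination of descriptors an isoform is *applicable* when at least
one member descriptor applies (union), when every member applies
(intersection), or when the single member applies.  On applicable isoforms
the verdict is ``consistent`` only when **every** applicable in-combination
descriptor says consistent; any applicable descriptor saying ``loss``
makes the combined verdict ``loss`` (the discordance rule: an isoform with
disagreeing descriptors is counted as a false negative in the positive set
and a true negative in the comparison set).

Confusion counts follow the usual definitions on a positive dataset
(MS-identified isoforms) and a comparison dataset (unknown or negative):
TP = positive & consistent, FN = positive & loss, FP = comparison &
consistent, TN = comparison & loss; not-applicable isoforms enter no cell
and only reduce coverage.  Coverage is (TP+TN+FP+FN) over the combined
size of the two datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations as _itercombos
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .descriptors import AS_SITES, DESCRIPTOR_NAMES, PFAM, STRUCTURE, Verdict

#: Short labels used in report tables.
SHORT_NAMES = {AS_SITES: "AS", STRUCTURE: "St", PFAM: "Pfam"}

_METRIC_COLUMNS = ("coverage", "accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class CombinationSpec:
    """A single descriptor, or a union/intersection of several."""

    descriptors: Tuple[str, ...]
    mode: str  # "single" | "union" | "intersection"

    def __post_init__(self) -> None:
        if not self.descriptors:
            raise ValueError("empty descriptor combination")
        if any(d not in DESCRIPTOR_NAMES for d in self.descriptors):
            raise ValueError(f"unknown descriptor in {self.descriptors}")
        if self.mode not in ("single", "union", "intersection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "single" and len(self.descriptors) != 1:
            raise ValueError("mode 'single' requires exactly one descriptor")
        if self.mode != "single" and len(self.descriptors) < 2:
            raise ValueError(f"mode {self.mode!r} requires >= 2 descriptors")

    @property
    def label(self) -> str:
        names = [SHORT_NAMES[d] for d in self.descriptors]
        if self.mode == "single":
            return names[0]
        sep = " U " if self.mode == "union" else " ∩ "
        return sep.join(names)


def single(descriptor: str) -> CombinationSpec:
    return CombinationSpec((descriptor,), "single")


def union(*descriptors: str) -> CombinationSpec:
    return CombinationSpec(tuple(descriptors), "union")


def intersection(*descriptors: str) -> CombinationSpec:
    return CombinationSpec(tuple(descriptors), "intersection")


def standard_combinations(
    descriptors: Sequence[str] = DESCRIPTOR_NAMES,
) -> List[CombinationSpec]:
    """Singles, then all unions, then all intersections (report row order)."""
    out = [single(d) for d in descriptors]
    for size in range(2, len(descriptors) + 1):
        for combo in _itercombos(descriptors, size):
            out.append(union(*combo))
    for size in range(2, len(descriptors) + 1):
        for combo in _itercombos(descriptors, size):
            out.append(intersection(*combo))
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    total_isoforms: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("negative confusion counts")
        if self.TP + self.TN + self.FP + self.FN > self.total_isoforms:
            raise ValueError("confusion counts exceed the cohort size")

    @property
    def applicable(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricRow:
    """Coverage/accuracy/sensitivity/specificity for one combination.

    Full-precision values are kept as floats (``None`` where a denominator
    is zero); :meth:`rounded` reports two decimals, rounding halves away
    from zero, computed from the integer counts so that exact halves (for
    example 101/200) round predictably.
    """

    label: str
    counts: ConfusionCounts

    @property
    def coverage(self) -> Optional[float]:
        return _ratio(self.counts.applicable, self.counts.total_isoforms)

    @property
    def accuracy(self) -> Optional[float]:
        return _ratio(self.counts.TP + self.counts.TN, self.counts.applicable)

    @property
    def sensitivity(self) -> Optional[float]:
        return _ratio(self.counts.TP, self.counts.TP + self.counts.FN)

    @property
    def specificity(self) -> Optional[float]:
        return _ratio(self.counts.TN, self.counts.TN + self.counts.FP)

    def rounded(self) -> Dict[str, Optional[float]]:
        c = self.counts
        return {
            "coverage": _round_ratio(c.applicable, c.total_isoforms),
            "accuracy": _round_ratio(c.TP + c.TN, c.applicable),
            "sensitivity": _round_ratio(c.TP, c.TP + c.FN),
            "specificity": _round_ratio(c.TN, c.TN + c.FP),
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def _round_ratio(num: int, den: int, ndigits: int = 2) -> Optional[float]:
    if not den:
        return None
    q = Decimal(num) / Decimal(den)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals, halves away from zero."""
    return float(
        Decimal(repr(x)).quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    )


def percentage(num: int, den: int) -> int:
    """Integer percentage with halves rounded away from zero."""
    if den == 0:
        raise ZeroDivisionError("percentage of an empty set")
    return int(
        (Decimal(100) * Decimal(num) / Decimal(den)).quantize(
            Decimal(1), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# combination and counting


def combine(
    outcomes: Mapping[str, Mapping[str, Verdict]],
    spec: CombinationSpec,
) -> Dict[str, Verdict]:
    """Combined verdict per isoform under a combination spec.

    ``outcomes`` maps isoform id to a per-descriptor verdict map; missing
    descriptors count as not applicable.
    """
    result: Dict[str, Verdict] = {}
    for iso_id in outcomes:
        per = outcomes[iso_id]
        verdicts = [per.get(d, Verdict.NOT_APPLICABLE) for d in spec.descriptors]
        applicable = [v for v in verdicts if v is not Verdict.NOT_APPLICABLE]
        if spec.mode == "intersection":
            ok = len(applicable) == len(spec.descriptors)
        else:  # single or union
            ok = bool(applicable)
        if not ok:
            result[iso_id] = Verdict.NOT_APPLICABLE
        elif any(v is Verdict.LOSS for v in applicable):
            result[iso_id] = Verdict.LOSS
        else:
            result[iso_id] = Verdict.CONSISTENT
    return result


def count_confusion(
    positive_verdicts: Mapping[str, Verdict],
    comparison_verdicts: Mapping[str, Verdict],
    total: Optional[int] = None,
) -> ConfusionCounts:
    """TP/TN/FP/FN from combined verdicts on the two datasets.

    ``total`` defaults to the combined size of the positive and comparison
    datasets (the coverage denominator).
    """
    if total is None:
        total = len(positive_verdicts) + len(comparison_verdicts)
    tp = sum(1 for v in positive_verdicts.values() if v is Verdict.CONSISTENT)
    fn = sum(1 for v in positive_verdicts.values() if v is Verdict.LOSS)
    fp = sum(1 for v in comparison_verdicts.values() if v is Verdict.CONSISTENT)
    tn = sum(1 for v in comparison_verdicts.values() if v is Verdict.LOSS)
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn, total_isoforms=total)


def metrics(counts: ConfusionCounts, label: str = "") -> MetricRow:
    return MetricRow(label, counts)


def evaluate_combinations(
    positive_outcomes: Mapping[str, Mapping[str, Verdict]],
    comparison_outcomes: Mapping[str, Mapping[str, Verdict]],
    specs: Optional[Sequence[CombinationSpec]] = None,
    total: Optional[int] = None,
) -> Dict[str, ConfusionCounts]:
    """Confusion counts per combination label over a positive/comparison pair."""
    if specs is None:
        specs = standard_combinations()
    if total is None:
        total = len(positive_outcomes) + len(comparison_outcomes)
    out: Dict[str, ConfusionCounts] = {}
    for spec in specs:
        pos = combine(positive_outcomes, spec)
        comp = combine(comparison_outcomes, spec)
        out[spec.label] = count_confusion(pos, comp, total)
    return out


def metrics_table(counts_by_label: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """Report table (Coverage, TP, TN, FP, FN, Accuracy, Sensitivity, Specificity)."""
    rows = []
    for label, counts in counts_by_label.items():
        row = MetricRow(label, counts)
        r = row.rounded()
        rows.append(
            {
                "combination": label,
                "coverage": r["coverage"],
                "TP": counts.TP,
                "TN": counts.TN,
                "FP": counts.FP,
                "FN": counts.FN,
                "accuracy": r["accuracy"],
                "sensitivity": r["sensitivity"],
                "specificity": r["specificity"],
                "coverage_full": row.coverage,
                "accuracy_full": row.accuracy,
                "sensitivity_full": row.sensitivity,
                "specificity_full": row.specificity,
            }
        )
    return pd.DataFrame(rows)


#: A printed two-decimal cell agrees with recomputation when it is within
#: half a printed unit of the full-precision ratio (exact halves therefore
#: agree with either neighbour).
PRINTED_CELL_TOLERANCE = 0.005 + 1e-12


def reproduce_metric_tables(
    rows: Sequence[Tuple[str, int, int, int, int]],
    total: int,
    expected: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Recompute a published metric table from its TP/TN/FP/FN counts.

    ``rows`` are (label, TP, TN, FP, FN) tuples; ``expected`` optionally
    maps label -> {metric: printed value}.  The returned frame carries the
    recomputed metrics (both rounded and full precision) plus, when
    expected values are given, a ``mismatches`` column naming every cell
    whose printed value differs from the recomputed ratio beyond rounding.
    """
    counts_by_label = {
        label: ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn, total_isoforms=total)
        for label, tp, tn, fp, fn in rows
    }
    table = metrics_table(counts_by_label)
    if expected is not None:
        flags: List[str] = []
        for _, row in table.iterrows():
            exp = expected.get(row["combination"], {})
            bad = []
            for metric in _METRIC_COLUMNS:
                if metric not in exp:
                    continue
                full = row[f"{metric}_full"]
                if full is None or pd.isna(full):
                    bad.append(metric)
                elif abs(full - exp[metric]) > PRINTED_CELL_TOLERANCE:
                    bad.append(metric)
            flags.append(",".join(bad))
        table["mismatches"] = flags
    return table


def discordant_positives(
    positive_outcomes: Mapping[str, Mapping[str, Verdict]],
    descriptors: Sequence[str],
) -> int:
    """Positives applicable to all given descriptors with a split verdict.

    Counts isoforms where every listed descriptor applies and the verdicts
    disagree (at least one loss and at least one consistent).  This is the
    correction term in the inclusion-exclusion identity
    ``TP(A u B) + D = TP(A) + TP(B) - TP(A n B)``; the identity is plain
    when no discordant positives exist.
    """
    n = 0
    for per in positive_outcomes.values():
        vs = [per.get(d, Verdict.NOT_APPLICABLE) for d in descriptors]
        if any(v is Verdict.NOT_APPLICABLE for v in vs):
            continue
        if any(v is Verdict.LOSS for v in vs) and any(
            v is Verdict.CONSISTENT for v in vs
        ):
            n += 1
    return n
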