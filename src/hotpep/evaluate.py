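"""Pairwise comparison of two annotation sets and the associated
sensitivity / precision / F1 statistics.

Hits are compared as sets of keys. True positives are hits found by both
methods; false positives are hits found by the method under test but not
the reference; false negatives the reverse. Sensitivity is TP/(TP+FN),
precision TP/(TP+FP), and F1 = 2TP/(2TP+FP+FN), the harmonic mean of the
two. Reported values are rounded half-up to two decimals; raw values are
retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class ComparisonCounts:
    true_positives: int
    false_positives: int
    false_negatives: int

    def __post_init__(self) -> None:
        if min(self.true_positives, self.false_positives, self.false_negatives) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def test_total(self) -> int:
        return self.true_positives + self.false_positives

    @property
    def reference_total(self) -> int:
        return self.true_positives + self.false_negatives


def compare(test: set[Hashable], reference: set[Hashable]) -> ComparisonCounts:
    """Set-algebra comparison of two hit-key sets.

    Keys are either plain accessions (the default granularity — the
    statistics count proteins) or (accession, family) pairs for a
    per-family audit.
    """
    return ComparisonCounts(
        true_positives=len(test & reference),
        false_positives=len(test - reference),
        false_negatives=len(reference - test),
    )


def sensitivity(c: ComparisonCounts) -> float:
    """TP/(TP+FN); undefined (ValueError) when the reference is empty."""
    denom = c.true_positives + c.false_negatives
    if denom == 0:
        raise ValueError("sensitivity undefined: TP + FN == 0")
    return c.true_positives / denom


def precision(c: ComparisonCounts) -> float:
    """TP/(TP+FP); undefined (ValueError) when the test set is empty."""
    denom = c.true_positives + c.false_positives
    if denom == 0:
        raise ValueError("precision undefined: TP + FP == 0")
    return c.true_positives / denom


def f1(c: ComparisonCounts) -> float:
    """2TP/(2TP+FP+FN); undefined (ValueError) when all counts are zero."""
    denom = 2 * c.true_positives + c.false_positives + c.false_negatives
    if denom == 0:
        raise ValueError("F1 undefined: all counts are zero")
    return 2 * c.true_positives / denom


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention,
    unlike Python's banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def combined_f1(counts: Sequence[ComparisonCounts]) -> dict[str, float]:
    """Two combination rules for F1 across datasets, both reported:

    * ``pooled`` — F1 of the summed TP/FP/FN counts;
    * ``mean`` — arithmetic mean of the per-dataset F1 values.

    The two rules genuinely differ and neither is canonical, so the caller
    chooses which to quote.
    """
    pooled = ComparisonCounts(
        sum(c.true_positives for c in counts),
        sum(c.false_positives for c in counts),
        sum(c.false_negatives for c in counts),
    )
    return {
        "pooled": f1(pooled),
        "mean": sum(f1(c) for c in counts) / len(counts),
    }


def comparison_table(
    methods: Mapping[str, ComparisonCounts],
    reference_total: int | None = None,
) -> pd.DataFrame:
    """Summary table: rows annotated/TP/FP/FN/sensitivity/precision/F1,
    one column per compared method. Statistics rounded to 2 decimals."""
    rows = [
        "annotated",
        "true_positives",
        "false_positives",
        "false_negatives",
        "sensitivity",
        "precision",
        "f1",
    ]
    data = {}
    for name, c in methods.items():
        data[name] = [
            c.test_total,
            c.true_positives,
            c.false_positives,
            c.false_negatives,
            round_half_up(sensitivity(c)),
            round_half_up(precision(c)),
            round_half_up(f1(c)),
        ]
    table = pd.DataFrame(data, index=rows)
    if reference_total is not None:
        table.insert(0, "reference", [reference_total, None, None, None, None, None, None])
    return table


def read_hit_list(path: str | Path, per_family: bool = False) -> set:
    """Read a hit list: one ``accession`` (or ``accession<TAB>family``) per
    line. With ``per_family`` the keys are (accession, family) pairs;
    otherwise family columns, if present, are ignored."""
    keys = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if per_family:
                if len(parts) < 2:
                    raise ValueError(f"per-family mode needs two columns: {line!r}")
                keys.add((parts[0], parts[1]))
            else:
                keys.add(parts[0])
    return keys
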