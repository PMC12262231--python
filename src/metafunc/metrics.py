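"""Evaluation machinery: overlap matrices, sensitivity/PFD, fold-change errors.

Sensitivity and PFD follow the standard contingency arithmetic on GO-term (or
species) sets against a gold standard G: sensitivity = 100·|M∩G|/|G| and
PFD = 100·(1 − |M∩G|/|M|), i.e. one minus precision.  The quasi-gold standard
is the GO-term union of all proteins accepted at an expected false-positive
count of 1 (E-value ≤ 1), without clustering.  Fold-change accuracy over a
set of pairwise comparisons is summarized by the signed expected error, the
expected mean absolute log2 fold-change error, and the pooled fraction of
errors within a bound (default ±2).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .evidence import ASPECTS, ProteinRecord

__all__ = [
    "TermSet",
    "FoldChangeComparison",
    "MetricSummary",
    "overlap_matrix",
    "sensitivity_pfd",
    "log2fc_error_metrics",
    "build_quasi_gold",
]


@dataclass(frozen=True)
class TermSet:
    label: str
    terms: frozenset[str]


@dataclass
class FoldChangeComparison:
    """Paired computed/true log2 fold changes for one pairwise comparison."""

    computed: Sequence[float]
    true: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.computed) != len(self.true):
            raise ValueError("computed/true length mismatch")
        if len(self.computed) == 0:
            raise ValueError("empty fold-change comparison")
        arr = np.asarray(self.computed, float), np.asarray(self.true, float)
        if not (np.isfinite(arr[0]).all() and np.isfinite(arr[1]).all()):
            raise ValueError("non-finite log2 fold change")

    @property
    def m(self) -> int:
        return len(self.computed)

    def errors(self) -> np.ndarray:
        return np.asarray(self.computed, float) - np.asarray(self.true, float)


@dataclass
class MetricSummary:
    e_error: float
    e_malfce: float
    pct_ev: float
    n_comparisons: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_ev <= 1.0:
            raise ValueError("pct_ev outside [0, 1]")
        if self.e_malfce < 0:
            raise ValueError("e_malfce must be non-negative")


def overlap_matrix(sets: List[TermSet]) -> np.ndarray:
    """Row-normalized overlap: entry (r, c) = |row ∩ col| / |row|."""
    if len(sets) < 2:
        raise ValueError("need at least two term sets")
    for s in sets:
        if not s.terms:
            raise ValueError(f"empty term set {s.label!r}")
    n = len(sets)
    mat = np.zeros((n, n))
    for r in range(n):
        for c in range(n):
            mat[r, c] = len(sets[r].terms & sets[c].terms) / len(sets[r].terms)
    return mat


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sensitivity_pfd(
    method, gold, rounding_digits: int | None = None
) -> Tuple[float, float]:
    """Sensitivity % and PFD % of a method set against a gold standard.

    ``method``/``gold`` are :class:`TermSet` instances, or ``method`` may be a
    ``(true_positive_count, reported_count)`` pair with ``gold`` the gold-set
    size — convenient when only printed contingency counts are available.
    ``rounding_digits`` applies half-up rounding to the printed precision.
    """
    if isinstance(method, TermSet):
        if not isinstance(gold, TermSet):
            raise ValueError("gold must be a TermSet when method is one")
        if not gold.terms:
            raise ValueError("empty gold standard")
        if not method.terms:
            raise ValueError("PFD undefined for an empty method set")
        tp = len(method.terms & gold.terms)
        reported = len(method.terms)
        gold_size = len(gold.terms)
    else:
        tp, reported = method
        gold_size = int(gold)
        if gold_size <= 0 or reported <= 0:
            raise ValueError("gold and reported counts must be positive")
    sens = 100.0 * tp / gold_size
    pfd = 100.0 * (1.0 - tp / reported)
    if rounding_digits is not None:
        sens = _round_half_up(sens, rounding_digits)
        pfd = _round_half_up(pfd, rounding_digits)
    return sens, pfd


def log2fc_error_metrics(
    comparisons: List[FoldChangeComparison], ev_bound: float = 2.0
) -> MetricSummary:
    """Signed/absolute fold-change error summaries over pairwise comparisons.

    E[Error] and E[MALFCE] average the per-comparison mean (signed, absolute)
    error over the N comparisons; the within-bound fraction pools all
    individual errors across comparisons.
    """
    if not comparisons:
        raise ValueError("no fold-change comparisons")
    n = len(comparisons)
    signed = sum(float(c.errors().mean()) for c in comparisons) / n
    absolute = sum(float(np.abs(c.errors()).mean()) for c in comparisons) / n
    total_m = sum(c.m for c in comparisons)
    within = sum(int((np.abs(c.errors()) <= ev_bound).sum()) for c in comparisons)
    return MetricSummary(signed, absolute, within / total_m, n)


def build_quasi_gold(
    proteins: Iterable[ProteinRecord], expected_fp: float = 1.0
) -> Dict[str, TermSet]:
    """Per-aspect GO-term union of proteins accepted at an expected
    false-positive count of ``expected_fp`` (accept E-value ≤ expected_fp),
    without clustering."""
    accepted = [p for p in proteins if p.evalue <= expected_fp]
    out: Dict[str, TermSet] = {}
    for aspect in ASPECTS:
        terms = frozenset().union(
            *(p.go_of_aspect(aspect) for p in accepted)
        ) if accepted else frozenset()
        out[aspect] = TermSet(f"quasi-gold-{aspect}", frozenset(terms))
    return out
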