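"""Statistical evaluation layer: rank-sum tests, ROC/AUC, threshold search.

Group comparisons use the two-sided Mann-Whitney Wilcoxon test — exact by
enumeration when the pooled sample is small and tie-free, otherwise the
normal approximation with tie and continuity corrections. The AUC is the
rank-based pair statistic (probability that a positive outscores a
negative, with half credit for ties), so ``auc == U / (n1 * n2)`` holds
exactly by construction. Threshold selection maximizes Youden's
J = TPR - FPR over the pooled score grid under the classification rule
``score >= threshold => positive``, breaking ties toward the lowest
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "ROCResult",
    "BenchmarkReport",
    "EXACT_TOTAL_CAP",
    "rank_sum_test",
    "roc_auc",
    "threshold_separation",
    "evaluate_benchmark",
]

#: exact-enumeration cap: pooled sample sizes up to this use the exact null
EXACT_TOTAL_CAP = 25


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-sided Mann-Whitney Wilcoxon comparison.

    ``u_statistic`` is U for the first group (number of pairs where the
    first group's value exceeds the second's, with half credit for ties).
    """

    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    n1: int
    n2: int


@dataclass(frozen=True)
class ROCResult:
    auc: float
    thresholds: tuple[float, ...]
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]
    best_threshold: float
    criterion: str = "youden"


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_total_cap: int = EXACT_TOTAL_CAP,
) -> ComparisonResult:
    """Two-sided Mann-Whitney Wilcoxon test between two groups.

    U is computed from midranks. The exact null distribution is used when
    n1 + n2 <= ``exact_total_cap`` and the pooled data are tie-free;
    otherwise the normal approximation with tie and continuity corrections
    applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size + b.size <= exact_total_cap and tie_free:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return ComparisonResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n1=int(a.size),
        n2=int(b.size),
    )


def _pair_statistic(pos: np.ndarray, neg: np.ndarray) -> float:
    """U for pos vs neg via midranks (pairs won + half credit for ties)."""
    pooled = np.concatenate([pos, neg])
    ranks = sps.rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    return float(r_pos - pos.size * (pos.size + 1) / 2.0)


def _roc_points(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points over the pooled score grid for rule score >= threshold.

    Thresholds sweep from above the maximum (no positives called) down
    through every distinct pooled score, so the curve starts at (0, 0) and
    ends at (1, 1).
    """
    grid = np.unique(np.concatenate([pos, neg]))[::-1]
    thresholds = np.concatenate([[np.inf], grid])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    return thresholds, tpr, fpr


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> ROCResult:
    """ROC analysis of positives vs negatives.

    AUC is the normalized pair statistic
    ``(#{pos > neg} + 0.5 * #{pos == neg}) / (n_pos * n_neg)``; the curve
    and the Youden-optimal threshold (ties broken toward the lowest
    threshold) come from a sweep over the pooled score grid.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    auc = _pair_statistic(pos, neg) / (pos.size * neg.size)
    thresholds, tpr, fpr = _roc_points(pos, neg)
    youden = tpr - fpr
    best_j = youden.max()
    # lowest threshold achieving the maximum J (excluding the +inf sentinel
    # unless nothing beats J = 0, in which case the grid minimum is returned)
    finite = thresholds[np.isfinite(thresholds) & (youden >= best_j - 1e-15)]
    best_threshold = float(finite.min()) if finite.size else float(thresholds[-1])
    return ROCResult(
        auc=float(auc),
        thresholds=tuple(float(t) for t in thresholds),
        tpr=tuple(float(t) for t in tpr),
        fpr=tuple(float(f) for f in fpr),
        best_threshold=best_threshold,
    )


def threshold_separation(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Best-separating threshold (max Youden J; ties -> lowest threshold)."""
    return roc_auc(pos, neg).best_threshold


@dataclass(frozen=True)
class BenchmarkReport:
    """Stratified evaluation of one model on one benchmark dataset."""

    model: str
    use_abs: bool
    matched_vs_benign: ComparisonResult
    matched_vs_mismatched: ComparisonResult
    plp_vs_benign: ComparisonResult
    roc: ROCResult

    def to_dict(self) -> dict:
        def comp(c: ComparisonResult) -> dict:
            return {
                "U": c.u_statistic,
                "p": c.p_value,
                "method": c.method,
                "n1": c.n1,
                "n2": c.n2,
            }

        return {
            "model": self.model,
            "use_abs": self.use_abs,
            "matched_vs_benign": comp(self.matched_vs_benign),
            "matched_vs_mismatched": comp(self.matched_vs_mismatched),
            "plp_vs_benign": comp(self.plp_vs_benign),
            "auc": self.roc.auc,
            "best_threshold": self.roc.best_threshold,
            "criterion": self.roc.criterion,
        }


def evaluate_benchmark(dataset, scores, use_abs: bool = True) -> BenchmarkReport:
    """Evaluate effect scores on a grouped benchmark dataset.

    ``dataset`` is a :class:`~utrcensus.benchmark.BenchmarkDataset`;
    ``scores`` a sequence of :class:`~utrcensus.effect_scoring.EffectScore`
    (or a mapping variant key -> EffectScore) covering every dataset item.
    Produces the three pairwise rank-sum comparisons (matched vs benign,
    matched vs mismatched, all P/LP vs benign) and the ROC for matched vs
    benign, on absolute or raw scores per ``use_abs``.
    """
    from .benchmark import Group

    if isinstance(scores, Mapping):
        by_key = dict(scores)
    else:
        by_key = {s.variant_key: s for s in scores}

    missing = [item.key for item in dataset.items if item.key not in by_key]
    if missing:
        raise ValueError(f"missing scores for dataset items: {missing}")

    def values(group_members) -> list[float]:
        return [
            by_key[item.key].abs if use_abs else by_key[item.key].raw
            for item in group_members
        ]

    matched = values([i for i in dataset.items if i.group is Group.PLP_MATCHED])
    mismatched = values([i for i in dataset.items if i.group is Group.PLP_MISMATCHED])
    benign = values([i for i in dataset.items if i.group is Group.BENIGN])

    model = next(iter(by_key.values())).model
    return BenchmarkReport(
        model=model,
        use_abs=use_abs,
        matched_vs_benign=rank_sum_test(matched, benign),
        matched_vs_mismatched=rank_sum_test(matched, mismatched),
        plp_vs_benign=rank_sum_test(matched + mismatched, benign),
        roc=roc_auc(matched, benign),
    )
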