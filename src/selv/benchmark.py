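"""Ranking-performance evaluation of SELV and competitor scores.

ROC and precision-recall curves are built with one threshold per distinct
score value (tied scores move together); the ROC AUC is the trapezoidal
area, equal to the probability that a pathogenic variant out-ranks a
neutral one with ties counting one half.  Paired AUC differences are
tested with DeLong's placement-value procedure, reported as a standardized
D-statistic against the normal distribution.  Distributional and
enrichment questions use the two-sample Kolmogorov-Smirnov test and
Fisher's exact test.

Orientation is always explicit: SELV flags pathogenicity at *low* values
(constrained loci show little population variability), whereas most
competitor predictors flag it at high values.  Nothing here auto-detects
direction.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateComparisonError, DomainError, SingleClassError

__all__ = [
    "HIGHER", "LOWER",
    "RocResult", "PrResult", "AucComparison", "TwoSampleKs", "ContingencyTest",
    "roc", "pr", "compare_auc", "ks_two_sample", "fisher_2x2",
    "benchmark_report",
]

HIGHER = "higher_is_pathogenic"
LOWER = "lower_is_pathogenic"
_ORIENTATIONS = (HIGHER, LOWER)


def _validate(scores, labels, orientation):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise DomainError(
            f"scores and labels must be aligned 1-d sequences, "
            f"got shapes {s.shape} and {y.shape}"
        )
    if np.isnan(s).any():
        raise DomainError("scores contain missing values; drop them pairwise first")
    if not np.isin(y, (0, 1)).all():
        raise DomainError("labels must be 0 (neutral) or 1 (pathogenic)")
    y = y.astype(int)
    if y.min() == y.max():
        raise SingleClassError("both a pathogenic and a neutral label are required")
    if orientation not in _ORIENTATIONS:
        raise DomainError(f"orientation must be one of {_ORIENTATIONS}")
    if orientation == LOWER:
        s = -s
    return s, y


@dataclass
class RocResult:
    """ROC curve: thresholds descending, curve from (0,0) to (1,1)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    orientation: str
    n_positive: int = 0
    n_negative: int = 0


@dataclass
class PrResult:
    """Precision-recall curve with step-wise (average-precision) area."""

    recall: np.ndarray
    precision: np.ndarray
    pr_auc: float
    orientation: str
    n_positive: int = 0
    n_negative: int = 0


@dataclass
class AucComparison:
    """Paired DeLong comparison of two correlated AUCs (pROC's D-statistic)."""

    auc_a: float
    auc_b: float
    d_statistic: float
    p_value: float
    n_paired: int
    var_diff: float = 0.0


@dataclass
class TwoSampleKs:
    d: float
    p_value: float


@dataclass
class ContingencyTest:
    table: np.ndarray
    odds_ratio: float
    p_value: float


def _curve_counts(s: np.ndarray, y: np.ndarray):
    """Cumulative TP/FP at each distinct (oriented) score, descending."""
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    distinct = np.flatnonzero(np.diff(s)) if len(s) else np.array([], int)
    last = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y)[last]
    fp = np.cumsum(1 - y)[last]
    return s[last], tp, fp


def roc(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: str = HIGHER,
) -> RocResult:
    """ROC curve and trapezoidal AUC.

    For ``lower_is_pathogenic`` the scores are negated internally, so the
    stored AUC is always the probability that a pathogenic variant
    out-ranks a neutral one (ties contribute one half).
    """
    s, y = _validate(scores, labels, orientation)
    thresholds, tp, fp = _curve_counts(s, y)
    n_pos, n_neg = int(tp[-1]), int(fp[-1])
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds, fpr, tpr, auc, orientation, n_pos, n_neg)


def pr(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: str = HIGHER,
) -> PrResult:
    """Precision-recall curve; area by the average-precision step rule.

    Precision is held constant over each recall increment, so the area is
    ``sum (R_k - R_{k-1}) * P_k`` over distinct cuts — never the linear
    interpolation, which over-estimates in PR space.
    """
    s, y = _validate(scores, labels, orientation)
    _, tp, fp = _curve_counts(s, y)
    n_pos, n_neg = int(tp[-1]), int(fp[-1])
    recall = tp / n_pos
    precision = tp / (tp + fp)
    pr_auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    # anchor the plotted curve at recall 0, holding the first precision
    recall_pts = np.r_[0.0, recall]
    precision_pts = np.r_[precision[0], precision]
    return PrResult(recall_pts, precision_pts, pr_auc, orientation, n_pos, n_neg)


def _placements(s: np.ndarray, y: np.ndarray):
    """DeLong placement values: per-positive V10 and per-negative V01."""
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    greater = (pos > neg).astype(float) + 0.5 * (pos == neg)
    return greater.mean(axis=1), greater.mean(axis=0)


def compare_auc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    orientation_a: str = HIGHER,
    orientation_b: str = HIGHER,
) -> AucComparison:
    """Paired DeLong test of the difference between two correlated AUCs.

    Both scores must be observed on the same variants (restrict to the
    pairwise-complete subset first).  Placement values give each AUC and
    the covariance of the pair; ``D = (auc_a - auc_b) / sd(diff)`` is
    referred two-sided to the standard normal.  Identical (or monotone
    transformed) score vectors give D = 0, p = 1 by construction.
    """
    sa, y = _validate(scores_a, labels, orientation_a)
    sb, _ = _validate(scores_b, labels, orientation_b)
    m, n = int((y == 1).sum()), int((y == 0).sum())
    if m < 2 or n < 2:
        raise SingleClassError(
            f"need >= 2 observations per class for a variance, got {m} and {n}"
        )
    v10_a, v01_a = _placements(sa, y)
    v10_b, v01_b = _placements(sb, y)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        if abs(diff) > 1e-12:
            raise DegenerateComparisonError(
                f"zero variance of the AUC difference with unequal AUCs "
                f"({auc_a:.6f} vs {auc_b:.6f})"
            )
        d = 0.0
    else:
        d = diff / math.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(d)))
    return AucComparison(auc_a, auc_b, d, p, m + n, max(var_diff, 0.0))


def ks_two_sample(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> TwoSampleKs:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p).

    D is the supremum distance between the two empirical CDFs; used to ask
    whether SELV distributes differently across genomic contexts (e.g.
    splice-site vs non-splice positions).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TwoSampleKs(float(res.statistic), float(res.pvalue))


def fisher_2x2(table) -> ContingencyTest:
    """Fisher's exact test on a 2x2 table of variant counts.

    Two-sided p sums hypergeometric probabilities no larger than the
    observed table's; the odds ratio is the conditional maximum-likelihood
    estimate (infinite for complete separation, reported as ``inf``).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DomainError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise DomainError("table cells must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise DomainError("table cells must be non-negative")
    if t.sum() == 0:
        raise DomainError("table has no observations")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    odds = stats.contingency.odds_ratio(t, kind="conditional").statistic
    return ContingencyTest(t, float(odds), float(p))


_DEFAULT_ORIENTATION = {"selv": LOWER}


def benchmark_report(
    frame: pd.DataFrame,
    score_columns: Sequence[str] | None = None,
    context: str | None = None,
    orientations: dict[str, str] | None = None,
    selv_column: str = "selv",
    label_column: str = "label",
) -> dict:
    """Evaluate SELV and each competitor on a labeled, scored table.

    For every competitor column the evaluation (ROC AUC, PR-AUC and the
    paired DeLong comparison against SELV) is restricted to the variants
    where both that competitor and SELV are observed; dropped counts are
    reported per score.  SELV defaults to ``lower_is_pathogenic``,
    competitors to ``higher_is_pathogenic`` unless overridden.  With no
    competitor columns the report is SELV-only.
    """
    if context is not None:
        frame = frame[frame["context"] == context]
    frame = frame[frame[label_column].notna()]
    orientations = {**_DEFAULT_ORIENTATION, **(orientations or {})}
    if score_columns is None:
        reserved = {
            "contig", "position", "ref", "alt", label_column, "context",
            selv_column, "n_variants", "predicted_class",
        }
        score_columns = [c for c in frame.columns if c not in reserved]
    n_labeled = len(frame)

    def orient(name: str) -> str:
        return orientations.get(name, LOWER if name == selv_column else HIGHER)

    def evaluate(name: str) -> dict:
        sub = frame[frame[name].notna() & frame[selv_column].notna()]
        scores = sub[name].to_numpy(float)
        labels = sub[label_column].to_numpy(int)
        o = orient(name)
        return {
            "auc": roc(scores, labels, o).auc,
            "pr_auc": pr(scores, labels, o).pr_auc,
            "n": len(sub),
            "n_dropped": n_labeled - len(sub),
            "orientation": o,
        }

    report = {
        "context": context,
        "pr_auc_interpolation": "step (average precision)",
        "scores": {selv_column: evaluate(selv_column)},
        "comparisons": {},
    }
    for name in score_columns:
        report["scores"][name] = evaluate(name)
        sub = frame[frame[name].notna() & frame[selv_column].notna()]
        cmp = compare_auc(
            sub[selv_column].to_numpy(float),
            sub[name].to_numpy(float),
            sub[label_column].to_numpy(int),
            orientation_a=orient(selv_column),
            orientation_b=orient(name),
        )
        report["comparisons"][name] = {
            "auc_selv": cmp.auc_a,
            "auc_other": cmp.auc_b,
            "d_statistic": cmp.d_statistic,
            "p_value": cmp.p_value,
            "n_paired": cmp.n_paired,
        }
    return report


def report_table(report: dict) -> pd.DataFrame:
    """Flatten a benchmark report into a human-readable summary table."""
    rows = []
    for name, entry in report["scores"].items():
        cmp = report["comparisons"].get(name, {})
        rows.append({
            "score": name,
            "orientation": entry["orientation"],
            "n": entry["n"],
            "n_dropped": entry["n_dropped"],
            "auc": entry["auc"],
            "pr_auc": entry["pr_auc"],
            "d_vs_selv": cmp.get("d_statistic", np.nan),
            "p_vs_selv": cmp.get("p_value", np.nan),
        })
    return pd.DataFrame(rows)
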