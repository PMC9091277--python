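"""Independent brute-force oracles used to verify the library's results.

Each oracle is written as plainly as possible — term-by-term summation,
exhaustive enumeration, naive ECDF sweeps — and deliberately shares no
code path with the implementation it checks.
"""

import math

import numpy as np
from scipy.stats import hypergeom


def entropy_term_sum(frequencies, log_base=math.e):
    """SELV by literal term-by-term summation of -F_i * log(F_i)."""
    terms = []
    for f in frequencies:
        if f == 0.0 or f == 1.0:
            terms.append(0.0)
        else:
            terms.append(-f * math.log(f) / math.log(log_base))
    return math.fsum(terms)


def auc_pair_count(scores, labels):
    """Mann-Whitney AUC by counting pathogenic-over-neutral pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_cuts(scores, labels):
    """PR area by enumerating every distinct cut, precision held per step."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for cut in sorted(set(scores), reverse=True):
        called = scores >= cut
        tp = int((called & (labels == 1)).sum())
        recall = tp / n_pos
        precision = tp / int(called.sum())
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def youden_exhaustive(scores, labels):
    """Best J over every achievable inclusive cut (lower-is-pathogenic)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    best = -math.inf
    for cut in [-math.inf, *sorted(set(scores)), math.inf]:
        called = scores <= cut
        sens = int((called & (labels == 1)).sum()) / n_pos
        spec = int((~called & (labels == 0)).sum()) / n_neg
        best = max(best, sens + spec - 1.0)
    return best


def ks_ecdf_sweep(a, b):
    """KS D by evaluating both ECDFs at every observed point."""
    a, b = np.sort(np.asarray(a, float)), np.sort(np.asarray(b, float))
    grid = np.unique(np.r_[a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def fisher_enumeration(table):
    """Two-sided Fisher p by full enumeration of fixed-margin tables."""
    (a, b), (c, d) = table
    r1, c1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, total, r1, c1)
    p_obs = hypergeom.pmf(a, total, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def confusion_matrix(scores, labels, threshold, lower_is_pathogenic=True):
    """TP/FN/TN/FP under the inclusive rule, one comparison at a time."""
    tp = fn = tn = fp = 0
    for s, y in zip(scores, labels):
        called = s <= threshold if lower_is_pathogenic else s >= threshold
        if y == 1:
            tp, fn = tp + called, fn + (not called)
        else:
            fp, tn = fp + called, tn + (not called)
    return tp, fn, tn, fp


def bootstrap_auc_diff_var(rng, scores_a, scores_b, labels, reps=2000):
    """Paired, class-stratified bootstrap variance of AUC_a - AUC_b."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    diffs = np.empty(reps)
    for r in range(reps):
        pi = pos[rng.integers(0, len(pos), len(pos))]
        ni = neg[rng.integers(0, len(neg), len(neg))]
        aucs = []
        for s in (scores_a, scores_b):
            ps, ns = s[pi][:, None], s[ni][None, :]
            aucs.append(float((ps > ns).mean() + 0.5 * (ps == ns).mean()))
        diffs[r] = aucs[0] - aucs[1]
    return float(diffs.var(ddof=1))
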