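"""Youden-index threshold calibration and VUS reclassification.

A cut-off for calling a variant pathogenic from its SELV score is chosen
by maximizing the Youden index J = sensitivity + specificity - 1 over all
candidate thresholds (midpoints between consecutive distinct scores, with
-inf/+inf sentinels).  Calibrations are per genomic context — splice-site,
nuclear non-coding and mitochondrial non-coding variants draw their
frequencies from different resources, so each context gets its own
cut-off.  Classification uses the inclusive rule: with the default
lower-is-pathogenic orientation a variant is called pathogenic when its
SELV is less than or equal to the threshold, so a SELV of 0 (a position
with no reported variability) is pathogenic at any positive threshold.

Reported sensitivity and specificity are resubstitution values on the
calibration data, and are labelled as such in the serialized calibration.
"""

from __future__ import annotations

import hashlib
import json
import math
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass

import numpy as np

from .benchmark import HIGHER, LOWER, _ORIENTATIONS
from .errors import DomainError, MissingCalibrationError, SingleClassError

__all__ = [
    "ThresholdCalibration",
    "ClassificationResult",
    "evaluate_at_threshold",
    "youden_threshold",
    "classify",
    "classification_counts",
    "save_calibrations",
    "load_calibrations",
]

PATHOGENIC = "pathogenic"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class ThresholdCalibration:
    """A context-specific decision threshold with its operating point."""

    context: str
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    orientation: str = LOWER
    metric_type: str = "resubstitution"
    calibration_hash: str = ""


@dataclass(frozen=True)
class ClassificationResult:
    variant: object
    selv: float
    predicted: str
    context: str
    threshold_used: float


def _check(scores, labels, orientation):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise DomainError("scores and labels must be aligned 1-d sequences")
    if np.isnan(s).any():
        raise DomainError("scores contain missing values")
    if not np.isin(y, (0, 1)).all():
        raise DomainError("labels must be 0 or 1")
    y = y.astype(int)
    if y.min() == y.max():
        raise SingleClassError("both classes are required")
    if orientation not in _ORIENTATIONS:
        raise DomainError(f"orientation must be one of {_ORIENTATIONS}")
    return s, y


def _predict(scores: np.ndarray, threshold: float, orientation: str) -> np.ndarray:
    """Inclusive decision rule: the threshold itself calls pathogenic."""
    if orientation == LOWER:
        return scores <= threshold
    return scores >= threshold


def evaluate_at_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    orientation: str = LOWER,
) -> tuple[float, float]:
    """Sensitivity and specificity of the inclusive rule at one cut-off."""
    s, y = _check(scores, labels, orientation)
    called = _predict(s, threshold, orientation)
    tp = int((called & (y == 1)).sum())
    tn = int((~called & (y == 0)).sum())
    return tp / int((y == 1).sum()), tn / int((y == 0).sum())


def _candidate_cuts(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.r_[-math.inf, mids, math.inf]


def youden_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: str = LOWER,
    context: str = "unspecified",
) -> ThresholdCalibration:
    """Calibrate a cut-off by maximizing J = sensitivity + specificity - 1.

    Candidate cuts are the midpoints between consecutive distinct scores
    plus -inf/+inf sentinels, so every achievable confusion matrix is
    represented.  Ties on J break toward higher sensitivity (missing a
    pathogenic variant costs more than a false alarm), then toward the
    lower threshold.
    """
    s, y = _check(scores, labels, orientation)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    best = None
    for cut in _candidate_cuts(s):
        called = _predict(s, cut, orientation)
        sens = int((called & (y == 1)).sum()) / n_pos
        spec = int((~called & (y == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -cut)
        if best is None or key > best[0]:
            best = (key, cut, sens, spec, j)
    _, cut, sens, spec, j = best
    return ThresholdCalibration(context, float(cut), sens, spec, j, orientation)


def classify(
    scored: Sequence[tuple[object, float]],
    calibrations: Mapping[str, ThresholdCalibration],
) -> list[ClassificationResult]:
    """Reclassify variants as pathogenic or neutral by context cut-offs.

    *scored* pairs each variant (an object with a ``context`` attribute)
    with its SELV value.  Every context present must have a calibration;
    otherwise the missing contexts are listed in the error.
    """
    contexts = {getattr(v, "context", "unspecified") for v, _ in scored}
    missing = sorted(c for c in contexts if c not in calibrations)
    if missing:
        raise MissingCalibrationError(
            f"no calibration for contexts {missing}; "
            f"available: {sorted(calibrations)}"
        )
    results = []
    for variant, value in scored:
        cal = calibrations[getattr(variant, "context", "unspecified")]
        called = bool(_predict(np.asarray([value]), cal.threshold, cal.orientation)[0])
        results.append(
            ClassificationResult(
                variant, value, PATHOGENIC if called else NEUTRAL,
                cal.context, cal.threshold,
            )
        )
    return results


def classification_counts(
    results: Sequence[ClassificationResult],
) -> dict[str, dict[str, int]]:
    """Per-context counts of pathogenic/neutral calls."""
    counts: dict[str, dict[str, int]] = {}
    for r in results:
        bucket = counts.setdefault(r.context, {PATHOGENIC: 0, NEUTRAL: 0})
        bucket[r.predicted] += 1
    return counts


def _hash_calibration_set(scores, labels) -> str:
    payload = json.dumps(
        [[float(s) for s in scores], [int(y) for y in labels]]
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def calibrate_contexts(
    frames: Mapping[str, tuple[Sequence[float], Sequence[int]]],
    orientation: str = LOWER,
) -> dict[str, ThresholdCalibration]:
    """Youden-calibrate one threshold per context from (scores, labels).

    Each calibration records a short hash of its calibration set so a
    classification run can be traced back to the data that set its cut-off.
    """
    out = {}
    for context, (scores, labels) in frames.items():
        cal = youden_threshold(scores, labels, orientation, context)
        out[context] = ThresholdCalibration(
            **{**asdict(cal), "calibration_hash": _hash_calibration_set(scores, labels)}
        )
    return out


def save_calibrations(
    calibrations: Mapping[str, ThresholdCalibration], path
) -> None:
    doc = {context: asdict(cal) for context, cal in calibrations.items()}
    with open(path, "w") as out:
        json.dump(doc, out, indent=2)
        out.write("\n")


def load_calibrations(path) -> dict[str, ThresholdCalibration]:
    with open(path) as src:
        doc = json.load(src)
    return {context: ThresholdCalibration(**entry) for context, entry in doc.items()}
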