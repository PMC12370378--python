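"""Scoring of detections against reference positions and image metrics.

Detection is scored by one-to-one optimal assignment between detected
and reference marker positions within a distance gate; the detection
rate uses the reference marker count as denominator and displacement
statistics are computed on matched pairs only. The image-agreement
metrics (signed mean error, mean absolute error, Dice coefficient) are
the standard quantitative QA surface for synthetic-CT style comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class EvalReport:
    n_truth: int
    n_detected: int
    n_matched: int
    detection_rate: float
    displacements_mm: np.ndarray
    mean_displacement_mm: float
    false_positives: list[int] = dc_field(default_factory=list)   # detection indices
    false_negatives: list[int] = dc_field(default_factory=list)   # truth indices
    matches: list[tuple[int, int]] = dc_field(default_factory=list)


def match_markers(
    detected: np.ndarray, truth: np.ndarray, gate_mm: float = 5.0
) -> EvalReport:
    """Optimal one-to-one matching of detected to reference positions.

    Hungarian assignment minimizing total Euclidean distance among pairs
    within `gate_mm`; unmatched detections are false positives, unmatched
    references false negatives. Displacement statistics consider matched
    pairs only.
    """
    if gate_mm <= 0:
        raise ValueError("gate_mm must be > 0")
    det = np.asarray(detected, dtype=float).reshape(-1, 3)
    tru = np.asarray(truth, dtype=float).reshape(-1, 3)
    n_d, n_t = len(det), len(tru)
    matches: list[tuple[int, int]] = []
    if n_d and n_t:
        dist = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=-1)
        big = gate_mm * max(n_d, n_t) * 10.0 + 1.0
        cost = np.where(dist <= gate_mm, dist, big)
        rows, cols = linear_sum_assignment(cost)
        matches = [
            (int(i), int(j)) for i, j in zip(rows, cols) if dist[i, j] <= gate_mm
        ]
    disp = np.array(
        [np.linalg.norm(det[i] - tru[j]) for i, j in matches], dtype=float
    )
    matched_d = {i for i, _ in matches}
    matched_t = {j for _, j in matches}
    return EvalReport(
        n_truth=n_t,
        n_detected=n_d,
        n_matched=len(matches),
        detection_rate=len(matches) / n_t if n_t else 0.0,
        displacements_mm=disp,
        mean_displacement_mm=float(disp.mean()) if disp.size else float("nan"),
        false_positives=sorted(set(range(n_d)) - matched_d),
        false_negatives=sorted(set(range(n_t)) - matched_t),
        matches=matches,
    )


def mean_error(img_a, img_b, mask=None):
    """Signed mean difference a - b over the mask; returns (ME, SD)."""
    diff = _masked_diff(img_a, img_b, mask)
    return float(diff.mean()), float(diff.std())


def mean_absolute_error(img_a, img_b, mask=None) -> float:
    """Mean of |a - b| over the mask."""
    return float(np.abs(_masked_diff(img_a, img_b, mask)).mean())


def _masked_diff(img_a, img_b, mask):
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    diff = a - b
    if mask is not None:
        diff = diff[np.asarray(mask, dtype=bool)]
    if diff.size == 0:
        raise ValueError("empty comparison region")
    return diff


def dice(mask_a, mask_b) -> float:
    """Dice similarity coefficient 2|A&B| / (|A| + |B|).

    Defined as 1.0 when both masks are empty (identical emptiness).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total
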