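"""Agreement, precision, area and repeatability metrics.

These implement the evaluation vocabulary used to compare automated and
human soma contours: Sorensen-Dice overlap between binary masks, a
per-manual-region best-match search (a region counts as detected when its
best Dice exceeds 0.5), yield rate and precision arithmetic, polygon areas
by the shoelace formula, the average overlapping ratio for repeated
measurements of one soma, and a STAPLE expectation-maximization consensus
across annotators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedMetricError
from .io_formats import Contour, SomaAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "MatchRow",
    "MatchTable",
    "MetricsReport",
    "ConsensusResult",
    "dice",
    "match_regions",
    "yield_rate",
    "precision_from_counts",
    "union_count",
    "shoelace_area",
    "avg_overlapping",
    "staple",
    "compile_report",
]


@dataclass(frozen=True)
class MatchRow:
    manual_region_id: str
    best_detected_id: int | None
    best_dice: float
    matched: bool


@dataclass
class MatchTable:
    """One row per manual region; ``matched`` iff best_dice > threshold."""

    rows: list[MatchRow]
    dice_threshold: float = 0.5

    @property
    def n_matched(self) -> int:
        return sum(r.matched for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


@dataclass
class MetricsReport:
    n_manual: int
    n_detected: int
    n_matched: int
    yield_rate_pct: float
    mean_dice: float
    area_pairs: pd.DataFrame  # manual_area_um2, detected_area_um2, mean_intensity
    mean_area_difference: float
    sd_area_difference: float
    area_correlation: float
    empty: bool = False

    def to_json_dict(self) -> dict:
        return {
            "n_manual": self.n_manual,
            "n_detected": self.n_detected,
            "n_matched": self.n_matched,
            "yield_rate_pct": round(self.yield_rate_pct),
            "yield_rate_pct_raw": self.yield_rate_pct,
            "mean_dice": self.mean_dice,
            "mean_area_difference": self.mean_area_difference,
            "sd_area_difference": self.sd_area_difference,
            "area_correlation": self.area_correlation,
            "empty": self.empty,
        }


@dataclass
class ConsensusResult:
    consensus: np.ndarray
    sensitivity: np.ndarray  # p_j per rater
    specificity: np.ndarray  # q_j per rater
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Sorensen-Dice coefficient ``2|X n Y| / (|X| + |Y|)``.

    1 means identical masks, 0 no pixels in common.  Two empty masks are an
    error, not a convention value.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ContractError(f"mask shapes differ: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        raise UndefinedMetricError("Dice of two empty masks is undefined")
    return 2.0 * int((x & y).sum()) / (nx + ny)


def match_regions(
    manual: list[SomaAnnotation],
    detected,
    shape: tuple[int, int] | None = None,
    dice_threshold: float = 0.5,
) -> MatchTable:
    """Best-overlap search from each manual region into the detections.

    For every manual region the detection with the highest Dice is found; a
    match requires that best Dice to be *strictly* greater than the
    threshold (0.5 by default).  The search is per manual region, so one
    detection may be the best match of several manual regions; such
    collisions are counted and logged.

    ``detected`` is a :class:`~somaseg.detector.DetectionSet` or any object
    with a ``masks()`` method; ``shape`` is required when manual masks are
    not rasterized yet and no detection provides one.
    """
    det_masks = detected.masks() if hasattr(detected, "masks") else list(detected)
    if shape is None:
        if det_masks:
            shape = det_masks[0].shape
        elif manual and manual[0].mask is not None:
            shape = manual[0].mask.shape
        else:
            raise ContractError("cannot infer the raster shape; pass shape=")
    for m in det_masks:
        if m.shape != tuple(shape):
            raise ContractError("detected masks are not in the manual frame")
    rows = []
    best_of: dict[int, int] = {}
    for ann in manual:
        mmask = ann.get_mask(shape)
        best_dice, best_idx = 0.0, None
        for i, dmask in enumerate(det_masks):
            if not dmask.any():
                continue
            d = dice(mmask, dmask)
            if d > best_dice:
                best_dice, best_idx = d, i
        matched = best_dice > dice_threshold
        if matched and best_idx is not None:
            best_of[best_idx] = best_of.get(best_idx, 0) + 1
        rows.append(MatchRow(ann.region_id, best_idx, best_dice, matched))
    collisions = sum(c - 1 for c in best_of.values() if c > 1)
    if collisions:
        logger.info(
            "%d manual regions share their best detection with another", collisions
        )
    return MatchTable(rows, dice_threshold)


def yield_rate(n_matched: int, n_manual: int) -> float:
    """Percentage of manual regions detected: ``100 * n_matched / n_manual``.

    The raw percentage is returned; reports round it to the nearest integer
    percent for display.
    """
    if n_manual <= 0:
        raise ValueError("n_manual must be > 0")
    if not 0 <= n_matched <= n_manual:
        raise ValueError("need 0 <= n_matched <= n_manual")
    return 100.0 * n_matched / n_manual


def precision_from_counts(true_positive: int, total_detected: int) -> float:
    """Fraction of detections that are real somata: ``tp / total``."""
    if total_detected <= 0:
        raise ValueError("total_detected must be > 0")
    if not 0 <= true_positive <= total_detected:
        raise ValueError("need 0 <= tp <= total")
    return true_positive / total_detected


def union_count(n_a: int, n_b: int, n_common: int) -> int:
    """Unique regions labeled by two annotators: ``n_a + n_b - n_common``."""
    if n_common > min(n_a, n_b) or min(n_a, n_b, n_common) < 0:
        raise ValueError("n_common cannot exceed either annotator's count")
    return n_a + n_b - n_common


def shoelace_area(contour: Contour, pixel_size_um: float = 1.0) -> float:
    """Polygon area by the shoelace formula, in um^2.

    Half the absolute cyclic cross-sum of the ordered vertices, scaled by
    the squared pixel size; independent of vertex orientation.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    cross = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    return 0.5 * abs(float(cross)) * pixel_size_um**2


def avg_overlapping(masks: list[np.ndarray]) -> float:
    """Repeatability of repeated contours of one soma.

    The mean, over the repeated masks, of (pixels common to all masks) /
    (pixels of that mask); 1 means the repeats are identical.  Designed for
    the five-trial protocol but accepts any count >= 2.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 repeated masks")
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if any(m.shape != masks[0].shape for m in masks):
        raise ContractError("repeated masks must share one shape")
    if any(not m.any() for m in masks):
        raise UndefinedMetricError("average overlapping undefined for empty masks")
    common = masks[0].copy()
    for m in masks[1:]:
        common &= m
    n_common = int(common.sum())
    return float(np.mean([n_common / int(m.sum()) for m in masks]))


# ---------------------------------------------------------------------------
# STAPLE consensus
# ---------------------------------------------------------------------------


def staple(
    masks: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 100,
    prior: float | None = None,
) -> ConsensusResult:
    """Simultaneous truth and performance level estimation.

    EM on the standard STAPLE model: each rater ``j`` has an unknown
    sensitivity ``p_j`` and specificity ``q_j``; the E-step computes the
    per-pixel posterior probability ``W_i`` that the true segmentation is
    foreground given the decisions ``d_ij`` and a scalar foreground prior
    (the mean rater foreground fraction unless given); the M-step
    re-estimates ``(p_j, q_j)`` from the weights.  Iteration stops when the
    largest parameter change drops below ``tol``; the consensus is
    ``W >= 0.5``.
    """
    if len(masks) < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    D = np.stack([np.asarray(m, dtype=bool).ravel() for m in masks]).astype(float)
    n_raters, n_pixels = D.shape
    if prior is None:
        prior = float(D.mean())
    lo, hi = 1e-6, 1 - 1e-6
    prior = float(np.clip(prior, lo, hi))
    p = np.full(n_raters, 0.9999)
    q = np.full(n_raters, 0.9999)
    converged = False
    it = 0
    W = np.full(n_pixels, prior)
    for it in range(1, max_iter + 1):
        # E-step
        log_a = np.log(prior) + (
            D * np.log(p[:, None]) + (1 - D) * np.log(1 - p[:, None])
        ).sum(axis=0)
        log_b = np.log(1 - prior) + (
            (1 - D) * np.log(q[:, None]) + D * np.log(1 - q[:, None])
        ).sum(axis=0)
        m = np.maximum(log_a, log_b)
        a = np.exp(log_a - m)
        b = np.exp(log_b - m)
        W = a / (a + b)
        # M-step
        sw = W.sum()
        swc = (1 - W).sum()
        new_p = np.clip((D * W).sum(axis=1) / max(sw, lo), lo, hi)
        new_q = np.clip(((1 - D) * (1 - W)).sum(axis=1) / max(swc, lo), lo, hi)
        delta = max(np.abs(new_p - p).max(), np.abs(new_q - q).max())
        p, q = new_p, new_q
        if delta < tol:
            converged = True
            break
    consensus = (W >= 0.5).reshape(masks[0].shape)
    return ConsensusResult(consensus, p, q, it, converged)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def compile_report(
    match_table: MatchTable,
    manual: list[SomaAnnotation],
    detected,
    image: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
) -> MetricsReport:
    """Aggregate a match table into the headline agreement numbers.

    Yield rate, mean matched Dice, paired shoelace areas (manual vs
    detected, in um^2) with per-soma mean intensity when an image is given,
    and descriptive statistics of the area differences (mean, SD, Pearson
    correlation).  An empty match table produces a flagged empty report.
    """
    n_manual = len(match_table.rows)
    det_list = detected.detections if hasattr(detected, "detections") else detected
    n_detected = len(det_list)
    n_matched = match_table.n_matched
    pairs = []
    by_id = {ann.region_id: ann for ann in manual}
    for row in match_table.rows:
        if not row.matched or row.best_detected_id is None:
            continue
        ann = by_id[row.manual_region_id]
        det = det_list[row.best_detected_id]
        manual_area = shoelace_area(ann.contour, pixel_size_um)
        detected_area = shoelace_area(det.contour, pixel_size_um)
        intensity = float(image[det.mask].mean()) if image is not None else np.nan
        pairs.append(
            {
                "manual_region_id": row.manual_region_id,
                "manual_area_um2": manual_area,
                "detected_area_um2": detected_area,
                "mean_intensity": intensity,
                "dice": row.best_dice,
            }
        )
    area_pairs = pd.DataFrame(
        pairs,
        columns=[
            "manual_region_id", "manual_area_um2", "detected_area_um2",
            "mean_intensity", "dice",
        ],
    )
    if not pairs:
        logger.warning("no matched pairs; report statistics are empty")
        return MetricsReport(
            n_manual=n_manual, n_detected=n_detected, n_matched=0,
            yield_rate_pct=0.0 if n_manual else float("nan"),
            mean_dice=float("nan"), area_pairs=area_pairs,
            mean_area_difference=float("nan"), sd_area_difference=float("nan"),
            area_correlation=float("nan"), empty=True,
        )
    diff = area_pairs["detected_area_um2"] - area_pairs["manual_area_um2"]
    if len(pairs) > 1 and area_pairs["manual_area_um2"].std() > 0:
        corr = float(
            np.corrcoef(
                area_pairs["manual_area_um2"], area_pairs["detected_area_um2"]
            )[0, 1]
        )
    else:
        corr = float("nan")
    return MetricsReport(
        n_manual=n_manual,
        n_detected=n_detected,
        n_matched=n_matched,
        yield_rate_pct=yield_rate(n_matched, n_manual) if n_manual else float("nan"),
        mean_dice=float(area_pairs["dice"].mean()),
        area_pairs=area_pairs,
        mean_area_difference=float(diff.mean()),
        sd_area_difference=float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
        area_correlation=corr,
    )
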