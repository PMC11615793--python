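"""Segmentation evaluation metrics and between-group comparisons.

Four metrics summarise how well a predicted intracranial mask matches its
annotation: voxel-wise accuracy, the Dice similarity coefficient
(DSC = 2|A∩B| / (|A|+|B|)), and the symmetric Hausdorff distance in voxel
units and in physical millimetres (``hd_physical = hd_voxel * spacing`` on
an isotropic grid).

Conventions: two empty masks have DSC 1.0 and one-empty pairs DSC 0.0; the
Hausdorff distance of an empty mask is an error (not infinity), so empty
predictions cannot silently corrupt summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .volumes import BinaryMask

__all__ = [
    "SegEval",
    "dsc",
    "voxel_accuracy",
    "hausdorff",
    "evaluate_segmentation",
    "compare_groups",
    "flag_outliers",
    "rank_sum_test",
]


@dataclass(frozen=True)
class SegEval:
    """Per-volume metric bundle for one prediction/annotation pair."""

    voxel_accuracy: float
    dsc: float
    hd_voxel: float
    hd_physical: float


def _check_grids(a: BinaryMask, b: BinaryMask) -> None:
    if tuple(a.shape) != tuple(b.shape) or not np.isclose(
        a.spacing_mm, b.spacing_mm
    ):
        raise ValueError(
            f"grid mismatch: {a.shape}@{a.spacing_mm} vs {b.shape}@{b.spacing_mm}"
        )


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); both-empty -> 1.0."""
    _check_grids(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.sum((a.data > 0) & (b.data > 0)))
    return 2.0 * inter / (na + nb)


def voxel_accuracy(a: BinaryMask, b: BinaryMask) -> float:
    """Fraction of voxels with equal labels."""
    _check_grids(a, b)
    return float(np.mean(a.data == b.data))


def hausdorff(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """Symmetric Hausdorff distance between the labelled point sets.

    Returns ``(hd_voxel, hd_physical)`` using the Euclidean metric on voxel
    indices and on physical coordinates respectively.  Raises ``ValueError``
    if either mask is empty (the distance is undefined).
    """
    _check_grids(a, b)
    pa = np.argwhere(a.data > 0)
    pb = np.argwhere(b.data > 0)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("Hausdorff distance undefined for empty masks")
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab = tb.query(pa, k=1)[0].max()
    d_ba = ta.query(pb, k=1)[0].max()
    hd_vox = float(max(d_ab, d_ba))
    return hd_vox, hd_vox * a.spacing_mm


def evaluate_segmentation(pred: BinaryMask, truth: BinaryMask) -> SegEval:
    """Bundle all four metrics for one prediction/annotation pair."""
    hd_vox, hd_mm = hausdorff(pred, truth)
    return SegEval(
        voxel_accuracy=voxel_accuracy(pred, truth),
        dsc=dsc(pred, truth),
        hd_voxel=hd_vox,
        hd_physical=hd_mm,
    )


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; exact null distribution for small
    tie-free samples (both n <= 25), normal approximation with continuity
    correction otherwise.  Returns ``(statistic, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 25 and len(y) <= 25
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


_METRIC_FIELDS = ("voxel_accuracy", "dsc", "hd_voxel", "hd_physical")


def compare_groups(
    evals_20w: list[SegEval], evals_30w: list[SegEval], alpha: float = 0.05
) -> dict:
    """Rank-sum comparison of the two gestational-age groups per metric.

    Returns ``{metric: {"statistic", "p", "significant"}}``.
    """
    if not evals_20w or not evals_30w:
        raise ValueError("both groups must be non-empty")
    report = {}
    for f in _METRIC_FIELDS:
        x = [getattr(e, f) for e in evals_20w]
        y = [getattr(e, f) for e in evals_30w]
        stat, p = rank_sum_test(x, y)
        report[f] = {"statistic": stat, "p": p, "significant": bool(p < alpha)}
    return report


def flag_outliers(evals: list[SegEval]) -> dict:
    """Boxplot-rule (1.5 IQR) outlier indices per metric distribution.

    ``hd_physical`` is deliberately excluded: across gestational ages the
    relative contour distance at a common voxel size is the comparable
    quantity, not the absolute physical distance.
    """
    out = {}
    for f in _METRIC_FIELDS:
        if f == "hd_physical":
            continue
        vals = np.array([getattr(e, f) for e in evals], dtype=float)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out[f] = [int(i) for i in np.nonzero((vals < lo) | (vals > hi))[0]]
    return out
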