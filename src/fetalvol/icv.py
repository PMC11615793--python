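"""Intracranial-volume measurement and the automated quality-control gate.

The measurement is the voxel count of the predicted mask times the physical
voxel volume: ``V = N * S`` with S = spacing³ mm³, converted to millilitres.

Quality control is template-based and fully automatic: the scan is
affine-registered to the gestational-age-specific template, the template's
intracranial mask is mapped back into the scan's native space through the
inverse affine, and the Dice overlap between the predicted mask and the
mapped template mask is the QC score.  Scans are retained only when the
score strictly exceeds the threshold (default 0.90).  Registration failures
yield score 0 with a recorded reason instead of raising, so batch runs over
heterogeneous sweeps (non-brain, partial coverage) complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .metrics import dsc
from .preprocess import AgeTemplate, apply_transform, register_affine
from .volumes import BinaryMask, Volume

__all__ = [
    "ICVResult",
    "compute_icv",
    "qc_score",
    "qc_gate",
    "choose_template",
    "DEFAULT_QC_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_QC_THRESHOLD = 0.90

#: wave centre ages (days) used to pick the nearest template
WAVE_CENTRE_AGE_DAYS = {"20w": 155.0, "30w": 211.5}


@dataclass(frozen=True)
class ICVResult:
    """Per-scan measurement record."""

    scan_id: str
    subject_id: str
    wave: str
    age_days: int
    n_voxels: int
    icv_ml: float
    qc_dsc: float
    qc_pass: bool


def compute_icv(m: BinaryMask) -> float:
    """V = N · spacing³, in millilitres (mm³ / 1000)."""
    return m.n_voxels * m.grid.voxel_volume_ml


def choose_template(age_days: float, templates: dict) -> AgeTemplate:
    """Template whose wave centre age is nearest to the scan's age."""
    if age_days is None:
        raise ValueError("gestational age required to choose a template")
    wave = min(
        WAVE_CENTRE_AGE_DAYS,
        key=lambda w: abs(WAVE_CENTRE_AGE_DAYS[w] - float(age_days)),
    )
    if wave not in templates:
        raise KeyError(f"no template for wave {wave}")
    return templates[wave]


def qc_score(pred: BinaryMask, v: Volume, template: AgeTemplate) -> float:
    """Template-overlap QC score of a predicted mask on its scan.

    Registers the scan to the template volume, maps the template mask into
    native space via the inverse affine, and returns its Dice overlap with
    the prediction.  A failed registration scores 0 (logged), not an
    exception.
    """
    if tuple(pred.shape) != tuple(v.shape):
        raise ValueError("prediction must live on the scan's grid")
    try:
        t = register_affine(v, template.template_volume, dof=12)
        mapped = apply_transform(
            template.template_mask, t.inverse(), reference_grid=v.grid
        )
        return dsc(pred, mapped)
    except Exception as exc:  # registration failure is a QC failure
        logger.warning("QC registration failed (%s); scoring 0", exc)
        return 0.0


def qc_gate(results, threshold: float = DEFAULT_QC_THRESHOLD):
    """Retain results with ``qc_dsc`` strictly above the threshold.

    Returns ``(retained, report)`` where the report carries scan and
    subject retention counts.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    results = list(results)
    retained = [r for r in results if r.qc_dsc > threshold]
    subjects_in = {r.subject_id for r in results}
    subjects_kept = {r.subject_id for r in retained}
    report = {
        "n_scans": len(results),
        "n_scans_retained": len(retained),
        "scan_retention": len(retained) / len(results) if results else 0.0,
        "n_subjects": len(subjects_in),
        "n_subjects_retained": len(subjects_kept),
        "subject_retention": len(subjects_kept) / len(subjects_in)
        if subjects_in
        else 0.0,
    }
    return retained, report
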