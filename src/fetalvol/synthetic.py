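"""Synthetic data: ultrasound-like head phantoms and simulated cohorts.

Two generators stand in for data that cannot be redistributed:

* :func:`make_phantom` builds a 3D head phantom — an ellipsoidal skull with a
  bright shell, a mid-intensity interior, darker banded background tissue,
  multiplicative speckle and an optional acoustic-shadow cone — together with
  the ground-truth intracranial mask (every voxel strictly inside the inner
  skull surface) and the analytic intracranial volume implied by that mask.
* :func:`simulate_cohort` draws a two-wave longitudinal cohort whose age
  distributions, age-adjusted sex effects on intracranial volume (ICV) and
  per-sex daily growth-rate distributions follow the demographic structure of
  a large fetal ultrasound cohort measured around 20 and 30 weeks of
  gestation.

Cohort model
------------
Sweep-level ICV at a wave is ``wave_mean(age) + sex_effect * 1[boy] +
subject_intercept + sweep_noise``, where ``wave_mean`` is a quadratic in age
centred at the wave's mean age.  In longitudinal mode the wave-2 value is
instead ``wave-1 value + rate * interval`` with a per-subject daily growth
rate drawn from the sex-specific rate distribution.  The two modes are
deliberately not forced to agree: they emulate a per-wave cross-sectional
subsample and a longitudinal best-scan subsample, which in real cohorts are
different selections.

Default parameters (ages in days, volumes in mL):

===================  ==========================  =========================
quantity             girls                        boys
===================  ==========================  =========================
wave-1 age           155.7 ± 6.2                  154.4 ± 6.2
wave-2 age           211.6 ± 5.7                  211.4 ± 5.8
interval             56.7 ± 7.8 (shared)
growth rate          3.03 ± 0.39 mL/day           3.15 ± 0.40 mL/day
sex effect           wave 1: +2.86 mL, wave 2: +12.35 mL (boys)
===================  ==========================  =========================

The wave mean-ICV curves are anchored so the marginal per-sex means emerge
from the age-adjusted sex effect plus the small per-sex age gap: at wave 1,
girls' mean ICV at age 155.0 d is 79.75 mL with a local slope of 1.5 mL/day
(so girls average 80.8 mL at 155.7 d and boys 81.7 mL at 154.4 d); at wave 2
girls' mean at 211.5 d is 244.65 mL with slope 4.5 mL/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volumes import BinaryMask, Volume, VolumeGrid

__all__ = [
    "PhantomSpec",
    "WaveIcvCurve",
    "CohortSpec",
    "make_phantom",
    "make_annotated_set",
    "simulate_cohort",
    "COHORT_COLUMNS",
]

#: plausible gestational-age range (days) for generated ages
AGE_RANGE_DAYS = (120, 240)

#: reference mean intracranial volumes (mL) of the two waves; phantom head
#: sizes are scaled so their ratio (≈ 3.09) is preserved on small grids
REFERENCE_WAVE_ICV_ML = {"20w": 81.3, "30w": 250.9}


# ---------------------------------------------------------------------------
# Head phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one ultrasound-like head phantom.

    The head is an ellipsoid with outer semi-axes ``head_semiaxes_mm`` whose
    shell of thickness ``skull_thickness_mm`` is bright; the ground-truth
    intracranial mask is everything strictly inside the shell's inner
    surface.  ``pose`` rotates (degrees, about the grid centre) and
    translates (mm) the head.
    """

    grid: VolumeGrid
    head_semiaxes_mm: tuple[float, float, float]
    skull_thickness_mm: float = 1.5
    interior_intensity: float = 0.45
    skull_intensity: float = 0.95
    background_intensity: float = 0.18
    speckle_strength: float = 0.3
    shadow: bool = False
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.head_semiaxes_mm):
            raise ValueError("head semi-axes must be positive")
        if not self.skull_thickness_mm > 0:
            raise ValueError("skull thickness must be positive")
        if any(a <= self.skull_thickness_mm for a in self.head_semiaxes_mm):
            raise ValueError("semi-axes must exceed the skull thickness")
        if not 0.0 <= self.speckle_strength <= 1.0:
            raise ValueError("speckle_strength must be in [0, 1]")


def _rotation_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def make_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask, float]:
    """Render a phantom; returns ``(volume, truth_mask, true_icv_ml)``.

    ``true_icv_ml`` is the mask voxel count times the voxel volume in mL,
    i.e. exactly what a perfect segmentation would measure.  Fully
    deterministic given ``spec`` (including its ``seed``).
    """
    grid = spec.grid
    spacing = grid.spacing_mm
    shape = grid.shape
    rng = np.random.default_rng(spec.seed)

    centre = (np.array(shape, dtype=float) - 1.0) / 2.0 * spacing
    head_centre = centre + np.asarray(spec.translation_mm, dtype=float)
    semi = np.asarray(spec.head_semiaxes_mm, dtype=float)

    # head must fit inside the grid after the pose
    extent = np.array(shape, dtype=float) * spacing
    if np.any(head_centre - semi.max() < -0.5 * spacing) or np.any(
        head_centre + semi.max() > extent - 0.5 * spacing
    ):
        raise ValueError("head does not fit inside the grid for this pose")

    idx = np.indices(shape, dtype=np.float64)
    coords = idx * spacing  # (3, X, Y, Z) physical coordinates
    rel = coords - head_centre.reshape(3, 1, 1, 1)
    rot = _rotation_matrix(spec.rotation_deg)
    # body-frame coordinates: p' = R^T (x - c)
    body = np.einsum("ji,jxyz->ixyz", rot, rel)

    e_outer = np.sum((body / semi.reshape(3, 1, 1, 1)) ** 2, axis=0)
    inner_semi = semi - spec.skull_thickness_mm
    e_inner = np.sum((body / inner_semi.reshape(3, 1, 1, 1)) ** 2, axis=0)

    mask = e_inner < 1.0
    shell = (e_outer <= 1.0) & ~mask

    # background: darker tissue with bands that move with the anatomy
    bands = 0.06 * np.sin(2.0 * np.pi * body[2] / (8.0 * spacing + 4.0))
    img = spec.background_intensity + bands
    img[mask] = spec.interior_intensity
    img[shell] = spec.skull_intensity

    if spec.shadow:
        # acoustic shadow: attenuate the cone "below" the skull (+z)
        below = body[2] > 0.0
        lateral = np.sqrt(body[0] ** 2 + body[1] ** 2)
        cone = below & (e_outer > 1.0) & (lateral < 0.6 * semi[:2].mean())
        img[cone] *= 0.35

    if spec.speckle_strength > 0:
        noise = rng.standard_normal(shape)
        noise = np.clip(noise, -2.5, 2.5)
        img = img * (1.0 + 0.25 * spec.speckle_strength * noise)
        img = np.clip(img, 0.0, None)

    volume = Volume(img, grid)
    truth = BinaryMask(mask.astype(np.uint8), grid)
    true_icv_ml = truth.n_voxels * grid.voxel_volume_ml
    return volume, truth, true_icv_ml


def _default_grid() -> VolumeGrid:
    return VolumeGrid((32, 32, 32), 1.0)


def make_annotated_set(
    n_per_wave: int,
    seed: int = 0,
    grid: VolumeGrid | None = None,
    speckle_strength: float = 0.3,
) -> list[tuple[Volume, BinaryMask, str]]:
    """Generate an annotated phantom set with two gestational-age waves.

    Head sizes are drawn so the wave-mean true ICVs keep the reference
    30-week/20-week ratio of ≈ 3.09; on small grids the absolute volumes are
    scaled down proportionally so the larger head still fits.  Each phantom
    gets a randomized pose (rotation up to ±15°, translation up to ±5% of
    the field of view).
    """
    if n_per_wave < 1:
        raise ValueError(f"n_per_wave must be >= 1, got {n_per_wave}")
    grid = grid or _default_grid()
    rng = np.random.default_rng(seed)

    min_extent = min(grid.extent_mm)
    thickness = 1.2 * grid.spacing_mm
    # mean equivalent *inner* radius of the larger (30w) head: the outer
    # shell fills ~2/3 of the field of view; the intracranial radii keep
    # the reference 30w/20w volume ratio
    r30 = 0.335 * min_extent - thickness
    ratio = REFERENCE_WAVE_ICV_ML["30w"] / REFERENCE_WAVE_ICV_ML["20w"]
    r20 = r30 / ratio ** (1.0 / 3.0)
    radius = {"20w": r20, "30w": r30}
    # mildly aspherical, volume-preserving axis ratios
    axis_ratio = np.array([1.12, 1.0, 0.9])
    axis_ratio /= np.prod(axis_ratio) ** (1.0 / 3.0)

    out: list[tuple[Volume, BinaryMask, str]] = []
    for wave in ("20w", "30w"):
        for _ in range(n_per_wave):
            r = radius[wave] * (1.0 + rng.uniform(-0.08, 0.08))
            semi = tuple(r * axis_ratio + thickness)
            rot = tuple(rng.uniform(-15.0, 15.0, size=3))
            tmax = 0.05 * min_extent
            trans = tuple(rng.uniform(-tmax, tmax, size=3))
            spec = PhantomSpec(
                grid=grid,
                head_semiaxes_mm=semi,
                skull_thickness_mm=thickness,
                speckle_strength=speckle_strength,
                shadow=bool(rng.random() < 0.5),
                rotation_deg=rot,
                translation_mm=trans,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, mask, _ = make_phantom(spec)
            out.append((vol, mask, wave))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveIcvCurve:
    """Mean ICV (mL) of girls at a wave as a quadratic in age (days),
    centred at ``centre_age_days``."""

    centre_age_days: float
    intercept_ml: float
    slope_ml_per_day: float
    quad_ml_per_day2: float

    def __call__(self, age_days) -> np.ndarray:
        d = np.asarray(age_days, dtype=float) - self.centre_age_days
        return self.intercept_ml + self.slope_ml_per_day * d + self.quad_ml_per_day2 * d**2


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated two-wave cohort (defaults documented in
    the module docstring)."""

    n_subjects: int = 1000
    boy_fraction: float = 0.51
    wave1_age_days: dict = field(
        default_factory=lambda: {"girl": (155.7, 6.2), "boy": (154.4, 6.2)}
    )
    wave2_age_days: dict = field(
        default_factory=lambda: {"girl": (211.6, 5.7), "boy": (211.4, 5.8)}
    )
    interval_days: tuple[float, float] = (56.7, 7.8)
    wave_mean_icv: dict = field(
        default_factory=lambda: {
            "20w": WaveIcvCurve(155.0, 79.75, 1.5, 0.02),
            "30w": WaveIcvCurve(211.5, 244.65, 4.5, 0.03),
        }
    )
    sex_effect_ml: dict = field(
        default_factory=lambda: {"20w": 2.86, "30w": 12.35}
    )
    growth_rate: dict = field(
        default_factory=lambda: {"girl": (3.03, 0.39), "boy": (3.15, 0.40)}
    )
    subject_sd_ml: float = 8.0
    sweep_sd_ml: float = 4.0
    sweeps_per_wave: int = 3
    qc_pass_fraction: float = 0.23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if not 0.0 < self.boy_fraction < 1.0:
            raise ValueError("boy_fraction must be in (0, 1)")
        for sd in (self.subject_sd_ml, self.sweep_sd_ml, self.interval_days[1]):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.sweeps_per_wave < 1:
            raise ValueError("sweeps_per_wave must be >= 1")

    def with_(self, **kw) -> "CohortSpec":
        return replace(self, **kw)


COHORT_COLUMNS = ["subject_id", "sex", "wave", "age_days", "icv_ml", "qc_dsc"]

_AGE_CLIP = {"20w": (140, 171), "30w": (199, 230)}


def _draw_age(rng, mean_sd, wave) -> int:
    lo, hi = _AGE_CLIP[wave]
    a = rng.normal(mean_sd[0], mean_sd[1])
    return int(np.clip(np.rint(a), lo, hi))


def _draw_qc(rng, pass_fraction: float) -> float:
    if rng.random() < pass_fraction:
        return float(rng.uniform(0.905, 0.99))
    return float(rng.uniform(0.25, 0.90))


def _n_sweeps(rng, mean: int) -> int:
    return max(1, int(rng.poisson(mean)))


def simulate_cohort(spec: CohortSpec, mode: str = "per_wave") -> pd.DataFrame:
    """Simulate sweep-level cohort records.

    ``mode='per_wave'``: each wave's ICV is drawn from that wave's mean-age
    curve plus the wave's age-adjusted sex effect, a subject random intercept
    and sweep noise; ages follow the per-sex wave distributions.

    ``mode='longitudinal'``: wave-1 ICV as above; a per-subject daily growth
    rate is drawn from the sex-specific distribution and wave-2 ICV is
    wave-1 truth + rate × interval (+ sweep noise).

    Returns a table with columns ``subject_id, sex, wave, age_days, icv_ml,
    qc_dsc``, one row per sweep.
    """
    if mode not in ("per_wave", "longitudinal"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []

    for sid in range(spec.n_subjects):
        sex = "boy" if rng.random() < spec.boy_fraction else "girl"
        is_boy = 1.0 if sex == "boy" else 0.0
        u = rng.normal(0.0, spec.subject_sd_ml)
        age1 = _draw_age(rng, spec.wave1_age_days[sex], "20w")

        curve1 = spec.wave_mean_icv["20w"]
        base1 = float(curve1(age1)) + spec.sex_effect_ml["20w"] * is_boy + u

        if mode == "per_wave":
            age2 = _draw_age(rng, spec.wave2_age_days[sex], "30w")
            curve2 = spec.wave_mean_icv["30w"]
            base2 = float(curve2(age2)) + spec.sex_effect_ml["30w"] * is_boy + u
        else:
            interval = max(1, int(np.rint(rng.normal(*spec.interval_days))))
            age2 = int(np.clip(age1 + interval, *_AGE_RANGE()))
            rate = rng.normal(*spec.growth_rate[sex])
            base2 = base1 + rate * (age2 - age1)

        for wave, age, base in (("20w", age1, base1), ("30w", age2, base2)):
            for _ in range(_n_sweeps(rng, spec.sweeps_per_wave)):
                icv = base + rng.normal(0.0, spec.sweep_sd_ml)
                icv = max(icv, 1.0)  # physical volumes are positive
                qc = _draw_qc(rng, spec.qc_pass_fraction)
                rows.append((f"S{sid:05d}", sex, wave, age, icv, qc))

    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _AGE_RANGE():
    return AGE_RANGE_DAYS
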