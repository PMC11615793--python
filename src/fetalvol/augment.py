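"""Training-set augmentation for volume/mask pairs.

Each augmented copy draws one spatial transform (elastic deformation,
rotation, scaling, mirroring) applied identically to the volume (trilinear)
and its mask (re-binarized at 0.5), followed by colour transforms
(brightness, contrast, gamma) and noise transforms (additive Gaussian noise,
Gaussian blur) applied to the volume only.  The composition order is fixed:
spatial → colour → noise.  Output intensities are clipped back to [0, 1];
masks stay strictly binary throughout.

Default ranges (all overridable): rotation ±15° per axis, scale
[0.9, 1.1], mirroring allowed on every axis, elastic field with 16-voxel
control-point spacing and 2-voxel displacement SD, brightness ±0.1,
contrast [0.8, 1.25], gamma [0.7, 1.5], noise SD [0, 0.05], blur sigma
[0, 1] voxels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, Volume

__all__ = ["AugmentationSpec", "augment_one", "augment_dataset"]


@dataclass(frozen=True)
class AugmentationSpec:
    """Parameter ranges for one augmentation draw."""

    copies_per_volume: int = 3
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    mirror_axes: tuple[int, ...] = (0, 1, 2)
    elastic_spacing_vox: int = 16
    elastic_sd_vox: float = 2.0
    elastic_prob: float = 0.5
    brightness: float = 0.1
    contrast_range: tuple[float, float] = (0.8, 1.25)
    gamma_range: tuple[float, float] = (0.7, 1.5)
    noise_sd_range: tuple[float, float] = (0.0, 0.05)
    blur_sigma_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_volume < 0:
            raise ValueError("copies_per_volume must be >= 0")
        for lo, hi in (
            self.scale_range,
            self.contrast_range,
            self.gamma_range,
            self.noise_sd_range,
            self.blur_sigma_range,
        ):
            if hi < lo:
                raise ValueError(f"degenerate range ({lo}, {hi})")

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0
            and self.scale_range == (1.0, 1.0)
            and not self.mirror_axes
            and (self.elastic_sd_vox == 0 or self.elastic_prob == 0)
            and self.brightness == 0
            and self.contrast_range == (1.0, 1.0)
            and self.gamma_range == (1.0, 1.0)
            and self.noise_sd_range == (0.0, 0.0)
            and self.blur_sigma_range == (0.0, 0.0)
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AugmentationSpec":
        d = json.loads(text)
        for k in (
            "scale_range",
            "mirror_axes",
            "contrast_range",
            "gamma_range",
            "noise_sd_range",
            "blur_sigma_range",
        ):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def with_(self, **kw) -> "AugmentationSpec":
        return replace(self, **kw)


IDENTITY_SPEC = AugmentationSpec(
    rotation_deg=0.0,
    scale_range=(1.0, 1.0),
    mirror_axes=(),
    elastic_sd_vox=0.0,
    brightness=0.0,
    contrast_range=(1.0, 1.0),
    gamma_range=(1.0, 1.0),
    noise_sd_range=(0.0, 0.0),
    blur_sigma_range=(0.0, 0.0),
)


def _rotation_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _sample_draw(spec: AugmentationSpec, rng: np.random.Generator, shape) -> dict:
    draw = {
        "mirror": tuple(
            ax for ax in spec.mirror_axes if rng.random() < 0.5
        ),
        "angles": tuple(rng.uniform(-spec.rotation_deg, spec.rotation_deg, 3))
        if spec.rotation_deg > 0
        else (0.0, 0.0, 0.0),
        "scale": float(rng.uniform(*spec.scale_range)),
        "elastic": None,
        "brightness": float(rng.uniform(-spec.brightness, spec.brightness))
        if spec.brightness > 0
        else 0.0,
        "contrast": float(rng.uniform(*spec.contrast_range)),
        "gamma": float(rng.uniform(*spec.gamma_range)),
        "noise_sd": float(rng.uniform(*spec.noise_sd_range)),
        "blur_sigma": float(rng.uniform(*spec.blur_sigma_range)),
        "noise_seed": int(rng.integers(0, 2**31 - 1)),
    }
    if spec.elastic_sd_vox > 0 and rng.random() < spec.elastic_prob:
        n_ctrl = [max(2, s // spec.elastic_spacing_vox + 1) for s in shape]
        draw["elastic"] = rng.normal(0.0, spec.elastic_sd_vox, size=(3, *n_ctrl))
    return draw


def _spatial_coords(draw: dict, shape) -> np.ndarray | None:
    """Sampling coordinates implementing rotation+scale (about the centre)
    plus the elastic displacement; None if the draw is spatially identity
    apart from mirroring (mirroring is applied exactly by slicing)."""
    rotate = any(a != 0 for a in draw["angles"])
    scale = draw["scale"] != 1.0
    elastic = draw["elastic"] is not None
    if not (rotate or scale or elastic):
        return None
    idx = np.indices(shape, dtype=np.float64)
    centre = (np.array(shape, dtype=float) - 1.0) / 2.0
    rel = idx - centre.reshape(3, 1, 1, 1)
    mat = _rotation_matrix(draw["angles"]) / draw["scale"]
    coords = np.einsum("ij,jxyz->ixyz", mat, rel) + centre.reshape(3, 1, 1, 1)
    if elastic:
        for ax in range(3):
            ctrl = draw["elastic"][ax]
            disp = ndimage.zoom(
                ctrl, [s / c for s, c in zip(shape, ctrl.shape)], order=1
            )
            pad = [(0, max(0, s - d)) for s, d in zip(shape, disp.shape)]
            if any(p[1] for p in pad):
                disp = np.pad(disp, pad, mode="edge")
            coords[ax] += disp[tuple(slice(0, s) for s in shape)]
    return coords


def _apply_spatial(data: np.ndarray, draw: dict, order: int) -> np.ndarray:
    for ax in draw["mirror"]:
        data = np.flip(data, axis=ax)
    coords = _spatial_coords(draw, data.shape)
    if coords is not None:
        data = ndimage.map_coordinates(
            np.ascontiguousarray(data, dtype=np.float64),
            coords,
            order=order,
            mode="nearest",
        )
    return data


def augment_one(
    v: Volume, m: BinaryMask, spec: AugmentationSpec, draw_seed: int
) -> tuple[Volume, BinaryMask]:
    """One augmented copy of a volume/mask pair.

    The identical sampled spatial transform is applied to both; colour and
    noise affect the volume only.  Deterministic in ``draw_seed``.
    """
    if tuple(v.shape) != tuple(m.shape):
        raise ValueError("volume and mask must share a grid")
    rng = np.random.default_rng(draw_seed)
    draw = _sample_draw(spec, rng, v.shape)

    vol = _apply_spatial(v.data, draw, order=1)
    msk = _apply_spatial(m.data.astype(np.float64), draw, order=1)
    msk = (msk > 0.5).astype(np.uint8)

    # colour: brightness shift, contrast about mid-grey, gamma
    vol = np.clip(vol + draw["brightness"], 0.0, 1.0)
    vol = np.clip(0.5 + (vol - 0.5) * draw["contrast"], 0.0, 1.0)
    vol = vol ** draw["gamma"]

    # noise: additive Gaussian then blur
    noise_rng = np.random.default_rng(draw["noise_seed"])
    if draw["noise_sd"] > 0:
        vol = vol + noise_rng.normal(0.0, draw["noise_sd"], size=vol.shape)
    if draw["blur_sigma"] > 0:
        vol = ndimage.gaussian_filter(vol, draw["blur_sigma"])
    vol = np.clip(vol, 0.0, 1.0)

    return Volume(vol, v.grid), BinaryMask(msk, m.grid)


def augment_dataset(
    pairs: list[tuple[Volume, BinaryMask]], spec: AugmentationSpec
) -> list[tuple[Volume, BinaryMask]]:
    """Originals plus ``copies_per_volume`` augmented copies per original.

    Order is deterministic under ``spec.seed``: all originals first, then
    copies grouped by original.  Each copy is checked to differ from its
    original (a measure-zero identity draw is redrawn) unless the spec is
    the identity spec.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(
        max(1, len(pairs) * max(1, spec.copies_per_volume) * 4)
    )
    out = [(v.copy(), m.copy()) for v, m in pairs]
    si = 0
    for v, m in pairs:
        for _ in range(spec.copies_per_volume):
            for _attempt in range(4):
                av, am = augment_one(v, m, spec, int(seeds[si % len(seeds)]) % (2**31))
                si += 1
                if spec.is_identity or not np.array_equal(av.data, v.data):
                    break
            out.append((av, am))
    return out
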