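"""HU windowing, anchor-centred patch extraction and training augmentation.

The screening pipeline feeds the classifier fixed-size patches cut from a
soft-tissue-windowed, isotropically resampled CT volume. The patch is
positioned on an anchor slice (the origin of the most cranial left renal
artery in annotated data, or a synthetic anchor from the automatic
abdomen-extraction heuristic). At training time the anchor and patch
centre are jittered and the volume is rotated/scaled in-plane to mimic
patient positioning and size variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .volume import CTVolume, resample

#: Soft-tissue window (HU) mapped onto [−1, 1].
WINDOW_LO = -200.0
WINDOW_HI = 400.0

#: Working voxel spacing in mm (median resolution of typical abdominal CT).
WORK_SPACING = (0.9, 0.9, 1.5)

#: Full-scale patch shape in voxels at the working spacing.
PATCH_SHAPE = (320, 384, 224)

PAD_VALUE = -1.0  # normalized air


@dataclass(frozen=True)
class AnchorPoint:
    """Axial slice marking the renal-artery level, with optional in-plane centre."""

    z_index: int
    center: tuple[int, int] | None = None  # (x, y) indices; None = volume centre

    def __post_init__(self):
        if self.z_index < 0:
            raise ValueError(f"z_index must be >= 0, got {self.z_index}")

    def resolve_center(self, vol_shape) -> tuple[int, int]:
        if self.center is not None:
            return tuple(int(c) for c in self.center)
        return (vol_shape[0] // 2, vol_shape[1] // 2)


@dataclass
class Patch:
    """Fixed-size normalized 3D tensor, the network input.

    All values lie in [−1, 1]; ``provenance`` records the source volume id,
    the anchor used, and any augmentation parameters applied.
    """

    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.data.shape


@dataclass(frozen=True)
class AugmentParams:
    """One draw of the training-time augmentation.

    anchor_shift : int, voxels in [−10, 10], along the cranio-caudal axis
    rotation_deg : float, degrees in [−12.6, 12.6], about the cranio-caudal axis
    scale_factor : float, in [0.9, 1.1], isotropic in-plane
    hu_jitter : float, HU in [−3, 3], a single global density offset
    center_offset : (int, int), in-plane patch-centre offset in voxels
    """

    anchor_shift: int = 0
    rotation_deg: float = 0.0
    scale_factor: float = 1.0
    hu_jitter: float = 0.0
    center_offset: tuple[int, int] = (0, 0)

    MAX_SHIFT = 10
    MAX_ROTATION_DEG = 12.6
    MAX_SCALE = 0.1
    MAX_HU_JITTER = 3.0
    MAX_CENTER_OFFSET = 32

    def validate(self) -> None:
        if abs(self.anchor_shift) > self.MAX_SHIFT:
            raise ValueError(f"anchor_shift {self.anchor_shift} outside ±{self.MAX_SHIFT}")
        if abs(self.rotation_deg) > self.MAX_ROTATION_DEG:
            raise ValueError(
                f"rotation_deg {self.rotation_deg} outside ±{self.MAX_ROTATION_DEG}"
            )
        if abs(self.scale_factor - 1.0) > self.MAX_SCALE + 1e-12:
            raise ValueError(f"scale_factor {self.scale_factor} outside [0.9, 1.1]")
        if abs(self.hu_jitter) > self.MAX_HU_JITTER:
            raise ValueError(f"hu_jitter {self.hu_jitter} outside ±{self.MAX_HU_JITTER}")
        off = self.center_offset
        if max(abs(off[0]), abs(off[1])) > self.MAX_CENTER_OFFSET:
            raise ValueError(f"center_offset {off} outside ±{self.MAX_CENTER_OFFSET}")


def window_normalize(vol: CTVolume, lo: float = WINDOW_LO, hi: float = WINDOW_HI) -> CTVolume:
    """Clamp HU values to [lo, hi] and map linearly onto [−1, 1].

    ``lo`` maps to −1, ``hi`` to +1; values outside saturate. The default
    window covers an extended soft-tissue range.
    """
    if lo >= hi:
        raise ValueError(f"window lower bound {lo} must be below upper bound {hi}")
    data = np.clip(np.asarray(vol.data, dtype=np.float32), lo, hi)
    data = (data - lo) / (hi - lo) * 2.0 - 1.0
    return CTVolume(data, vol.spacing, vol.origin)


def prepare_volume(
    vol: CTVolume,
    spacing: tuple[float, float, float] = WORK_SPACING,
    window: tuple[float, float] = (WINDOW_LO, WINDOW_HI),
) -> CTVolume:
    """Window then resample a raw HU volume into pipeline form.

    Returns a volume in [−1, 1] at the working spacing; border samples
    introduced by the resampling are normalized air (−1).
    """
    normalized = window_normalize(vol, *window)
    return resample(normalized, spacing, fill_value=-1.0)


def scale_anchor(anchor: AnchorPoint, from_spacing, to_spacing, n_slices: int) -> AnchorPoint:
    """Carry an anchor's slice index across a resampling step."""
    z = int(round(anchor.z_index * from_spacing[2] / to_spacing[2]))
    return AnchorPoint(int(np.clip(z, 0, n_slices - 1)), center=anchor.center)


def _crop_pad(data: np.ndarray, start, shape, pad_value: float) -> np.ndarray:
    out = np.full(shape, pad_value, dtype=np.float32)
    src, dst = [], []
    for ax in range(3):
        s0 = start[ax]
        s1 = s0 + shape[ax]
        src.append(slice(max(s0, 0), min(s1, data.shape[ax])))
        dst.append(slice(max(-s0, 0), max(-s0, 0) + (min(s1, data.shape[ax]) - max(s0, 0))))
    if all(sl.stop > sl.start for sl in src):
        out[tuple(dst)] = data[tuple(src)]
    return out


def extract_patch(
    vol: CTVolume,
    anchor: AnchorPoint,
    shape: tuple[int, int, int] = PATCH_SHAPE,
    volume_id: str | None = None,
) -> Patch:
    """Cut a fixed-size patch centred on the anchor slice.

    The volume is expected to be windowed to [−1, 1] and resampled to the
    working spacing already. Regions falling outside the volume are padded
    with −1 (normalized air).
    """
    if not (0 <= anchor.z_index < vol.n_slices):
        raise ValueError(
            f"anchor slice {anchor.z_index} outside volume with {vol.n_slices} slices"
        )
    cx, cy = anchor.resolve_center(vol.data.shape)
    center = (cx, cy, anchor.z_index)
    start = [c - s // 2 for c, s in zip(center, shape)]
    data = _crop_pad(np.asarray(vol.data, dtype=np.float32), start, tuple(shape), PAD_VALUE)
    return Patch(
        data,
        provenance={"volume_id": volume_id, "anchor": (cx, cy, anchor.z_index)},
    )


def augment(
    vol: CTVolume,
    anchor: AnchorPoint,
    params: AugmentParams,
    shape: tuple[int, int, int] = PATCH_SHAPE,
    window_width: float = WINDOW_HI - WINDOW_LO,
    volume_id: str | None = None,
) -> Patch:
    """Apply one augmentation draw and extract the patch.

    Order of operations: anchor z-shift, in-plane centre offset, rotation
    about the cranio-caudal axis, isotropic in-plane scaling, patch
    extraction, then the global HU jitter (expressed in normalized units as
    ``2 * hu_jitter / window_width``). When rotation and scale are exactly
    neutral no interpolation is performed at all, so the identity draw is
    bit-exact equal to :func:`extract_patch`.
    """
    params.validate()
    z = int(np.clip(anchor.z_index + params.anchor_shift, 0, vol.n_slices - 1))
    cx, cy = anchor.resolve_center(vol.data.shape)
    cx += int(params.center_offset[0])
    cy += int(params.center_offset[1])

    data = np.asarray(vol.data, dtype=np.float32)
    if params.rotation_deg != 0.0 or params.scale_factor != 1.0:
        theta = np.deg2rad(params.rotation_deg)
        s = params.scale_factor
        # Map output in-plane coordinates back to input: rotate by θ and
        # divide by the scale factor, pivoting on the patch centre.
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        mat = np.eye(3)
        mat[:2, :2] = rot / s
        pivot = np.array([cx, cy, 0.0])
        offset = pivot - mat @ pivot
        data = ndimage.affine_transform(
            data, mat, offset=offset, order=1, mode="constant", cval=PAD_VALUE
        ).astype(np.float32)

    shifted = AnchorPoint(z, center=(cx, cy))
    patch = extract_patch(CTVolume(data, vol.spacing, vol.origin), shifted, shape, volume_id)
    if params.hu_jitter != 0.0:
        jitter = 2.0 * params.hu_jitter / window_width
        patch.data = np.clip(patch.data + np.float32(jitter), -1.0, 1.0)
    patch.provenance["augment"] = asdict(params)
    return patch


def sample_augment_params(
    rng: np.random.Generator,
    max_shift: int = AugmentParams.MAX_SHIFT,
    max_rotation_deg: float = AugmentParams.MAX_ROTATION_DEG,
    max_scale: float = AugmentParams.MAX_SCALE,
    max_hu_jitter: float = AugmentParams.MAX_HU_JITTER,
    max_center_offset: int = AugmentParams.MAX_CENTER_OFFSET,
) -> AugmentParams:
    """Draw augmentation parameters uniformly from their intervals.

    The defaults are the voxel-unit bounds at the reference working spacing
    of 0.9 × 0.9 × 1.5 mm. The shift and centre-offset bounds are voxel
    counts, so when training on a coarser grid they should be scaled down
    to keep the *physical* jitter magnitude the same (e.g. halved at
    1.8 mm in-plane); rotation, scale and density jitter are
    resolution-independent. Deterministic for a fixed generator state.
    """
    return AugmentParams(
        anchor_shift=int(rng.integers(-max_shift, max_shift + 1)),
        rotation_deg=float(rng.uniform(-max_rotation_deg, max_rotation_deg)),
        scale_factor=float(rng.uniform(1.0 - max_scale, 1.0 + max_scale)),
        hu_jitter=float(rng.uniform(-max_hu_jitter, max_hu_jitter)),
        center_offset=tuple(
            int(v) for v in rng.integers(-max_center_offset, max_center_offset + 1, size=2)
        ),
    )
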