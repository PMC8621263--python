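"""Automatic abdominal image-region extraction.

The screening pipeline needs an anchor slice without manual annotation.
This heuristic finds the abdomen from the HU distribution along the
cranio-caudal axis: the fraction of soft-tissue voxels per axial slice
bounds the body region (the longest contiguous run above a threshold),
and the per-slice fraction of high-HU (bone) voxels locates the abdomen
centre as the low plateau between the pelvic peak caudally and the
rib-cage rise cranially — the stretch between the top of the hip bone and
the lower ribs, where only the spine contributes bone.

All numeric choices (HU bands, run threshold, smoothing width) are
configuration with the defaults below; the two detectors are isolated
behind :func:`abdomen_bounds` and :func:`abdomen_center` so alternative
criteria can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .preprocess import AnchorPoint, Patch, extract_patch, window_normalize, WORK_SPACING, PATCH_SHAPE
from .volume import CTVolume, resample

#: soft-tissue HU band
SOFT_TISSUE_BAND = (-100.0, 200.0)
#: above this is treated as bone; set above contrast-filled arterial lumen
#: (~300 HU), which would otherwise masquerade as bone along the aorta
BONE_THRESHOLD = 400.0
#: minimum soft-tissue fraction for a slice to count as body; low enough
#: that the lung-bearing cranial abdomen of a small patient still counts
TAU_SOFT_TISSUE = 0.10
#: moving-average width (slices) applied to both profiles
SMOOTH_WIDTH = 5
#: the renal-artery level sits cranial of the mid-abdomen by roughly this
#: fraction of the abdominal extent; the synthetic anchor is offset by it
#: so automatic extraction matches the anchor convention used in training
RENAL_OFFSET_FRAC = 0.13


class NoAbdomenError(RuntimeError):
    """Raised when no contiguous soft-tissue run is found."""


@dataclass(frozen=True)
class AbdomenRegion:
    """Detected abdominal extent along z with its per-slice profiles."""

    z_lower: int
    z_upper: int
    z_center: int
    soft_tissue_profile: np.ndarray
    bone_profile: np.ndarray

    def __post_init__(self):
        n = len(self.soft_tissue_profile)
        if not (0 <= self.z_lower < self.z_center < self.z_upper < n):
            raise ValueError(
                f"require 0 <= z_lower < z_center < z_upper < {n}, got "
                f"({self.z_lower}, {self.z_center}, {self.z_upper})"
            )


def tissue_profiles(
    vol: CTVolume,
    soft_band: tuple[float, float] = SOFT_TISSUE_BAND,
    bone_threshold: float = BONE_THRESHOLD,
    smooth_width: int = SMOOTH_WIDTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axial-slice soft-tissue and bone voxel fractions, smoothed.

    Operates on the raw (unnormalized) HU volume. Both profiles are
    smoothed with a moving average of ``smooth_width`` slices.
    """
    data = np.asarray(vol.data)
    if data.size == 0:
        raise ValueError("empty volume")
    lo, hi = soft_band
    soft = ((data >= lo) & (data <= hi)).mean(axis=(0, 1))
    bone = (data > bone_threshold).mean(axis=(0, 1))
    if smooth_width > 1:
        soft = uniform_filter1d(soft, smooth_width, mode="nearest")
        bone = uniform_filter1d(bone, smooth_width, mode="nearest")
    return soft, bone


def abdomen_bounds(
    soft_tissue_profile: np.ndarray, tau: float = TAU_SOFT_TISSUE
) -> tuple[int, int]:
    """Ends of the longest contiguous slice run with soft-tissue fraction > tau."""
    profile = np.asarray(soft_tissue_profile)
    if profile.size == 0:
        raise ValueError("empty profile")
    above = profile > tau
    if not above.any():
        raise NoAbdomenError(
            f"no abdomen found: no slice exceeds soft-tissue fraction {tau}"
        )
    # run-length encode the boolean profile and take the longest True run
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    starts, stops = edges[::2], edges[1::2]
    best = np.argmax(stops - starts)
    return int(starts[best]), int(stops[best] - 1)


def abdomen_center(
    bone_profile: np.ndarray,
    bounds: tuple[int, int],
    plateau_margin: float = 0.10,
) -> int:
    """Mid-slice of the low bone plateau between the pelvic and rib peaks.

    Searches the bone profile within ``bounds`` for its two outermost
    prominent peaks (pelvis caudal, rib cage cranial) and returns the
    midpoint of the minimum plateau between them — the slices whose bone
    fraction is within ``plateau_margin`` of the inter-peak minimum
    (relative to the local peak height). Falls back to the midpoint of
    the bounds, with a warning, when no two-peak structure is present.
    """
    z0, z1 = bounds
    profile = np.asarray(bone_profile, dtype=float)
    if not (0 <= z0 < z1 < profile.size):
        raise ValueError(f"invalid bounds {bounds} for profile of {profile.size} slices")
    segment = profile[z0 : z1 + 1]
    span = segment.max() - segment.min()
    # sentinel-pad so maxima touching the bounds (a pelvis starting right
    # at the caudal edge) still register as peaks
    padded = np.concatenate(([segment.min() - 1.0], segment, [segment.min() - 1.0]))
    peaks, _ = find_peaks(padded, prominence=0.25 * span if span > 0 else None)
    peaks = peaks - 1
    if span <= 0 or len(peaks) < 2:
        center = (z0 + z1) // 2
        warnings.warn(
            "no pelvis/rib two-peak bone structure detected; "
            f"falling back to bounds midpoint slice {center}"
        )
        return int(center)
    caudal, cranial = peaks[0], peaks[-1]
    inner = segment[caudal : cranial + 1]
    floor = inner.min()
    height = min(segment[caudal], segment[cranial])
    plateau = np.flatnonzero(inner <= floor + plateau_margin * (height - floor))
    mid = (plateau[0] + plateau[-1]) // 2
    return int(z0 + caudal + mid)


def detect_region(vol: CTVolume, **kwargs) -> AbdomenRegion:
    """Chain profiles -> bounds -> centre into one detection result."""
    soft, bone = tissue_profiles(
        vol,
        soft_band=kwargs.get("soft_band", SOFT_TISSUE_BAND),
        bone_threshold=kwargs.get("bone_threshold", BONE_THRESHOLD),
        smooth_width=kwargs.get("smooth_width", SMOOTH_WIDTH),
    )
    bounds = abdomen_bounds(soft, tau=kwargs.get("tau", TAU_SOFT_TISSUE))
    center = abdomen_center(bone, bounds)
    return AbdomenRegion(bounds[0], bounds[1], center, soft, bone)


def auto_extract(
    vol: CTVolume,
    patch_shape: tuple[int, int, int] = PATCH_SHAPE,
    spacing: tuple[float, float, float] = WORK_SPACING,
    window: tuple[float, float] = (-200.0, 400.0),
    renal_offset_frac: float = RENAL_OFFSET_FRAC,
    **detect_kwargs,
) -> tuple[Patch, AnchorPoint, AbdomenRegion]:
    """Fully automatic screening extraction: detect the abdomen on the raw
    HU volume, then window, resample and cut the patch around a synthetic
    anchor derived from the detected centre (in-plane centred).

    The anchor is placed ``renal_offset_frac`` of the abdominal extent
    cranial of the detected centre — the typical position of the renal
    arteries relative to the mid-abdomen — so that the automatic pathway
    positions its patch the same way the annotated (renal-level) anchors
    do.

    Returns the normalized patch, the synthetic anchor (in resampled
    coordinates), and the detected region. Raises :class:`NoAbdomenError`
    when the volume contains no abdominal soft-tissue run.
    """
    region = detect_region(vol, **detect_kwargs)
    normalized = window_normalize(vol, *window)
    resampled = resample(normalized, spacing, fill_value=-1.0)
    # carry the anchor slice into resampled coordinates
    z_anchor = region.z_center + renal_offset_frac * (region.z_upper - region.z_lower)
    z_anchor = int(round(z_anchor * vol.spacing[2] / spacing[2]))
    z_anchor = int(np.clip(z_anchor, 0, resampled.n_slices - 1))
    anchor = AnchorPoint(z_anchor)
    patch = extract_patch(resampled, anchor, patch_shape)
    patch.provenance["abdomen_region"] = {
        "z_lower": region.z_lower,
        "z_upper": region.z_upper,
        "z_center": region.z_center,
    }
    return patch, anchor, region
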