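"""CT volume container and NIfTI I/O with physical-spacing metadata.

The package-wide convention is index order ``(x, y, z)`` with axial slices
indexed along the last axis and ``z`` increasing cranially (RAS-like).
Readers reorient into this convention from the NIfTI header so downstream
code never has to reason about flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

HU_MIN = -1024.0
HU_MAX = 4096.0
AIR_HU = -1024.0


@dataclass
class CTVolume:
    """A 3D scalar grid in Hounsfield units with voxel spacing and origin.

    Parameters
    ----------
    data
        3D array, Hounsfield units, index order (x, y, z), z cranial.
    spacing
        Per-axis voxel size in mm, all components positive.
    origin
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"CTVolume requires a 3D array, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        """Number of axial slices (extent along z)."""
        return self.data.shape[2]

    def physical_extent(self) -> tuple[float, float, float]:
        """Extent of the grid in mm along each axis."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def copy(self) -> "CTVolume":
        return CTVolume(self.data.copy(), self.spacing, self.origin)


def _affine(vol: CTVolume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def read_volume(path) -> CTVolume:
    """Read a NIfTI file into the internal (x, y, z) convention.

    The image is reoriented to closest-canonical (RAS) so z increases
    cranially, and values are clamped to the valid HU range
    [−1024, 4096].

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If the image is not three-dimensional.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"expected a 3D image, got shape {tuple(img.shape)} from {path}"
        )
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    data = np.clip(data, HU_MIN, HU_MAX)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return CTVolume(data, spacing, origin)


def write_volume(vol: CTVolume, path) -> None:
    """Write a volume as NIfTI-1, encoding data, spacing and origin."""
    if any(s <= 0 for s in vol.spacing):  # belt and braces: invariant re-check
        raise ValueError(f"refusing to write non-positive spacing {vol.spacing}")
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample(
    vol: CTVolume,
    target_spacing: tuple[float, float, float],
    order: int = 1,
    fill_value: float = AIR_HU,
) -> CTVolume:
    """Resample to a new voxel spacing by trilinear interpolation.

    Output dimensions are ``round(dim * spacing / target_spacing)`` per
    axis, preserving the physical extent to within one voxel. Samples
    falling outside the input grid are filled with air (−1024 HU).

    Parameters
    ----------
    order
        Interpolation order: 1 (trilinear, default, for images) or
        0 (nearest neighbour, for label masks).
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be 3 positive values, got {target_spacing}")

    in_shape = vol.data.shape
    factors = [vs / ts for vs, ts in zip(vol.spacing, target_spacing)]
    out_shape = tuple(max(1, int(round(n * f))) for n, f in zip(in_shape, factors))
    if out_shape == in_shape and np.allclose(vol.spacing, target_spacing):
        return CTVolume(vol.data.copy(), target_spacing, vol.origin)

    # Voxel i of the output sits at physical i * target_spacing, i.e. at
    # input index i * target_spacing / spacing (shared origin at index 0).
    grids = np.meshgrid(
        *[np.arange(n) * ts / vs for n, ts, vs in zip(out_shape, target_spacing, vol.spacing)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float32),
        np.stack([g.ravel() for g in grids]),
        order=order,
        mode="constant",
        cval=fill_value,
    ).reshape(out_shape)
    return CTVolume(out.astype(np.float32), target_spacing, vol.origin)
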