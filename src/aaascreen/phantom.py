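"""Synthetic abdominal CT phantoms with ground truth.

Clinical CT cannot be redistributed, so every other module is exercised
on generated volumes that reproduce the coarse structure an abdominal
scan shows in Hounsfield units: an elliptical soft-tissue torso with a
fat rim, air outside the body, lung tissue cranially, a bony spine along
the full torso, pelvic rings caudally and a rib shell cranially, and a
contrast-filled aorta running cranio-caudally anterior-left of the
spine. An aneurysm is a fusiform (spindle-shaped) dilation of the aortic
tube, optionally lined with lower-HU thrombus and an optional stent-like
high-HU insert; Gaussian noise is added on top.

Ground truth is *measured*, not asserted: the per-slice equivalent
diameter of the generated vessel decides the label by the screening
definition (a focal increase of at least 50% over the baseline
diameter), so a corrupted geometry flips the label accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import AnchorPoint
from .volume import CTVolume

# material HU values
HU = {
    "air": -1000.0,
    "lung": -800.0,
    "fat": -100.0,
    "soft": 40.0,
    "thrombus": 60.0,
    "bone": 700.0,
    "stent": 2000.0,
    "lumen_arterial": 300.0,
    "lumen_venous": 120.0,
}

#: diameter ratio defining an aneurysm (50% focal increase)
AAA_RATIO = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material recipe for one phantom.

    Distances are mm; the grid is index order (x, y, z), z cranial.
    ``aneurysm_max_diameter_mm`` is the target outer diameter at the apex
    of the fusiform bulge; the truth label is nevertheless decided by the
    diameter measured on the generated vessel mask.
    """

    shape: tuple[int, int, int] = (128, 128, 160)
    spacing: tuple[float, float, float] = (1.8, 1.8, 3.0)
    torso_axes_mm: tuple[float, float] = (190.0, 150.0)  # full in-plane axes
    torso_z_frac: tuple[float, float] = (0.125, 0.875)  # of the grid z extent
    aorta_diameter_mm: float = 20.0
    aorta_sway_mm: float = 3.0  # lateral centerline excursion
    lumen_phase: str = "arterial"  # or "venous"
    aneurysm: bool = False
    aneurysm_max_diameter_mm: float = 40.0
    aneurysm_extent_mm: float = 80.0
    aneurysm_center_frac: float = 0.45  # of the torso height, caudal->cranial
    thrombus_fraction: float = 0.0  # fraction of sac cross-section area
    stent: bool = False
    lungs: bool = True
    anchor_frac: float = 0.62  # renal-artery level, fraction of torso height
    noise_hu: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("shape and spacing must be positive")
        if self.lumen_phase not in ("arterial", "venous"):
            raise ValueError(f"unknown contrast phase {self.lumen_phase!r}")
        if not 0.0 <= self.thrombus_fraction < 1.0:
            raise ValueError("thrombus_fraction must be in [0, 1)")
        d = self.aneurysm_max_diameter_mm if self.aneurysm else self.aorta_diameter_mm
        if d >= 0.5 * min(self.torso_axes_mm):
            raise ValueError(
                f"aorta of {d} mm does not fit a {self.torso_axes_mm} mm torso"
            )
        extent = self.physical_extent()
        if max(self.torso_axes_mm) > min(extent[0], extent[1]) :
            raise ValueError("torso larger than the grid")

    def physical_extent(self):
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass
class PhantomTruth:
    """Measured ground truth of a generated phantom."""

    label: int
    anchor: AnchorPoint
    aorta_mask: np.ndarray  # vessel incl. thrombus, bool
    abdomen_extent: tuple[int, int]  # torso slice range (inclusive)
    max_diameter_mm: float
    baseline_diameter_mm: float


def _equivalent_diameters(mask: np.ndarray, spacing) -> np.ndarray:
    """Per-slice circle-equivalent diameter (mm) of a vessel mask."""
    areas = mask.sum(axis=(0, 1)) * spacing[0] * spacing[1]
    return 2.0 * np.sqrt(areas / np.pi)


def measure_vessel(mask: np.ndarray, spacing, z_range=None) -> tuple[float, float]:
    """(max, baseline) per-slice equivalent diameter of a vessel mask.

    Baseline is the median over slices containing vessel; an empty mask
    measures (0, 0).
    """
    d = _equivalent_diameters(np.asarray(mask, bool), spacing)
    if z_range is not None:
        d = d[z_range[0] : z_range[1] + 1]
    d = d[d > 0]
    if d.size == 0:
        return 0.0, 0.0
    return float(d.max()), float(np.median(d))


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Assemble one phantom volume and its measured truth; deterministic
    per ``spec.seed``."""
    spec.validate()
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing

    x = (np.arange(nx) - (nx - 1) / 2) * sx
    y = (np.arange(ny) - (ny - 1) / 2) * sy
    z = np.arange(nz) * sz
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    a, b = spec.torso_axes_mm[0] / 2, spec.torso_axes_mm[1] / 2
    z_total = nz * sz
    z0, z1 = spec.torso_z_frac[0] * z_total, spec.torso_z_frac[1] * z_total
    torso_h = z1 - z0
    in_torso_z = (Z >= z0) & (Z <= z1)

    re = np.sqrt((X / a) ** 2 + (Y / b) ** 2)  # elliptical radius
    body = (re <= 1.0) & in_torso_z

    vol = np.full(spec.shape, HU["air"], dtype=np.float32)
    vol[body] = HU["soft"]
    fat_rim = body & (re > 1.0 - 9.0 / min(a, b))
    vol[fat_rim] = HU["fat"]

    # lungs: paired low-HU ellipses in the cranial fifth of the torso
    if spec.lungs:
        lung_z = (Z >= z1 - 0.20 * torso_h) & (Z <= z1)
        for side in (-1, 1):
            lung = (
                ((X - side * 0.45 * a) / (0.33 * a)) ** 2
                + ((Y + 0.05 * b) / (0.55 * b)) ** 2
            ) <= 1.0
            vol[lung & lung_z & body] = HU["lung"]

    # bone: spine along the torso, pelvic rings caudal, rib shell cranial
    y_spine = 0.55 * b
    spine = ((X**2 + (Y - y_spine) ** 2) <= 14.0**2) & in_torso_z
    vol[spine] = HU["bone"]
    pelvis_z = (Z >= z0) & (Z <= z0 + 0.20 * torso_h)
    for side in (-1, 1):
        ring_r = np.sqrt((X - side * 0.55 * a) ** 2 + (Y - 0.15 * b) ** 2)
        ring = (ring_r <= 34.0) & (ring_r >= 25.0) & pelvis_z & body
        vol[ring] = HU["bone"]
    rib_z = (Z >= z1 - 0.22 * torso_h) & (Z <= z1)
    ribs = (re <= 0.96) & (re >= 0.90) & rib_z & in_torso_z
    vol[ribs] = HU["bone"]

    # aorta: tube anterior-left of the spine with a gently swaying centerline
    r0 = spec.aorta_diameter_mm / 2
    xa = -12.0 + spec.aorta_sway_mm * np.sin(2 * np.pi * (Z - z0) / (1.6 * torso_h))
    ya = y_spine - 14.0 - r0 - 8.0
    radius = np.full(nz, r0)
    z_apex = z0 + spec.aneurysm_center_frac * torso_h
    if spec.aneurysm:
        half = spec.aneurysm_extent_mm / 2
        rmax = spec.aneurysm_max_diameter_mm / 2
        bump = np.cos(np.pi * (z - z_apex) / (2 * half)) ** 2
        bump[np.abs(z - z_apex) > half] = 0.0
        radius = r0 + (rmax - r0) * bump
    rad = radius[None, None, :]
    dist2 = (X - xa) ** 2 + (Y - ya) ** 2
    vessel = (dist2 <= rad**2) & in_torso_z

    lumen_hu = HU["lumen_arterial"] if spec.lumen_phase == "arterial" else HU["lumen_venous"]
    if spec.aneurysm and spec.thrombus_fraction > 0:
        # thrombus lines the sac: lumen keeps (1 - f) of the cross-section
        dilated = radius > r0 + 1.0
        lum_r = np.where(dilated, radius * np.sqrt(1 - spec.thrombus_fraction), radius)
        lumen = (dist2 <= (lum_r[None, None, :]) ** 2) & in_torso_z
        vol[vessel] = HU["thrombus"]
        vol[lumen] = lumen_hu
    else:
        vol[vessel] = lumen_hu

    if spec.stent:
        stent_half = min(25.0, spec.aneurysm_extent_mm / 2 if spec.aneurysm else 25.0)
        stent_z = np.abs(Z - z_apex) <= stent_half
        shell = (dist2 <= (r0 + 0.5) ** 2) & (dist2 >= (r0 - 2.0) ** 2) & stent_z & in_torso_z
        vol[shell] = HU["stent"]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_hu > 0:
        vol = vol + rng.normal(0.0, spec.noise_hu, size=vol.shape).astype(np.float32)
    vol = np.clip(vol, -1024.0, 4096.0).astype(np.float32)

    torso_slices = np.flatnonzero(in_torso_z[0, 0])
    max_d, base_d = measure_vessel(vessel, spec.spacing)
    anchor_z = int(round((z0 + spec.anchor_frac * torso_h) / sz))
    anchor_z = int(np.clip(anchor_z, 0, nz - 1))
    truth = PhantomTruth(
        label=int(max_d >= AAA_RATIO * base_d),
        anchor=AnchorPoint(anchor_z),
        aorta_mask=vessel,
        abdomen_extent=(int(torso_slices[0]), int(torso_slices[-1])),
        max_diameter_mm=max_d,
        baseline_diameter_mm=base_d,
    )
    return CTVolume(vol, spec.spacing), truth


#: variability ranges used by :func:`generate_dataset`; each case draws
#: uniformly from these unless overridden
DEFAULT_VARIABILITY = {
    "torso_scale": (0.85, 1.15),
    "aorta_diameter_mm": (16.0, 24.0),
    "aneurysm_ratio": (1.6, 2.6),  # apex diameter / baseline diameter
    "aneurysm_extent_mm": (50.0, 110.0),
    "thrombus_fraction": (0.0, 0.6),
    "arterial_prob": 100 / 187 * 85 / 100,  # mixed-phase composition
    "stent_prob": 0.08,
    "noise_hu": (8.0, 18.0),
    "anchor_jitter_slices": 2,  # mimics annotation variance
}


def generate_dataset(
    n: int,
    prevalence: float = 100 / 187,
    variability: dict | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
):
    """Draw ``n`` phantoms with ``round(n * prevalence)`` positives.

    Per-case geometry is sampled from ``variability`` (see
    ``DEFAULT_VARIABILITY``); anchors are jittered by a few slices to
    mimic annotation variance. Returns a list of (CTVolume, PhantomTruth).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    var = dict(DEFAULT_VARIABILITY)
    if variability:
        var.update(variability)
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)

    n_pos = int(round(n * prevalence))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)

    out = []
    for i, lab in enumerate(labels):
        scale = rng.uniform(*var["torso_scale"])
        d0 = rng.uniform(*var["aorta_diameter_mm"])
        spec = replace(
            base,
            torso_axes_mm=tuple(t * scale for t in base.torso_axes_mm),
            aorta_diameter_mm=d0,
            lumen_phase="arterial" if rng.random() < var["arterial_prob"] else "venous",
            aneurysm=bool(lab),
            aneurysm_max_diameter_mm=min(
                d0 * rng.uniform(*var["aneurysm_ratio"]),
                0.45 * scale * min(base.torso_axes_mm),
            ),
            aneurysm_extent_mm=rng.uniform(*var["aneurysm_extent_mm"]),
            aneurysm_center_frac=base.aneurysm_center_frac + rng.uniform(-0.05, 0.05),
            thrombus_fraction=rng.uniform(*var["thrombus_fraction"]) if lab else 0.0,
            stent=bool(rng.random() < var["stent_prob"]),
            noise_hu=rng.uniform(*var["noise_hu"]),
            seed=int(rng.integers(2**31)),
        )
        vol, truth = generate_phantom(spec)
        jitter = int(rng.integers(-var["anchor_jitter_slices"], var["anchor_jitter_slices"] + 1))
        zj = int(np.clip(truth.anchor.z_index + jitter, 0, vol.n_slices - 1))
        truth.anchor = AnchorPoint(zj)
        out.append((vol, truth))
    return out
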