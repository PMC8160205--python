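"""Micro-CT style volume processing and morphometrics.

Pipeline: median filter -> unsharp mask -> threshold segmentation (Otsu or
fixed) with largest-component cleanup -> surface area and volume.

Surface area comes from a marching-cubes isosurface of the binary mask at
level 0.5, not from voxel-face counting: face counting overestimates curved
surfaces by up to ~1.5x, while the triangulated isosurface converges to the
true area for resolved geometry. Volume is the voxel count times the voxel
volume. Units: voxel size in micrometres; outputs in mm^2 / mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure as skmeasure

from .errors import EmptyMaskError


@dataclass(frozen=True)
class VoxelVolume:
    """3-D grid of intensities (or a binary mask) with isotropic voxels."""

    grid: np.ndarray
    voxel_size: float           # um per edge, isotropic
    provenance: str = ""

    def __post_init__(self):
        grid = np.asarray(self.grid)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 3 or min(grid.shape) < 1:
            raise ValueError("grid must be a non-empty 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self):
        return self.grid.shape


def median_filter(vol: VoxelVolume, radius: int = 1) -> VoxelVolume:
    """Cubic-neighbourhood median filter with reflective edge handling."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * int(radius) + 1
    out = ndimage.median_filter(vol.grid, size=size, mode="reflect")
    return VoxelVolume(out, vol.voxel_size, provenance=vol.provenance + "|median")


def unsharp_mask(vol: VoxelVolume, sigma: float = 1.0, amount: float = 1.0) -> VoxelVolume:
    """Gaussian unsharp mask: out = in + amount * (in - blur(in, sigma)).

    The result is clipped to the input intensity range so sharpening never
    invents intensities outside the acquired dynamic range.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    g = vol.grid.astype(float)
    blur = ndimage.gaussian_filter(g, sigma=sigma, mode="reflect")
    out = g + amount * (g - blur)
    out = np.clip(out, g.min(), g.max())
    return VoxelVolume(out, vol.voxel_size, provenance=vol.provenance + "|unsharp")


def segment(vol: VoxelVolume, method: str = "otsu", threshold: float | None = None,
            fill_holes: bool = False) -> VoxelVolume:
    """Binary segmentation with largest-26-connected-component cleanup.

    ``method="otsu"`` picks the threshold from the intensity histogram;
    ``method="fixed"`` requires ``threshold``. Interior voids are kept (and
    therefore counted as surface) unless ``fill_holes`` is set — how internal
    porosity is treated is a genuine analysis choice, so it is explicit.
    """
    g = vol.grid
    if method == "otsu":
        thr = float(skfilters.threshold_otsu(g))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold segmentation requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask = g > thr
    if not mask.any():
        raise EmptyMaskError(f"threshold {thr:g} produced an empty mask")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return VoxelVolume(mask, vol.voxel_size,
                       provenance=vol.provenance + f"|segment({method})")


@dataclass(frozen=True)
class MorphologyMetrics:
    """Surface area / volume morphometrics of a segmented specimen."""

    surface_area: float          # mm^2
    volume: float                # mm^3
    sa_v: float                  # mm^-1
    dry_weight: float | None = None   # g
    sa_dw: float | None = None       # mm^2 g^-1

    def summary(self) -> str:
        lines = [
            "Morphometrics",
            "-------------",
            f"surface area: {self.surface_area:.2f} mm^2",
            f"volume:       {self.volume:.2f} mm^3",
            f"SA/V:         {self.sa_v:.3f} mm^-1",
        ]
        if self.sa_dw is not None:
            lines.append(f"SA/DW:        {self.sa_dw:.1f} mm^2/g")
        return "\n".join(lines)


def measure(binary: VoxelVolume, dry_weight: float | None = None,
            smooth_sigma: float = 0.8) -> MorphologyMetrics:
    """Mesh surface area and voxel volume of a binary mask.

    The mask is zero-padded so the isosurface closes at the array border;
    marching cubes runs at level 0.5 with the physical voxel spacing. A
    light Gaussian pre-smoothing (``smooth_sigma`` voxels, default 0.8)
    suppresses the staircase inflation that a binary isosurface suffers on
    curved surfaces (~+9% on a 25-voxel sphere, brought to <1%); it rounds
    genuinely sharp edges over ~one voxel, so set ``smooth_sigma=0`` when
    measuring sharp-edged calibration geometry.
    """
    mask = binary.grid.astype(bool)
    if not mask.any():
        raise EmptyMaskError("cannot measure an empty mask")
    vs_mm = binary.voxel_size / 1000.0
    volume = float(mask.sum()) * vs_mm**3
    pad = max(1, int(np.ceil(2 * smooth_sigma)))
    padded = np.pad(mask, pad).astype(np.float32)
    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(padded, smooth_sigma)
        # objects only a voxel or two across blur below the 0.5 level;
        # fall back to the raw binary isosurface for them
        if smoothed.max() > 0.5:
            padded = smoothed
    verts, faces, _, _ = skmeasure.marching_cubes(
        padded, level=0.5, spacing=(vs_mm,) * 3
    )
    surface_area = float(skmeasure.mesh_surface_area(verts, faces))
    sa_dw = None
    if dry_weight is not None:
        if dry_weight <= 0:
            raise ValueError("dry weight must be positive")
        sa_dw = surface_area / dry_weight
    return MorphologyMetrics(
        surface_area=surface_area,
        volume=volume,
        sa_v=surface_area / volume,
        dry_weight=dry_weight,
        sa_dw=sa_dw,
    )


def resample_isotropic(grid: np.ndarray, voxel_sizes: tuple[float, float, float]) -> VoxelVolume:
    """Resample an anisotropic grid onto the finest axis spacing, with a warning."""
    vs = np.asarray(voxel_sizes, dtype=float)
    if np.allclose(vs, vs[0]):
        return VoxelVolume(grid, float(vs[0]))
    target = float(vs.min())
    warnings.warn(
        f"anisotropic voxels {tuple(vs)} um resampled to isotropic {target} um"
    )
    zoom = vs / target
    out = ndimage.zoom(grid.astype(float), zoom, order=1)
    return VoxelVolume(out, target, provenance="|resampled")
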