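"""Slice-addition volumetry, 3-D ROI attenuation and surface extraction.

The volume of a segmented gland is quantified by the slice addition
technique (SAT): within each slice the number of segmented voxels is
multiplied by the single-voxel volume, and the per-slice partial volumes are
summed.  Because voxel counts are integers this is identical, exactly, to
the total voxel count times the voxel volume, and identical along any slice
axis; the per-slice decomposition is retained for reporting.

Attenuation is the mean HU over exactly the segmented voxels — a 3-D ROI
covering the whole organ including its boundary voxels, so partial-volume
blending at the organ border is deliberately part of the measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure

from .grid_io import ImageGrid, LabelMask

__all__ = [
    "VolumetryResult",
    "AttenuationResult",
    "EmptyMaskError",
    "compute_volume",
    "mean_attenuation",
    "extract_surface",
    "DEFAULT_HOMOGENEITY_SD_HU",
]

#: Glands whose HU standard deviation exceeds this are flagged non-homogeneous
#: (heterogeneous contrast distribution suggests cysts or inactive neoplasms).
#: The underlying criterion is qualitative; this default is an operational
#: stand-in and is configurable everywhere it is used.
DEFAULT_HOMOGENEITY_SD_HU = 25.0


class EmptyMaskError(ValueError):
    """Raised when a measurement is requested on an empty segmentation."""


@dataclass(frozen=True)
class VolumetryResult:
    """SAT volume of one gland.

    ``total_volume_cm3`` equals ``voxel_count * voxel_volume_mm3 / 1000`` and
    equals the sum of ``per_slice_volumes_cm3``; ``per_slice_counts`` are the
    integer voxel counts per slice along ``slice_axis`` and sum to
    ``voxel_count`` exactly.
    """

    total_volume_cm3: float
    voxel_count: int
    per_slice_counts: np.ndarray
    per_slice_volumes_cm3: np.ndarray
    slice_axis: int
    voxel_volume_mm3: float


@dataclass(frozen=True)
class AttenuationResult:
    mean_hu: float
    sd_hu: float
    n_voxels: int
    homogeneous: bool


def compute_volume(mask: LabelMask, slice_axis: int | None = None) -> VolumetryResult:
    """Slice-addition volume of a segmented gland.

    Parameters
    ----------
    mask
        Nonempty binary segmentation.
    slice_axis
        Axis along which the per-slice decomposition is reported; defaults to
        the coarsest-spacing (through-plane) axis.  The total is independent
        of this choice.
    """
    if mask.voxel_count == 0:
        raise EmptyMaskError("empty segmentation")
    if slice_axis is None:
        slice_axis = int(np.argmax(mask.spacing))
    other = tuple(ax for ax in range(3) if ax != slice_axis)
    counts = mask.occupancy.sum(axis=other).astype(np.int64)
    voxel_count = int(counts.sum())
    vv = mask.voxel_volume_mm3
    return VolumetryResult(
        total_volume_cm3=voxel_count * vv / 1000.0,
        voxel_count=voxel_count,
        per_slice_counts=counts,
        per_slice_volumes_cm3=counts * (vv / 1000.0),
        slice_axis=slice_axis,
        voxel_volume_mm3=vv,
    )


def mean_attenuation(
    grid: ImageGrid,
    mask: LabelMask,
    homogeneity_sd_hu: float = DEFAULT_HOMOGENEITY_SD_HU,
) -> AttenuationResult:
    """Mean and SD of HU over the masked 3-D ROI (boundary voxels included)."""
    mask.check_compatible(grid)
    if mask.voxel_count == 0:
        raise EmptyMaskError("empty segmentation")
    vals = grid.values[mask.occupancy.astype(bool)]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    return AttenuationResult(
        mean_hu=mean,
        sd_hu=sd,
        n_voxels=int(vals.size),
        homogeneous=bool(sd <= homogeneity_sd_hu),
    )


def extract_surface(mask: LabelMask) -> trimesh.Trimesh:
    """Closed triangulated surface of the segmented gland, in mm coordinates.

    Marching cubes at iso-level 0.5 on the zero-padded occupancy field.  The
    mesh is watertight for any nonempty mask; for masks of >= 1000 voxels its
    enclosed volume tracks the SAT volume to within a few percent, while for
    very small structures marching cubes systematically under-encloses (the
    iso-surface cuts between voxel centres).
    """
    if mask.voxel_count == 0:
        raise EmptyMaskError("empty segmentation")
    n_comp = measure.label(mask.occupancy, connectivity=1).max()
    if n_comp > 1:
        warnings.warn(
            f"mask has {n_comp} connected components; surface will be disjoint",
            stacklevel=2,
        )
    padded = np.pad(mask.occupancy.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    # undo the one-voxel pad so coordinates match voxel-centre mm positions
    verts = verts - np.asarray(mask.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh
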