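"""Reading, writing and resampling of CT voxel grids and segmentation masks.

A CT study is represented by an :class:`ImageGrid` (Hounsfield-unit values on
a regular 3-D lattice with millimetre spacing) and, for each segmented organ,
a :class:`LabelMask` of identical geometry.  Grid axes are tagged with the
anatomical direction they run along — craniocaudal (``CC``), dorsoventral
(``DV``) or mediolateral (``ML``) — because the downstream caliper
measurements (length, height, width) are defined anatomically, not in array
index order.

Supported on disk: NIfTI-1 (read/write) and single-frame DICOM series
(read only, with HU rescale applied).  Axis labels are recovered from the
NIfTI affine orientation codes; when a file carries no usable orientation
they must be supplied explicitly — they are never guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ANATOMICAL_AXES",
    "ImageGrid",
    "LabelMask",
    "GridCompatibilityError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_inplane",
]

#: Canonical anatomical axis labels: craniocaudal, dorsoventral, mediolateral.
ANATOMICAL_AXES = ("CC", "DV", "ML")

# NIfTI axis codes mapped onto anatomical directions.  For a quadruped both
# R/L polarities run mediolaterally, A/P dorsoventrally and S/I craniocaudally;
# polarity is irrelevant for extents and volumes so only the axis is kept.
_AXCODE_TO_ANAT = {"R": "ML", "L": "ML", "A": "DV", "P": "DV", "S": "CC", "I": "CC"}
_ANAT_TO_AXCODE = {"ML": "R", "DV": "A", "CC": "S"}

_SPACING_ATOL_MM = 1e-4


class GridCompatibilityError(ValueError):
    """A mask and grid disagree in shape, spacing or axis labels."""


def _validate_axes(axes: Sequence[str]) -> tuple[str, str, str]:
    axes = tuple(str(a).upper() for a in axes)
    if sorted(axes) != sorted(ANATOMICAL_AXES):
        raise ValueError(
            f"axes must be a permutation of {ANATOMICAL_AXES}, got {axes!r}"
        )
    return axes  # type: ignore[return-value]


@dataclass
class ImageGrid:
    """Hounsfield-unit values on a regular 3-D grid.

    Parameters
    ----------
    values
        3-D array of HU values; stored as float64.
    spacing
        Voxel edge lengths in mm, one per array axis, all positive.
    axes
        Anatomical direction of each array axis, a permutation of
        ``("CC", "DV", "ML")``.
    origin
        Position of the centre of voxel ``(0, 0, 0)`` in mm.

    Voxel coordinates are centre-based: voxel ``i`` along an axis with
    spacing ``s`` spans ``[i*s - s/2, i*s + s/2)`` mm relative to the origin.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = ANATOMICAL_AXES
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must all be finite")
        self.axes = _validate_axes(self.axes)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    def axis_of(self, anatomical: str) -> int:
        """Array axis index running along the given anatomical direction."""
        return self.axes.index(anatomical.upper())


@dataclass
class LabelMask:
    """Binary occupancy aligned voxel-for-voxel with a companion grid."""

    occupancy: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = ANATOMICAL_AXES
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={occ.ndim}")
        uniq = np.unique(occ)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
        self.occupancy = occ.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.axes = _validate_axes(self.axes)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def axis_of(self, anatomical: str) -> int:
        return self.axes.index(anatomical.upper())

    def check_compatible(self, grid: ImageGrid) -> None:
        """Raise :class:`GridCompatibilityError` unless aligned with *grid*."""
        if self.shape != grid.shape:
            raise GridCompatibilityError(
                f"mask shape {self.shape} != grid shape {grid.shape}"
            )
        if not np.allclose(self.spacing, grid.spacing, atol=_SPACING_ATOL_MM, rtol=0):
            raise GridCompatibilityError(
                f"mask spacing {self.spacing} != grid spacing {grid.spacing}"
            )
        if self.axes != grid.axes:
            raise GridCompatibilityError(f"mask axes {self.axes} != grid axes {grid.axes}")


# ---------------------------------------------------------------------------
# NIfTI / DICOM I/O
# ---------------------------------------------------------------------------


def _affine_for(spacing, axes, origin) -> np.ndarray:
    """Affine whose orientation codes encode the anatomical axis labels."""
    # Unit direction per array axis: ML->+x(R), DV->+y(A), CC->+z(S).
    order = {"ML": 0, "DV": 1, "CC": 2}
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    for array_axis, (label, s) in enumerate(zip(axes, spacing)):
        aff[order[label], array_axis] = s
        aff[order[label], 3] = origin[array_axis]
    return aff


def _axes_from_affine(affine: np.ndarray) -> tuple[str, str, str] | None:
    try:
        codes = nib.orientations.aff2axcodes(affine)
    except Exception:
        return None
    labels = tuple(_AXCODE_TO_ANAT.get(c) for c in codes)
    if None in labels or sorted(labels) != sorted(ANATOMICAL_AXES):  # degenerate affine
        return None
    return labels  # type: ignore[return-value]


def read_volume(path: str | Path, axes: Sequence[str] | None = None) -> ImageGrid:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path
        ``.nii``/``.nii.gz`` file, or a directory containing one DICOM series.
    axes
        Explicit anatomical axis labels, overriding (or standing in for
        missing) file orientation metadata.

    DICOM stored values are converted to HU with the rescale slope/intercept.
    A file without pixel-spacing metadata is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_series(path, axes)

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid pixel spacing (zooms={zooms})")
    if axes is None:
        axes = _axes_from_affine(img.affine)
        if axes is None:
            raise ValueError(
                f"{path}: orientation metadata is unusable; pass explicit axes "
                f"(e.g. axes=('CC','DV','ML'))"
            )
    origin = tuple(float(x) for x in img.affine[:3, 3][:3])
    return ImageGrid(data, tuple(float(z) for z in zooms), _validate_axes(axes), origin)


def _read_dicom_series(directory: Path, axes: Sequence[str] | None) -> ImageGrid:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"{directory}: no DICOM files found")
    slices = [pydicom.dcmread(str(f)) for f in files]

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    first = slices[0]
    if not getattr(first, "PixelSpacing", None):
        raise ValueError(f"{directory}: DICOM series lacks PixelSpacing metadata")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        z0, z1 = sort_key(slices[0]), sort_key(slices[1])
        dz = abs(z1 - z0)
        if dz <= 0:
            dz = float(getattr(first, "SliceThickness", 0) or 0)
    else:
        dz = float(getattr(first, "SliceThickness", 0) or 0)
    if dz <= 0:
        raise ValueError(f"{directory}: cannot determine slice spacing")

    slope = float(getattr(first, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(first, "RescaleIntercept", 0.0) or 0.0)
    stack = np.stack([ds.pixel_array.astype(np.float64) for ds in slices], axis=-1)
    hu = stack * slope + intercept

    if axes is None:
        # In-plane rows/columns are DV/ML for a transverse series; the stack
        # axis is craniocaudal.  Require explicit labels unless the series
        # declares a standard axial orientation.
        iop = getattr(first, "ImageOrientationPatient", None)
        if iop is not None and np.allclose([float(v) for v in iop], [1, 0, 0, 0, 1, 0]):
            axes = ("ML", "DV", "CC")
        else:
            raise ValueError(
                f"{directory}: series orientation not recognised; pass explicit axes"
            )
    return ImageGrid(hu, (row_mm, col_mm, dz), _validate_axes(axes))


def write_volume(grid: ImageGrid, path: str | Path) -> None:
    """Write a grid as NIfTI-1; the affine encodes spacing and axis labels."""
    aff = _affine_for(grid.spacing, grid.axes, grid.origin)
    img = nib.Nifti1Image(grid.values, aff)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def write_mask(mask: LabelMask, path: str | Path) -> None:
    aff = _affine_for(mask.spacing, mask.axes, mask.origin)
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, grid: ImageGrid) -> LabelMask:
    """Read a segmentation mask and bind it to its companion grid.

    Any nonzero stored label is mapped to occupancy 1.  Shape or spacing
    disagreement with *grid* (beyond 1e-4 mm) is an error; an all-zero mask
    is valid here and rejected only by downstream measurements.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got ndim={data.ndim}")
    occ = (data != 0).astype(np.uint8)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = LabelMask(occ, zooms, grid.axes, grid.origin)
    mask.check_compatible(grid)
    return mask


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _resample_axis_coords(n: int, old: float, new: float) -> np.ndarray:
    """Cell-centred sample positions (in voxel index units) for one axis.

    The voxel extent ``[-old/2, n*old - old/2]`` is tiled with cells of the
    new size and their centres are sampled.  When ``new == old`` this is the
    identity, and at integer refinement ratios the sample points fall between
    the old centres rather than exactly on the 0.5 iso-contour of an
    interpolated binary mask (which would bias thresholded volumes).
    """
    n_new = max(1, int(np.floor(n * old / new + 1e-9)))
    ratio = new / old
    return -0.5 + (np.arange(n_new) + 0.5) * ratio


def _trilinear_resample(
    values: np.ndarray, spacing, target, inplane_axes, mode: str = "nearest"
) -> np.ndarray:
    coords_1d = []
    for ax in range(3):
        if ax in inplane_axes:
            coords_1d.append(_resample_axis_coords(values.shape[ax], spacing[ax], target))
        else:
            coords_1d.append(np.arange(values.shape[ax], dtype=float))
    mesh = np.meshgrid(*coords_1d, indexing="ij")
    return ndimage.map_coordinates(values, mesh, order=1, mode=mode, cval=0.0)


def resample_inplane(
    grid: ImageGrid,
    mask: LabelMask | None = None,
    target: float = 0.2,
    slice_axis: int | None = None,
) -> tuple[ImageGrid, LabelMask | None]:
    """Resample the two in-plane axes to a uniform pixel size.

    Clinical abdominal series have fine in-plane pixels (0.26-0.97 mm here)
    and coarse 2 mm slices; interpolating the pixel size to a common 0.2 mm
    makes measurements comparable across scans.  Intensities are interpolated
    trilinearly; the mask is interpolated as a real field and re-thresholded
    at 0.5, which reproduces the original mask exactly when the target equals
    the current spacing.

    Parameters
    ----------
    target
        Desired in-plane pixel size in mm (> 0).
    slice_axis
        Array axis of the through-plane (slice) direction; defaults to the
        axis with the coarsest spacing.  Its spacing is preserved.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if mask is not None:
        mask.check_compatible(grid)
    if slice_axis is None:
        slice_axis = int(np.argmax(grid.spacing))
    inplane = tuple(ax for ax in range(3) if ax != slice_axis)

    extents = [grid.shape[ax] * grid.spacing[ax] for ax in inplane]
    if target > min(extents):
        warnings.warn(
            f"target spacing {target} mm exceeds the in-plane extent "
            f"{min(extents):.3g} mm; output will be a single sample",
            stacklevel=2,
        )

    if all(abs(grid.spacing[ax] - target) < 1e-12 for ax in inplane):
        return grid, mask

    new_spacing = tuple(
        target if ax in inplane else grid.spacing[ax] for ax in range(3)
    )
    new_values = _trilinear_resample(grid.values, grid.spacing, target, inplane)
    out_grid = ImageGrid(new_values, new_spacing, grid.axes, grid.origin)
    out_mask = None
    if mask is not None:
        real = _trilinear_resample(
            mask.occupancy.astype(np.float64), mask.spacing, target, inplane,
            mode="grid-constant",
        )
        out_mask = LabelMask((real >= 0.5).astype(np.uint8), new_spacing, mask.axes, mask.origin)
    return out_grid, out_mask
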