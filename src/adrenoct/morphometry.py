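"""Linear caliper measurements of a segmented gland in an adjusted plane.

The measurement protocol mirrors how adrenal glands are measured on a CT
workstation: the maximal craniocaudal length L is fixed first, the
transverse viewing plane is tilted orthogonal to that length axis (so every
gland is sectioned in a standardised pose regardless of how the animal lay
in the scanner), and height H (dorsoventral diameter) and width W
(mediolateral diameter) are read off at the cranial pole, the caudal pole
and — for the left gland — the isthmus.  The dorsoventral aortic diameter,
used to normalise gland size, is measured the same way on an aorta mask.

Here L is formalised as the 3-D farthest-point distance between occupied
voxel centres (rotation invariant by construction), and the adjusted plane
as a resampling of the mask into a gland-aligned orthonormal frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .grid_io import ANATOMICAL_AXES, LabelMask
from .volumetry import EmptyMaskError

__all__ = [
    "GlandFrame",
    "PoleStations",
    "craniocaudal_length",
    "gland_frame_from_mask",
    "reorient_to_gland_frame",
    "locate_poles_and_isthmus",
    "height_width_at",
    "aortic_dorsoventral_diameter",
]


@dataclass(frozen=True)
class GlandFrame:
    """Orthonormal gland-aligned frame expressed in grid physical coordinates.

    ``length_dir`` points along the gland's long (craniocaudal) axis;
    ``dv_dir`` and ``ml_dir`` span the adjusted transverse plane and are the
    minimal-rotation images of the anatomical dorsoventral and mediolateral
    axes.  The rotation with rows ``(length_dir, dv_dir, ml_dir)`` is proper
    (determinant +1).
    """

    length_dir: np.ndarray
    dv_dir: np.ndarray
    ml_dir: np.ndarray

    def __post_init__(self) -> None:
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("gland frame directions must be orthonormal")
        if np.linalg.det(R) < 0.99:
            raise ValueError("gland frame must be a proper rotation (det +1)")

    @property
    def rotation(self) -> np.ndarray:
        return np.vstack([self.length_dir, self.dv_dir, self.ml_dir]).astype(float)


def _occupied_points_mm(mask: LabelMask) -> np.ndarray:
    idx = np.argwhere(mask.occupancy)
    return idx * np.asarray(mask.spacing)


def craniocaudal_length(mask: LabelMask) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Maximal 3-D distance between occupied voxel centres, with endpoints.

    The farthest pair is found on the convex hull of the occupied centres
    (the diameter of a point set is attained at hull vertices), falling back
    to an exhaustive scan for tiny or degenerate (coplanar) masks.
    """
    if mask.voxel_count == 0:
        raise EmptyMaskError("empty segmentation")
    pts = _occupied_points_mm(mask)
    if len(pts) == 1:
        warnings.warn("single-voxel mask: length is 0", stacklevel=2)
        return 0.0, (pts[0], pts[0])
    cand = pts
    if len(pts) > 500:
        try:
            cand = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate geometry: scan all points
    if len(cand) > 20000:  # pathological hull; subsample deterministically
        cand = cand[:: len(cand) // 20000 + 1]
    d = cdist(cand, cand)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return float(d[i, j]), (cand[i], cand[j])


def gland_frame_from_mask(mask: LabelMask) -> GlandFrame:
    """Gland frame with the length axis along the farthest-point chord.

    The transverse directions are the projections of the mask's anatomical
    DV and ML axes onto the plane orthogonal to the length axis,
    renormalised (minimal-rotation convention), so H and W keep their
    anatomical meaning in the adjusted plane.
    """
    length_mm, (p, q) = craniocaudal_length(mask)
    if length_mm == 0:
        raise ValueError("degenerate frame: mask has no extent")
    u = (q - p) / np.linalg.norm(q - p)
    cc_axis = mask.axis_of("CC")
    if u[cc_axis] < 0:  # orient consistently along the +CC grid direction
        u = -u
    e_dv = np.zeros(3)
    e_dv[mask.axis_of("DV")] = 1.0
    dv = e_dv - (e_dv @ u) * u
    if np.linalg.norm(dv) < 1e-6:  # length axis happens to run dorsoventrally
        e_ml = np.zeros(3)
        e_ml[mask.axis_of("ML")] = 1.0
        ml = e_ml - (e_ml @ u) * u
        ml /= np.linalg.norm(ml)
        dv = np.cross(ml, u)
        return GlandFrame(u, dv, np.cross(u, dv))
    dv /= np.linalg.norm(dv)
    return GlandFrame(u, dv, np.cross(u, dv))


def reorient_to_gland_frame(
    mask: LabelMask, frame: GlandFrame, iso_spacing_mm: float | None = None
) -> LabelMask:
    """Resample the mask into the gland frame (axis 0 = length axis).

    The occupancy field is interpolated trilinearly at isotropic sample
    spacing (default: the finest original spacing) and re-thresholded at
    0.5.  Output axes are labelled ``("CC", "DV", "ML")`` in gland-frame
    terms; for well-resolved glands the voxel-count volume is preserved to
    within about 1%.
    """
    if mask.voxel_count == 0:
        raise EmptyMaskError("empty segmentation")
    iso = float(iso_spacing_mm) if iso_spacing_mm is not None else float(min(mask.spacing))
    if iso <= 0:
        raise ValueError("iso spacing must be positive")
    R = frame.rotation
    pts = _occupied_points_mm(mask)
    g = pts @ R.T
    gmin = g.min(axis=0) - 2 * iso
    gmax = g.max(axis=0) + 2 * iso
    shape = np.ceil((gmax - gmin) / iso).astype(int) + 1
    ax = [gmin[k] + np.arange(shape[k]) * iso for k in range(3)]
    G = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)  # gland-frame mm
    P = G @ R  # back to grid physical mm (R.T applied to each point)
    coords = [P[..., k] / mask.spacing[k] for k in range(3)]
    real = ndimage.map_coordinates(
        mask.occupancy.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    )
    return LabelMask((real >= 0.5).astype(np.uint8), (iso, iso, iso), ANATOMICAL_AXES)


@dataclass(frozen=True)
class PoleStations:
    """Slice indices (along the length axis) of the measurement stations."""

    cranial: int
    caudal: int
    isthmus: int


def _station_areas(mask: LabelMask) -> tuple[np.ndarray, int]:
    axis = mask.axis_of("CC")
    other = tuple(a for a in range(3) if a != axis)
    return mask.occupancy.sum(axis=other).astype(np.int64), axis


def locate_poles_and_isthmus(
    mask: LabelMask, pole_window: float = 0.5
) -> PoleStations:
    """Measurement stations on a gland resampled into its gland frame.

    The cranial pole station is the cross-section of maximal area within the
    cranial ``pole_window`` fraction of the occupied length (ties resolved
    toward the cranial end), the caudal pole likewise in the caudal window
    (ties toward the caudal end), and the isthmus is the minimal-area
    section strictly between the two poles (ties toward the midpoint).
    Cranial is, by convention, the low-index end of the length axis.
    """
    if not 0 < pole_window <= 1:
        raise ValueError("pole_window must be in (0, 1]")
    areas, _ = _station_areas(mask)
    occ = np.nonzero(areas)[0]
    if occ.size < 5:
        raise ValueError("gland too small for pole analysis (< 5 occupied stations)")
    z0, z1 = int(occ[0]), int(occ[-1])
    span = z1 - z0
    cran_hi = z0 + pole_window * span
    caud_lo = z1 - pole_window * span
    cran_cand = occ[occ <= cran_hi + 1e-9]
    caud_cand = occ[occ >= caud_lo - 1e-9]
    # ties toward the respective gland end
    cranial = int(cran_cand[np.argmax(areas[cran_cand])])
    caud_rev = caud_cand[::-1]
    caudal = int(caud_rev[np.argmax(areas[caud_rev])])
    between = occ[(occ > cranial) & (occ < caudal)]
    if between.size == 0:
        raise ValueError("no stations strictly between the pole stations")
    mid = 0.5 * (cranial + caudal)
    order = between[np.lexsort((np.abs(between - mid), areas[between]))]
    isthmus = int(order[0])
    return PoleStations(cranial=cranial, caudal=caudal, isthmus=isthmus)


def _extent_mm(indices: np.ndarray, spacing: float) -> float:
    # voxel-centre to voxel-centre plus one voxel
    return float((indices.max() - indices.min() + 1) * spacing)


def height_width_at(mask: LabelMask, station: int) -> tuple[float, float]:
    """Height (DV extent) and width (ML extent) of the section at *station*.

    *mask* is expected in a frame whose axes carry anatomical labels (as
    produced by :func:`reorient_to_gland_frame`); the station indexes the CC
    axis and the extents are axis-aligned calipers along DV and ML.
    """
    cc = mask.axis_of("CC")
    section = np.take(mask.occupancy, station, axis=cc)
    if not section.any():
        raise ValueError(f"empty cross-section at station {station}")
    rem_axes = [a for a in range(3) if a != cc]
    # rows/cols of the section correspond to the remaining axes in order
    dv_pos = rem_axes.index(mask.axis_of("DV"))
    idx = np.argwhere(section)
    h = _extent_mm(idx[:, dv_pos], mask.spacing[mask.axis_of("DV")])
    w = _extent_mm(idx[:, 1 - dv_pos], mask.spacing[mask.axis_of("ML")])
    return h, w


def aortic_dorsoventral_diameter(aorta_mask: LabelMask, station: int) -> float:
    """Dorsoventral diameter of the aorta at a transverse station.

    The station (slice index along the craniocaudal axis, conventionally
    chosen just caudal to the cranial mesenteric artery) is supplied by the
    caller; landmark detection is out of scope.
    """
    if aorta_mask.voxel_count == 0:
        raise EmptyMaskError("empty segmentation")
    cc = aorta_mask.axis_of("CC")
    if not 0 <= station < aorta_mask.shape[cc]:
        raise ValueError(f"station {station} outside volume extent")
    section = np.take(aorta_mask.occupancy, station, axis=cc)
    if not section.any():
        raise ValueError(f"aorta mask empty at station {station}")
    rem_axes = [a for a in range(3) if a != cc]
    dv_pos = rem_axes.index(aorta_mask.axis_of("DV"))
    idx = np.argwhere(section)
    return _extent_mm(idx[:, dv_pos], aorta_mask.spacing[aorta_mask.axis_of("DV")])
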