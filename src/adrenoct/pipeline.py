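"""End-to-end measurement of one gland from a CT volume and its mask."""

from __future__ import annotations

from typing import Any

from .grid_io import ImageGrid, LabelMask
from .indices import compute_rva
from .morphometry import (
    aortic_dorsoventral_diameter,
    craniocaudal_length,
    gland_frame_from_mask,
    height_width_at,
    locate_poles_and_isthmus,
    reorient_to_gland_frame,
)
from .volumetry import DEFAULT_HOMOGENEITY_SD_HU, compute_volume, mean_attenuation

__all__ = ["measure_gland"]


def measure_gland(
    grid: ImageGrid,
    mask: LabelMask,
    side: str = "left",
    aorta_mask: LabelMask | None = None,
    aorta_station: int | None = None,
    homogeneity_sd_hu: float = DEFAULT_HOMOGENEITY_SD_HU,
) -> dict[str, Any]:
    """Run the full measurement protocol on one segmented gland.

    Volumetry and attenuation are computed on the raw mask; the caliper
    measurements are taken after resampling the mask into its gland frame
    (length axis first); the RVA is added when an aorta mask and station
    are supplied.  Returns a flat JSON-serialisable report.
    """
    vol = compute_volume(mask)
    att = mean_attenuation(grid, mask, homogeneity_sd_hu=homogeneity_sd_hu)
    length_mm, _ = craniocaudal_length(mask)
    frame = gland_frame_from_mask(mask)
    reo = reorient_to_gland_frame(mask, frame)
    stations = locate_poles_and_isthmus(reo)
    cr_h, cr_w = height_width_at(reo, stations.cranial)
    ca_h, ca_w = height_width_at(reo, stations.caudal)

    report: dict[str, Any] = {
        "side": side,
        "volume_cm3": vol.total_volume_cm3,
        "voxel_count": vol.voxel_count,
        "mean_hu": att.mean_hu,
        "sd_hu": att.sd_hu,
        "n_voxels": att.n_voxels,
        "homogeneous": att.homogeneous,
        "length_mm": length_mm,
        "cranial_height_mm": cr_h,
        "cranial_width_mm": cr_w,
        "caudal_height_mm": ca_h,
        "caudal_width_mm": ca_w,
    }
    if side == "left":
        is_h, is_w = height_width_at(reo, stations.isthmus)
        report["isthmus_height_mm"] = is_h
        report["isthmus_width_mm"] = is_w
    if aorta_mask is not None:
        if aorta_station is None:
            raise ValueError("aorta_station is required when an aorta mask is given")
        d = aortic_dorsoventral_diameter(aorta_mask, aorta_station)
        report["aorta_dv_mm"] = d
        report["rva"] = compute_rva(vol.total_volume_cm3, d)
    return report
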