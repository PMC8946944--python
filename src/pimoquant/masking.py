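"""Binary-mask construction for stained tumor sections.

Implements the mask vocabulary of the xenograft workflow: a tumor-tissue
mask from the nuclear (DAPI) channel, an autofluorescent red-blood-cell
(RBC) exclusion mask, high-intensity marker masks with a calibrated
minimum-size filter, and mask arithmetic. All micron-valued parameters are
converted through the source image's own calibration; the one deliberate
exception is the tissue-edge erosion, which is specified in pixels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .types import BinaryMask, ChannelImage, ThresholdPolicy, um_to_px

__all__ = [
    "compute_threshold",
    "tissue_mask",
    "rbc_mask",
    "marker_mask",
    "subtract",
    "pimo_seed_mask",
]

#: connectivity for component labelling: 2 = 8-connected neighbours
DEFAULT_CONNECTIVITY = 2


def compute_threshold(img: ChannelImage, policy: ThresholdPolicy) -> float:
    """Return the intensity cutoff selected by ``policy`` on ``img``.

    A constant image under ``otsu`` has no between-class split; the
    constant itself is returned so that the downstream ``>=`` convention
    yields a full mask (callers record the degenerate case in provenance).
    """
    px = img.pixels
    if policy.method == "fixed":
        return float(policy.value)  # type: ignore[arg-type]
    if policy.method == "quantile":
        return float(np.quantile(px, policy.value))  # type: ignore[arg-type]
    # otsu
    if np.ptp(px) == 0:
        return float(px.flat[0])
    return float(threshold_otsu(px))


def _filled(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(mask)


def tissue_mask(
    nuclear: ChannelImage,
    policy: ThresholdPolicy,
    erosion_px: int = 10,
    fill_holes: bool = True,
) -> BinaryMask:
    """Tumor-section mask from the nuclear channel.

    Threshold, fill interior holes (necrotic DAPI-dark cores are still
    tumor area for zone restriction), then erode with a disk of radius
    ``erosion_px`` **pixels** to avoid sampling the section edge. Every
    downstream mask is restricted to this one.
    """
    if erosion_px < 0:
        raise ValueError("erosion_px must be non-negative")
    thr = compute_threshold(nuclear, policy)
    m = nuclear.pixels >= thr
    if fill_holes:
        m = _filled(m)
    if erosion_px > 0:
        m = ndimage.binary_erosion(m, structure=disk(erosion_px))
    if not m.any():
        warnings.warn("tissue mask is empty", stacklevel=2)
    return BinaryMask(
        m,
        nuclear.pixel_size_um,
        provenance=(
            f"tissue: {policy.method} threshold {thr:.6g} on {nuclear.label or 'nuclear'}, "
            f"fill_holes={fill_holes}, erosion {erosion_px} px"
        ),
        meta={"threshold": thr, "erosion_px": erosion_px, "policy": policy.method},
    )


def rbc_mask(
    nuclear: ChannelImage, policy: ThresholdPolicy, tissue: BinaryMask
) -> BinaryMask:
    """Mask of very bright autofluorescent red-blood-cell speckles.

    RBCs autofluoresce across channels, so they are segmented once (in the
    nuclear channel, well above the tissue threshold) and excluded from all
    intensity measurements. The cutoff must exceed the tissue threshold;
    anything else means the policy is segmenting tissue, not speckles.
    """
    if tissue.shape != nuclear.shape:
        raise ValueError("tissue mask and nuclear channel differ in shape")
    thr = compute_threshold(nuclear, policy)
    tissue_thr = tissue.meta.get("threshold")
    if tissue_thr is not None and thr <= tissue_thr:
        raise ValueError(
            f"RBC threshold {thr:.6g} must exceed the tissue threshold {tissue_thr:.6g}"
        )
    m = (nuclear.pixels >= thr) & tissue.pixels
    return BinaryMask(
        m,
        nuclear.pixel_size_um,
        provenance=f"rbc: {policy.method} threshold {thr:.6g}, restricted to tissue",
        meta={"threshold": thr, "policy": policy.method},
    )


def _size_filter(
    mask: np.ndarray,
    pixel_size_um: float,
    min_size_um: float,
    size_measure: str,
    connectivity: int,
) -> np.ndarray:
    """Drop connected components at or below the size floor.

    ``size_measure='equivalent_diameter'`` keeps components whose
    equivalent-circle diameter (µm) exceeds ``min_size_um``;
    ``'area'`` compares the component area in µm² against ``min_size_um``.
    """
    lab = label(mask, connectivity=connectivity)
    if lab.max() == 0:
        return np.zeros_like(mask)
    keep = np.zeros(lab.max() + 1, dtype=bool)
    for rp in regionprops(lab):
        if size_measure == "equivalent_diameter":
            size = rp.equivalent_diameter_area * pixel_size_um
        elif size_measure == "area":
            size = rp.area * pixel_size_um**2
        else:
            raise ValueError(f"unknown size_measure {size_measure!r}")
        keep[rp.label] = size > min_size_um
    return keep[lab]


def marker_mask(
    marker: ChannelImage,
    policy: ThresholdPolicy,
    tissue: BinaryMask,
    min_size_um: float = 30.0,
    size_measure: str = "equivalent_diameter",
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> BinaryMask:
    """High-intensity regions of a stain, size-filtered to kill speckle.

    Super-threshold pixels within tissue; connected components whose
    equivalent-circle diameter is <= ``min_size_um`` (default 30 µm) are
    removed so isolated bright pixels never enter quantification.
    """
    if tissue.shape != marker.shape:
        raise ValueError("tissue mask and marker channel differ in shape")
    if min_size_um <= 0:
        raise ValueError("min_size_um must be positive")
    thr = compute_threshold(marker, policy)
    m = (marker.pixels >= thr) & tissue.pixels
    m = _size_filter(m, marker.pixel_size_um, min_size_um, size_measure, connectivity)
    return BinaryMask(
        m,
        marker.pixel_size_um,
        provenance=(
            f"marker {marker.label!r}: {policy.method} threshold {thr:.6g}, "
            f"{size_measure} > {min_size_um} um, connectivity={connectivity}"
        ),
        meta={
            "threshold": thr,
            "min_size_um": min_size_um,
            "size_measure": size_measure,
            "connectivity": connectivity,
        },
    )


def subtract(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Set difference ``a AND NOT b`` on identically calibrated masks."""
    if a.shape != b.shape or not np.isclose(a.pixel_size_um, b.pixel_size_um):
        raise ValueError("masks differ in shape or calibration")
    return BinaryMask(
        a.pixels & ~b.pixels,
        a.pixel_size_um,
        provenance=f"({a.provenance}) minus ({b.provenance})",
        meta=dict(a.meta),
    )


def pimo_seed_mask(
    pimo: ChannelImage,
    fixed_threshold: float,
    tissue: BinaryMask,
    rbc: BinaryMask,
    min_size_um: float = 30.0,
    size_measure: str = "equivalent_diameter",
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> BinaryMask:
    """Pimonidazole-positive seed regions for zonal analysis.

    The PIMO cutoff is a *fixed* intensity shared by every serial section
    of one tumor (the caller picks it once and passes it to each section);
    the RBC mask is subtracted afterwards. The result seeds the concentric
    annulus zones.
    """
    m = marker_mask(
        pimo,
        ThresholdPolicy("fixed", fixed_threshold),
        tissue,
        min_size_um=min_size_um,
        size_measure=size_measure,
        connectivity=connectivity,
    )
    out = subtract(m, rbc)
    out.provenance = (
        f"pimo seed: fixed threshold {fixed_threshold:.6g}, "
        f"{size_measure} > {min_size_um} um, RBC subtracted"
    )
    out.meta = {**m.meta, "rbc_subtracted": True}
    return out
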