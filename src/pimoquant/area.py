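"""Percent-positive-area scoring of serially sectioned PDX tumors.

Serial sections of one tumor are stained with different antibodies (for
example GLUT3 alone, GLUT1/CA9, and a GLUT1/GLUT3/CA9 triple cocktail)
and compared by the fraction of tumor area each stain covers — not by
pixelwise overlap, which serial sections cannot support. The tumor mask
comes from E-cadherin (a membrane stain marking epithelial tumor cells)
rather than DAPI, no dilation is applied to the marker binary, and the
stain threshold is fixed on a designated *anchor* section (the triple
stain) and reused verbatim on the others so section-to-section staining
variation cannot re-tune the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .masking import _size_filter, compute_threshold
from .types import BinaryMask, ChannelImage, ThresholdPolicy

__all__ = [
    "SerialSectionSet",
    "AreaResult",
    "tumor_mask_ecad",
    "anchored_marker_masks",
    "percent_positive_area",
    "panel_comparison",
]


@dataclass
class SerialSectionSet:
    """Ordered serial sections of one tumor, one stain each.

    ``sections`` maps a stain label to that section's channels (at least
    an E-cadherin channel and the stain channel). ``anchor_label`` names
    the section whose stain image fixes the shared threshold.
    """

    sections: list[tuple[str, dict[str, ChannelImage]]]
    anchor_label: str
    stain_channel: str = "stain"
    ecad_channel: str = "ecadherin"

    def __post_init__(self) -> None:
        labels = [s for s, _ in self.sections]
        if self.anchor_label not in labels:
            raise ValueError(f"anchor {self.anchor_label!r} not among sections {labels}")
        sizes = {
            chans[self.stain_channel].pixel_size_um for _, chans in self.sections
        }
        if len(sizes) > 1:
            raise ValueError("all sections must share one pixel size")

    def channels(self, label: str) -> dict[str, ChannelImage]:
        for s, chans in self.sections:
            if s == label:
                return chans
        raise KeyError(label)


@dataclass
class AreaResult:
    """Percent of tumor area covered by one stain on one section."""

    stain: str
    stain_area_px: int
    tumor_area_px: int

    def __post_init__(self) -> None:
        if self.tumor_area_px <= 0:
            raise ValueError("tumor_area_px must be positive")
        if not (0 <= self.stain_area_px <= self.tumor_area_px):
            raise ValueError("stain area must lie within [0, tumor area]")

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.stain_area_px / self.tumor_area_px


def tumor_mask_ecad(
    ecad: ChannelImage,
    policy: ThresholdPolicy,
    erosion_px: int = 0,
    fill_holes: bool = True,
) -> BinaryMask:
    """Tumor mask from the E-cadherin channel.

    Threshold then fill holes: E-cadherin outlines membranes, so the
    raw super-threshold set is a lace of rings whose interiors are tumor
    cytoplasm and must be filled. No edge erosion by default (that step
    belonged to the DAPI recipe); an empty result is an error because
    percent area would be undefined.
    """
    thr = compute_threshold(ecad, policy)
    m = ecad.pixels >= thr
    if fill_holes:
        m = ndimage.binary_fill_holes(m)
    if erosion_px > 0:
        from skimage.morphology import disk

        m = ndimage.binary_erosion(m, structure=disk(erosion_px))
    if not m.any():
        raise ValueError("empty tumor mask: percent-positive area undefined")
    return BinaryMask(
        m,
        ecad.pixel_size_um,
        provenance=f"tumor (ecad): {policy.method} threshold {thr:.6g}, erosion {erosion_px} px",
        meta={"threshold": thr, "erosion_px": erosion_px},
    )


def anchored_marker_masks(
    sset: SerialSectionSet,
    policy: ThresholdPolicy,
    min_size_um: float = 30.0,
    tumor_policy: ThresholdPolicy | None = None,
    size_measure: str = "equivalent_diameter",
    connectivity: int = 2,
) -> dict[str, BinaryMask]:
    """Stain masks with the threshold fixed on the anchor section.

    The cutoff is computed once, on the anchor's stain channel, then
    applied verbatim to every section (a dimmer section therefore yields
    a smaller mask — the threshold is never re-fit). Each mask is
    restricted to its own section's E-cadherin tumor mask and
    size-filtered exactly as in the xenograft recipe.
    """
    anchor = sset.channels(sset.anchor_label)[sset.stain_channel]
    thr = compute_threshold(anchor, policy)
    tumor_policy = tumor_policy or ThresholdPolicy("otsu")
    out: dict[str, BinaryMask] = {}
    for stain, chans in sset.sections:
        stain_img = chans[sset.stain_channel]
        tumor = tumor_mask_ecad(chans[sset.ecad_channel], tumor_policy)
        m = (stain_img.pixels >= thr) & tumor.pixels
        m = _size_filter(m, stain_img.pixel_size_um, min_size_um, size_measure, connectivity)
        out[stain] = BinaryMask(
            m,
            stain_img.pixel_size_um,
            provenance=(
                f"stain {stain!r}: anchored threshold {thr:.6g} "
                f"(from {sset.anchor_label!r}), {size_measure} > {min_size_um} um"
            ),
            meta={
                "threshold": thr,
                "anchor": sset.anchor_label,
                "min_size_um": min_size_um,
                "tumor_area_px": tumor.area_px,
            },
        )
    return out


def percent_positive_area(stain_mask: BinaryMask, tumor_mask: BinaryMask) -> AreaResult:
    """Stain area within tumor, as percent of total tumor area."""
    if stain_mask.shape != tumor_mask.shape or not np.isclose(
        stain_mask.pixel_size_um, tumor_mask.pixel_size_um
    ):
        raise ValueError("masks differ in shape or calibration")
    tumor_px = tumor_mask.area_px
    if tumor_px == 0:
        raise ValueError("empty tumor mask: percent-positive area undefined")
    overlap = int((stain_mask.pixels & tumor_mask.pixels).sum())
    return AreaResult(stain=stain_mask.provenance or "stain", stain_area_px=overlap, tumor_area_px=tumor_px)


def panel_comparison(
    results: dict[str, AreaResult], reference: str = "triple"
) -> pd.DataFrame:
    """Percent areas per stain plus ratios of the reference stain to each.

    The ratio reference/stain quantifies how much more tumor area the
    combined (triple) stain covers than a single stain; a zero percent
    single stain gives a missing ratio rather than infinity.
    """
    if len(results) < 2:
        raise ValueError("need results for at least two stains")
    if reference not in results:
        raise ValueError(f"reference stain {reference!r} missing from results")
    ref_pct = results[reference].percent_positive
    rows = []
    for stain, res in results.items():
        pct = res.percent_positive
        ratio = ref_pct / pct if pct > 0 else float("nan")
        rows.append(
            {
                "stain": stain,
                "stain_area_px": res.stain_area_px,
                "tumor_area_px": res.tumor_area_px,
                "percent_positive": pct,
                f"ratio_{reference}_over_stain": ratio,
            }
        )
    return pd.DataFrame(rows)
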