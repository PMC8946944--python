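"""Concentric distance-band ("donut") analysis around hypoxic seed regions.

The seed mask (pimonidazole-positive tissue) is expanded into annular
bands — by default >0–15 µm and >15–30 µm — and everything further than
the last band is distal tumor background. Marker enrichment is reported
as the zone mean fluorescence divided by the background mean, so a fold
of 1 means "no different from tumor tissue far from any hypoxic pocket".

Dilation is implemented by thresholding the Euclidean distance transform
of the seed, which gives exact micron semantics for arbitrarily shaped
(including concave or merging) seeds: a pixel belongs to band k iff its
distance to the nearest seed pixel lies in ((k-1)·w, k·w].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import BinaryMask, ChannelImage

__all__ = ["ZoneSet", "ZoneStats", "crop_tiles", "build_zones", "zone_stats", "summarize_fields"]

BACKGROUND = "background"
SEED = "seed"


def _ring_label(k: int) -> str:
    return f"ring{k}"


@dataclass
class ZoneSet:
    """Disjoint labeled zones: seed, annuli, and distal background.

    Invariants (checked at construction): zones are pairwise disjoint,
    all restricted to tissue, and ring k sits between the k-1 and k
    micron-dilations of the seed.
    """

    seed: BinaryMask
    rings: list[BinaryMask]
    background: BinaryMask
    ring_width_um: float
    n_rings: int
    empty_seed: bool = False

    def labels(self) -> list[str]:
        return [SEED] + [_ring_label(k + 1) for k in range(len(self.rings))] + [BACKGROUND]

    def masks(self) -> dict[str, BinaryMask]:
        out = {SEED: self.seed}
        for k, r in enumerate(self.rings, start=1):
            out[_ring_label(k)] = r
        out[BACKGROUND] = self.background
        return out

    def _check(self) -> None:
        arrs = [m.pixels for m in self.masks().values()]
        total = np.zeros_like(arrs[0], dtype=np.uint8)
        for a in arrs:
            total += a.astype(np.uint8)
        if total.max() > 1:
            raise AssertionError("zones are not pairwise disjoint")


@dataclass
class ZoneStats:
    """Per-marker zone means and folds relative to distal background.

    Zones with zero pixels are *missing* (NaN), never zero: an empty ring
    carries no information and must not drag fold summaries toward 0.
    When the background zone itself is empty every fold is undefined and
    ``background_defined`` is False.
    """

    marker: str
    mean_intensity: dict[str, float]
    background_mean: float
    fold_change: dict[str, float]
    pixel_counts: dict[str, int]
    background_defined: bool = True
    field_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "field": self.field_id,
                "marker": self.marker,
                "zone": z,
                "pixel_count": self.pixel_counts[z],
                "mean_intensity": self.mean_intensity[z],
                "fold_change": self.fold_change[z],
            }
            for z in self.mean_intensity
        ]
        return pd.DataFrame(rows)


def crop_tiles(img: ChannelImage, tile_mm: float = 5.0) -> list[ChannelImage]:
    """Cut a stitched image into non-overlapping ``tile_mm`` squares.

    Trailing partial tiles are dropped. An image smaller than one tile is
    returned whole, with a warning, rather than discarded.
    """
    if tile_mm <= 0:
        raise ValueError("tile_mm must be positive")
    side = int(round(tile_mm * 1000.0 / img.pixel_size_um))
    h, w = img.shape
    ny, nx = h // side, w // side
    if ny == 0 or nx == 0:
        warnings.warn(
            f"image ({h}x{w} px) smaller than one {tile_mm} mm tile; returning it whole",
            stacklevel=2,
        )
        return [img]
    tiles = []
    for iy in range(ny):
        for ix in range(nx):
            r0, c0 = iy * side, ix * side
            tiles.append(
                ChannelImage(
                    img.pixels[r0 : r0 + side, c0 : c0 + side].copy(),
                    img.pixel_size_um,
                    label=img.label,
                    origin_px=(img.origin_px[0] + r0, img.origin_px[1] + c0),
                )
            )
    return tiles


def seed_distance_um(seed: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Euclidean distance (µm) from each pixel to the nearest seed pixel."""
    if not seed.any():
        return np.full(seed.shape, np.inf)
    return ndimage.distance_transform_edt(~seed) * pixel_size_um


def build_zones(
    seed: BinaryMask,
    tissue: BinaryMask,
    rbc: BinaryMask,
    ring_width_um: float = 15.0,
    n_rings: int = 2,
    exclude_rbc_everywhere: bool = True,
) -> ZoneSet:
    """Expand a seed into annular bands and a distal background zone.

    ring_k = pixels with seed distance in ((k-1)·w, k·w]; background =
    tissue further than n_rings·w from any seed. All zones are restricted
    to tissue. By default the RBC mask is excluded from *every* zone so
    cross-channel autofluorescence cannot inflate zone means; with
    ``exclude_rbc_everywhere=False`` only the seed (which already had RBC
    subtracted upstream) is affected, matching the narrowest reading of
    the original recipe.
    """
    for m, nm in ((tissue, "tissue"), (rbc, "rbc")):
        if m.shape != seed.shape or not np.isclose(m.pixel_size_um, seed.pixel_size_um):
            raise ValueError(f"{nm} mask differs from seed in shape or calibration")
    if ring_width_um <= 0 or n_rings < 1:
        raise ValueError("ring_width_um must be > 0 and n_rings >= 1")

    px = seed.pixel_size_um
    tissue_ok = tissue.pixels & ~rbc.pixels if exclude_rbc_everywhere else tissue.pixels
    empty_seed = not seed.pixels.any()
    if empty_seed:
        warnings.warn("empty seed: all zones empty, background = tissue - rbc", stacklevel=2)
    d = seed_distance_um(seed.pixels, px)

    seed_zone = seed.pixels & tissue_ok
    rings: list[BinaryMask] = []
    for k in range(1, n_rings + 1):
        band = (d > (k - 1) * ring_width_um) & (d <= k * ring_width_um) & tissue_ok
        rings.append(
            BinaryMask(band, px, provenance=f"ring >{(k-1)*ring_width_um}-{k*ring_width_um} um")
        )
    bg = (d > n_rings * ring_width_um) & tissue.pixels & ~rbc.pixels
    zones = ZoneSet(
        seed=BinaryMask(seed_zone, px, provenance="seed zone (0 um)"),
        rings=rings,
        background=BinaryMask(bg, px, provenance=f"background >{n_rings*ring_width_um} um"),
        ring_width_um=ring_width_um,
        n_rings=n_rings,
        empty_seed=empty_seed,
    )
    zones._check()
    return zones


def zone_stats(marker: ChannelImage, zones: ZoneSet, field_id: str = "") -> ZoneStats:
    """Mean raw marker intensity per zone and fold vs. distal background.

    Intensities are taken from the raw channel — the fold normalization by
    the distal-background mean absorbs any additive offset. Folds are NaN
    for empty zones, and for all zones when the background zone is empty.
    """
    if marker.shape != zones.seed.shape:
        raise ValueError("marker shape does not match zones")
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for z, m in zones.masks().items():
        n = m.area_px
        counts[z] = n
        means[z] = float(marker.pixels[m.pixels].mean()) if n else float("nan")
    bg = means[BACKGROUND]
    bg_ok = counts[BACKGROUND] > 0
    if not bg_ok:
        warnings.warn("background zone empty: fold changes undefined", stacklevel=2)
    folds = {
        z: (means[z] / bg if bg_ok and counts[z] > 0 else float("nan")) for z in means
    }
    return ZoneStats(
        marker=marker.label,
        mean_intensity=means,
        background_mean=bg,
        fold_change=folds,
        pixel_counts=counts,
        background_defined=bg_ok,
        field_id=field_id,
    )


def summarize_fields(stats: list[ZoneStats]) -> pd.DataFrame:
    """Per-tumor table across optical fields.

    Keeps one row per (field, zone) and appends two aggregates per zone:
    a pixel-weighted mean fold (pooled-pixel estimate) and the unweighted
    mean of per-field folds, since either aggregation is defensible when
    several fields of one tumor are combined.
    """
    if not stats:
        raise ValueError("need at least one field")
    per_field = pd.concat([s.to_frame() for s in stats], ignore_index=True)
    aggs = []
    for (marker, zone), grp in per_field.groupby(["marker", "zone"], sort=False):
        ok = grp["fold_change"].notna() & (grp["pixel_count"] > 0)
        g = grp[ok]
        w = g["pixel_count"].to_numpy(dtype=float)
        weighted = float(np.average(g["fold_change"], weights=w)) if len(g) else float("nan")
        unweighted = float(g["fold_change"].mean()) if len(g) else float("nan")
        aggs.append(
            {
                "field": "pooled_weighted",
                "marker": marker,
                "zone": zone,
                "pixel_count": int(w.sum()),
                "mean_intensity": float("nan"),
                "fold_change": weighted,
            }
        )
        aggs.append(
            {
                "field": "mean_of_fields",
                "marker": marker,
                "zone": zone,
                "pixel_count": int(w.sum()),
                "mean_intensity": float("nan"),
                "fold_change": unweighted,
            }
        )
    return pd.concat([per_field, pd.DataFrame(aggs)], ignore_index=True)
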