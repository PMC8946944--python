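"""Seeded synthetic tumor-section images and DE tables with known truth.

Every downstream stage of the pipeline is validated against data from
this module, because the generator records exactly what it drew: the
tissue footprint, the hypoxic-pocket (pimonidazole-positive) mask, the
red-blood-cell speckles, the realized per-zone marker folds, and the true
percent-positive areas. Generation is a pure function of the spec and its
seed.

The image model, briefly:

* tissue occupies the frame minus a blank border;
* hypoxic pockets are unions of 1–3 overlapping ellipses (irregular
  blobs), placed inside the tissue;
* the pimonidazole channel is plateau-bright inside pockets with a sharp
  exponential edge (adduct formation is threshold-like in oxygen);
* marker channels follow a radial fold profile: the seed fold inside a
  pocket, interpolated linearly through the ring-midpoint folds down to
  1.0 at the outer band edge — hypoxia markers show graded halos;
* red blood cells are small, very bright disks burned into *every*
  channel (their autofluorescence crosses filter sets);
* additive Gaussian noise, clipped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import BinaryMask, ChannelImage
from .zonal import BACKGROUND, SEED, build_zones

__all__ = [
    "SectionSpec",
    "SectionGroundTruth",
    "DESpec",
    "generate_section",
    "generate_serial_sections",
    "generate_pdx_sections",
    "generate_de_tables",
]


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of one synthetic stained section.

    ``zone_fold`` gives the true marker fold versus distal background at
    the seed (inside pockets) and at each ring midpoint; the background
    fold is 1 by construction. ``gradient_halfwidth_um`` is the distance
    over which the pimonidazole edge intensity decays to half.
    """

    height_px: int = 512
    width_px: int = 512
    pixel_size_um: float = 1.0
    n_pockets: int = 3
    pocket_radius_um: tuple[float, float] = (30.0, 60.0)
    gradient_halfwidth_um: float = 2.0
    tissue_margin_px: int = 10
    n_rbc: int = 5
    rbc_radius_um: float = 6.0
    background_mean: float = 100.0
    zone_fold: Mapping[str, float] = field(
        default_factory=lambda: {"seed": 3.0, "ring1": 2.0, "ring2": 1.5}
    )
    noise_sd: float = 10.0
    seed: int = 0
    # secondary knobs (fixed study conditions, rarely touched)
    pimo_fold: float = 5.0  # pimo plateau over background inside pockets
    rbc_fold: float = 10.0  # RBC speckle intensity over background
    ring_width_um: float = 15.0
    nuclear_texture: float = 0.15  # relative amplitude of smooth DAPI texture

    def validate(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.pocket_radius_um
        if not (0 < lo <= hi):
            raise ValueError("pocket_radius_um must satisfy 0 < min <= max")
        if self.gradient_halfwidth_um <= 0 or self.rbc_radius_um <= 0:
            raise ValueError("physical lengths must be positive")
        if self.n_pockets < 0 or self.n_rbc < 0 or self.tissue_margin_px < 0:
            raise ValueError("counts and margins must be non-negative")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if SEED not in self.zone_fold:
            raise ValueError("zone_fold must contain a 'seed' entry")
        if any(v < 0 for v in self.zone_fold.values()):
            raise ValueError("zone folds must be >= 0")

    @property
    def n_rings(self) -> int:
        return sum(1 for k in self.zone_fold if k.startswith("ring"))


@dataclass
class SectionGroundTruth:
    """What the generator actually drew, for use as an oracle.

    ``true_zone_fold`` holds the realized mean of the noiseless fold
    field over each ground-truth zone (RBC pixels excluded), so
    recomputing a zone mean from the emitted noiseless image over these
    masks reproduces it to machine precision. ``true_percent_area`` maps
    channel label to the percent of tissue covered by its half-maximum
    super-threshold region.
    """

    tissue_mask: BinaryMask
    pimo_mask: BinaryMask
    rbc_mask: BinaryMask
    true_zone_fold: dict[str, float]
    true_percent_area: dict[str, float]
    pocket_centroids_um: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers


def _rngs(seed: int, n_sections: int):
    """Deterministic child generators: one for geometry, one shared content
    stream per section (serial sections share noise by design), one jitter."""
    geo = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    content_seed = np.random.SeedSequence([int(seed), 202])
    jitter = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    return geo, content_seed, jitter


def _draw_pockets(spec: SectionSpec, rng: np.random.Generator) -> list[dict]:
    """Sample pocket geometry: per pocket a center plus 1-3 ellipses."""
    h_um = spec.height_px * spec.pixel_size_um
    w_um = spec.width_px * spec.pixel_size_um
    margin_um = spec.tissue_margin_px * spec.pixel_size_um
    lo, hi = spec.pocket_radius_um
    pockets = []
    for _ in range(spec.n_pockets):
        r = rng.uniform(lo, hi)
        # ellipse extent can reach 1.4 r (offset 0.4 r + semi-axis r); keep the
        # pocket plus a 30 um halo clear of the tissue edge when space permits
        inset = margin_um + 1.4 * r + 30.0
        cy = rng.uniform(inset, h_um - inset) if 2 * inset < h_um else h_um / 2
        cx = rng.uniform(inset, w_um - inset) if 2 * inset < w_um else w_um / 2
        n_ell = rng.integers(1, 4)
        ellipses = []
        for _ in range(n_ell):
            ellipses.append(
                dict(
                    dy=rng.uniform(-0.4, 0.4) * r,
                    dx=rng.uniform(-0.4, 0.4) * r,
                    a=rng.uniform(0.6, 1.0) * r,
                    b=rng.uniform(0.6, 1.0) * r,
                    theta=rng.uniform(0, np.pi),
                )
            )
        pockets.append(dict(cy=cy, cx=cx, r=r, ellipses=ellipses))
    return pockets


def _rasterize_pockets(
    spec: SectionSpec,
    pockets: Iterable[dict],
    offset_um: tuple[float, float] = (0.0, 0.0),
    subset: Sequence[int] | None = None,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    yy = yy * spec.pixel_size_um
    xx = xx * spec.pixel_size_um
    mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    for i, p in enumerate(pockets):
        if subset is not None and i not in subset:
            continue
        for e in p["ellipses"]:
            cy = p["cy"] + e["dy"] + offset_um[0]
            cx = p["cx"] + e["dx"] + offset_um[1]
            ct, st = np.cos(e["theta"]), np.sin(e["theta"])
            u = (yy - cy) * ct + (xx - cx) * st
            v = -(yy - cy) * st + (xx - cx) * ct
            mask |= (u / e["a"]) ** 2 + (v / e["b"]) ** 2 <= 1.0
    return mask


def _draw_rbcs(spec: SectionSpec, rng: np.random.Generator) -> np.ndarray:
    h_um = spec.height_px * spec.pixel_size_um
    w_um = spec.width_px * spec.pixel_size_um
    yy, xx = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    yy = yy * spec.pixel_size_um
    xx = xx * spec.pixel_size_um
    mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    margin_um = spec.tissue_margin_px * spec.pixel_size_um
    r = spec.rbc_radius_um
    for _ in range(spec.n_rbc):
        cy = rng.uniform(margin_um + r, h_um - margin_um - r)
        cx = rng.uniform(margin_um + r, w_um - margin_um - r)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def _tissue(spec: SectionSpec) -> np.ndarray:
    m = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    b = spec.tissue_margin_px
    if b == 0:
        m[:] = True
    else:
        m[b:-b, b:-b] = True
    return m


def _fold_profile(spec: SectionSpec, dist_um: np.ndarray) -> np.ndarray:
    """Radial marker fold versus distance from the pocket boundary.

    Seed fold inside pockets (distance 0); outside, linear through the
    ring-midpoint folds down to 1.0 at the outer band edge and beyond.
    """
    w = spec.ring_width_um
    n = spec.n_rings
    knots = [0.0] + [(k - 0.5) * w for k in range(1, n + 1)] + [n * w]
    vals = [float(spec.zone_fold[SEED])]
    vals += [float(spec.zone_fold[f"ring{k}"]) for k in range(1, n + 1)]
    vals += [1.0]
    finite = np.minimum(dist_um, knots[-1] + 1.0)
    return np.interp(finite, knots, vals)


# ---------------------------------------------------------------------------
# section generation


def _render_section(
    spec: SectionSpec,
    pockets: list[dict],
    offset_um: tuple[float, float],
    content_seed: np.random.SeedSequence,
) -> tuple[dict[str, ChannelImage], SectionGroundTruth]:
    rng = np.random.default_rng(content_seed)
    tissue = _tissue(spec)
    pocket = _rasterize_pockets(spec, pockets, offset_um) & tissue
    rbc = _draw_rbcs(spec, rng) & tissue
    bg = spec.background_mean
    px = spec.pixel_size_um

    if pocket.any():
        dist = ndimage.distance_transform_edt(~pocket) * px
    else:
        dist = np.full(pocket.shape, np.inf)

    fold = _fold_profile(spec, dist)
    marker_clean = np.where(tissue, bg * fold, 0.0)
    pimo_decay = np.exp2(-dist / spec.gradient_halfwidth_um)
    pimo_clean = np.where(tissue, bg * (1.0 + (spec.pimo_fold - 1.0) * pimo_decay), 0.0)
    texture = ndimage.gaussian_filter(rng.standard_normal(tissue.shape), sigma=8)
    tsd = texture.std()
    if tsd > 0:
        texture = texture / tsd * spec.nuclear_texture
    nuclear_clean = np.where(tissue, bg * (1.0 + texture), 0.0)

    rbc_value = bg * spec.rbc_fold
    channels = {}
    for label, clean in (("nuclear", nuclear_clean), ("pimo", pimo_clean), ("marker", marker_clean)):
        img = np.where(rbc, rbc_value, clean)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)
        channels[label] = ChannelImage(img, px, label=label)

    # ground truth: realized zone folds of the noiseless fold field
    # (an empty seed is a legitimate no-pocket spec here, not a pipeline
    # anomaly, so the empty-seed warning is suppressed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        zones = build_zones(
            BinaryMask(pocket, px, provenance="true pocket"),
            BinaryMask(tissue, px, provenance="true tissue"),
            BinaryMask(rbc, px, provenance="true rbc"),
            ring_width_um=spec.ring_width_um,
            n_rings=spec.n_rings,
        )
    true_fold: dict[str, float] = {}
    for z, m in zones.masks().items():
        true_fold[z] = float(fold[m.pixels].mean()) if m.area_px else float("nan")

    tissue_area = tissue.sum()
    half_max = 1.0 + (float(spec.zone_fold[SEED]) - 1.0) / 2.0
    pct = {
        "pimo": 100.0 * pocket.sum() / tissue_area,
        "marker": 100.0 * ((fold >= half_max) & tissue).sum() / tissue_area,
    }
    centroids = []
    for p in pockets:
        centroids.append((p["cy"] + offset_um[0], p["cx"] + offset_um[1]))
    gt = SectionGroundTruth(
        tissue_mask=BinaryMask(tissue, px, provenance="true tissue"),
        pimo_mask=BinaryMask(pocket, px, provenance="true pocket"),
        rbc_mask=BinaryMask(rbc, px, provenance="true rbc"),
        true_zone_fold=true_fold,
        true_percent_area=pct,
        pocket_centroids_um=centroids,
    )
    return channels, gt


def generate_serial_sections(
    spec: SectionSpec, n: int, jitter_um: float = 0.0
) -> list[tuple[dict[str, ChannelImage], SectionGroundTruth]]:
    """Serial sections sharing one pocket geometry, translated by jitter.

    Adjacent physical sections cut the same pockets a few microns apart;
    this is modelled as a rigid translation of the pocket geometry with a
    seeded magnitude of at most ``jitter_um / 2`` per section (so any two
    sections differ by at most ``jitter_um``). Stain content (noise
    field, RBC placement) is shared across the set, making ``jitter=0``
    sections bit-identical — the oracle contract for serial consistency.
    """
    spec.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if jitter_um < 0:
        raise ValueError("jitter_um must be non-negative")
    geo, content_seed, jrng = _rngs(spec.seed, n)
    pockets = _draw_pockets(spec, geo)
    out = []
    for _ in range(n):
        ang = jrng.uniform(0, 2 * np.pi)
        mag = jrng.uniform(0, jitter_um / 2.0)
        off = (mag * np.sin(ang), mag * np.cos(ang)) if jitter_um > 0 else (0.0, 0.0)
        out.append(_render_section(spec, pockets, off, content_seed))
    return out


def generate_section(
    spec: SectionSpec,
) -> tuple[dict[str, ChannelImage], SectionGroundTruth]:
    """Generate one synthetic stained section (channels + ground truth)."""
    return generate_serial_sections(spec, 1, 0.0)[0]


def generate_pdx_sections(
    spec: SectionSpec,
    stain_pockets: Mapping[str, Sequence[int] | None],
    stain_fold: float = 3.0,
    jitter_um: float = 0.0,
) -> dict[str, tuple[dict[str, ChannelImage], SectionGroundTruth]]:
    """Serial PDX-style sections: E-cadherin plus one hard-edged stain each.

    ``stain_pockets`` maps stain label -> indices of the pockets that
    stain covers (``None`` = all). An anchor built from all pockets is
    the union of the single-stain patterns by construction, emulating a
    triple antibody cocktail over single stains. Stains are rendered as a
    flat plateau (``stain_fold`` x background) with hard edges, so the
    recorded ``true_percent_area`` is exact and threshold-independent.
    """
    spec.validate()
    geo, content_seed, jrng = _rngs(spec.seed, len(stain_pockets))
    pockets = _draw_pockets(spec, geo)
    bg = spec.background_mean
    px = spec.pixel_size_um
    tissue = _tissue(spec)
    tissue_area = tissue.sum()
    out: dict[str, tuple[dict[str, ChannelImage], SectionGroundTruth]] = {}
    for label, subset in stain_pockets.items():
        ang = jrng.uniform(0, 2 * np.pi)
        mag = jrng.uniform(0, jitter_um / 2.0)
        off = (mag * np.sin(ang), mag * np.cos(ang)) if jitter_um > 0 else (0.0, 0.0)
        pattern = _rasterize_pockets(spec, pockets, off, subset=subset) & tissue
        rng = np.random.default_rng(content_seed)
        rbc = _draw_rbcs(spec, rng) & tissue
        ecad_clean = np.where(tissue, bg * 2.0, 0.0)
        stain_clean = np.where(tissue, np.where(pattern, bg * stain_fold, bg), 0.0)
        rbc_value = bg * spec.rbc_fold
        chans = {}
        for ch_label, clean in (("ecadherin", ecad_clean), ("stain", stain_clean)):
            img = np.where(rbc, rbc_value, clean)
            if spec.noise_sd > 0:
                img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            chans[ch_label] = ChannelImage(np.clip(img, 0.0, None), px, label=ch_label)
        gt = SectionGroundTruth(
            tissue_mask=BinaryMask(tissue, px, provenance="true tissue"),
            pimo_mask=BinaryMask(pattern, px, provenance="true stain pattern"),
            rbc_mask=BinaryMask(rbc, px, provenance="true rbc"),
            true_zone_fold={},
            true_percent_area={"stain": 100.0 * pattern.sum() / tissue_area},
        )
        out[label] = (chans, gt)
    return out


# ---------------------------------------------------------------------------
# DE tables


@dataclass(frozen=True)
class DESpec:
    """Parameters of synthetic differential-expression tables.

    Emulates per-timepoint hypoxia-vs-normoxia contrasts: a planted
    subset of hypoxia-responsive genes gets a shared log2 fold change
    (``effect_log2fc``) with Gaussian scatter and small Beta-distributed
    adjusted p-values; null genes are centered at zero with uniform
    adjusted p-values. Adjusted p's are generated directly because the
    downstream summaries consume Padj, not counts.
    """

    n_genes: int = 5000
    n_comparisons: int = 3
    n_hypoxia_genes: int = 40
    effect_log2fc: float = 4.0
    null_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_comparisons <= 0:
            raise ValueError("n_genes and n_comparisons must be positive")
        if self.n_hypoxia_genes < 0 or self.n_hypoxia_genes > self.n_genes:
            raise ValueError("need 0 <= n_hypoxia_genes <= n_genes")
        if self.null_sd <= 0:
            raise ValueError("null_sd must be positive")


def generate_de_tables(spec: DESpec) -> tuple[list[pd.DataFrame], set[str]]:
    """Synthetic per-comparison DE tables and the planted hypoxia gene set.

    Returns one DataFrame per comparison with columns ``gene``,
    ``log2fc``, ``padj`` (comparison label in ``df.attrs['comparison']``)
    plus the set of planted hypoxia-responsive gene ids.
    """
    spec.validate()
    genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    hits = set(genes[: spec.n_hypoxia_genes])
    is_hit = np.zeros(spec.n_genes, dtype=bool)
    is_hit[: spec.n_hypoxia_genes] = True
    tables = []
    labels = [f"{t}h_vs_0h" for t in (6, 12, 24)]
    for j in range(spec.n_comparisons):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 404, j]))
        lfc = rng.normal(0.0, spec.null_sd, size=spec.n_genes)
        lfc[is_hit] = rng.normal(spec.effect_log2fc, spec.null_sd, size=is_hit.sum())
        padj = rng.uniform(0.0, 1.0, size=spec.n_genes)
        padj[is_hit] = rng.beta(0.5, 200.0, size=is_hit.sum())
        df = pd.DataFrame({"gene": genes, "log2fc": lfc, "padj": padj})
        df.attrs["comparison"] = labels[j] if j < len(labels) else f"cmp{j}"
        tables.append(df)
    return tables, hits
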