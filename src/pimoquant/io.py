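"""Reading and writing sections, masks, and provenance records.

Sections travel as multipage TIFF (one page per channel) with the
micron-per-pixel calibration in the TIFF resolution tags and a sidecar
YAML listing the channel labels (and a pixel-size fallback for files
whose tags were stripped). Masks are 8-bit PNG/TIFF, 0/255. Every table
written by the pipelines is accompanied by a JSON provenance record
holding the config snapshot and the thresholds actually used.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .types import BinaryMask, ChannelImage

__all__ = [
    "write_section",
    "read_section",
    "write_mask",
    "read_mask",
    "write_provenance",
]


def write_section(
    path: str | Path,
    channels: dict[str, ChannelImage],
    sidecar: str | Path | None = None,
) -> Path:
    """Write channels as a multipage TIFF plus a YAML sidecar.

    Resolution tags record pixels-per-centimeter derived from the shared
    micron-per-pixel calibration.
    """
    path = Path(path)
    labels = list(channels)
    px_um = channels[labels[0]].pixel_size_um
    if any(not np.isclose(c.pixel_size_um, px_um) for c in channels.values()):
        raise ValueError("all channels of one section must share pixel size")
    ppcm = 10000.0 / px_um
    with tifffile.TiffWriter(path) as tw:
        for lab in labels:
            tw.write(
                channels[lab].pixels.astype(np.float32),
                resolution=(ppcm, ppcm),
                resolutionunit="CENTIMETER",
                contiguous=False,
            )
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump({"channels": labels, "pixel_size_um": float(px_um)}, sort_keys=False)
    )
    return path


def _pixel_size_from_tags(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = xres if isinstance(xres, tuple) else (xres, 1)
    if num == 0:
        return None
    per_unit = num / den
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch, cm
    if unit_um is None:
        return None
    return unit_um / per_unit


def read_section(
    path: str | Path, sidecar: str | Path | None = None
) -> dict[str, ChannelImage]:
    """Read a multipage TIFF section back into labelled channels.

    Channel labels come from the sidecar YAML; the calibration comes from
    the TIFF resolution tags, falling back to the sidecar's
    ``pixel_size_um`` when tags are absent.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar YAML not found: {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    labels = meta["channels"]
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        if len(pages) != len(labels):
            raise ValueError(
                f"{path}: {len(pages)} pages but {len(labels)} channel labels"
            )
        px_um = _pixel_size_from_tags(pages[0]) or meta.get("pixel_size_um")
        if px_um is None:
            raise ValueError(f"{path}: no calibration in tags and no sidecar fallback")
        return {
            lab: ChannelImage(page.asarray().astype(float), float(px_um), label=lab)
            for lab, page in zip(labels, pages)
        }


def write_mask(path: str | Path, mask: BinaryMask) -> Path:
    """Write a mask as 8-bit 0/255 PNG (or TIFF, by extension)."""
    path = Path(path)
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path, pixel_size_um: float) -> BinaryMask:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127, pixel_size_um, provenance=f"read from {path}")


def write_provenance(
    path: str | Path,
    config: dict,
    thresholds: dict | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a JSON provenance record next to an output table."""
    from . import __version__

    rec = {
        "software": {"name": "pimoquant", "version": __version__},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "thresholds": thresholds or {},
    }
    if extra:
        rec.update(extra)
    path = Path(path)
    path.write_text(json.dumps(rec, indent=2, sort_keys=True, default=str))
    return path
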