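"""Reading slide images with physical-scale metadata, and writing overlays.

Whole-slide scans are pyramidal TIFFs (Aperio SVS is a TIFF variant); plain
PNG/TIFF rasters are first-class inputs for testing and small fields of view.
The physical scale is carried as microns-per-pixel (mpp) and rescaled by the
pyramid level's downsample factor, so area thresholds expressed in um^2 stay
meaningful at any working resolution.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import numpy as np
from PIL import Image

log = logging.getLogger("steatoquant")

#: Scanner resolution assumed when a raster carries no physical metadata
#: (0.249 um/px, the maximum resolution of a 40x Aperio scan).
DEFAULT_MPP = 0.249


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


class LevelError(ValueError):
    """Requested pyramid level does not exist."""


class GeometryError(ValueError):
    """Mask/image dimension mismatch."""


@dataclasses.dataclass
class SlideImage:
    """An RGB raster with physical scale provenance.

    Attributes
    ----------
    pixels : uint8 array, shape (H, W, 3)
        8-bit RGB data, row-major, origin top-left.
    mpp : float
        Microns per pixel (isotropic) at this level.
    level : int
        Pyramid level the pixels were read from (0 = full resolution).
    source_path : str
        Where the pixels came from; "<synthetic>" for generated slides.
    mpp_assumed : bool
        True when mpp was not found in metadata and the default was used.
    """

    pixels: np.ndarray
    mpp: float
    level: int = 0
    source_path: str = "<memory>"
    mpp_assumed: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:  # grayscale promoted to RGB
            px = np.stack([px] * 3, axis=-1)
        if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected an RGB raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("empty image")
        self.pixels = np.ascontiguousarray(px, dtype=np.uint8)
        if not (self.mpp > 0):
            raise ValueError(f"mpp must be positive, got {self.mpp}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def downsample(self, factor: int) -> "SlideImage":
        """Block-mean downsample by an integer factor; mpp scales with it."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if factor == 1:
            return self
        h, w = self.shape
        hh, ww = h // factor * factor, w // factor * factor
        blocks = self.pixels[:hh, :ww].reshape(
            hh // factor, factor, ww // factor, factor, 3
        )
        px = blocks.mean(axis=(1, 3)).round().astype(np.uint8)
        return SlideImage(
            pixels=px,
            mpp=self.mpp * factor,
            level=self.level,
            source_path=self.source_path,
            mpp_assumed=self.mpp_assumed,
        )


# ---------------------------------------------------------------------------
# metadata: microns per pixel
# ---------------------------------------------------------------------------

def _mpp_from_tiff(path: Path) -> float | None:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            # Aperio SVS stores "MPP = 0.249" inside ImageDescription
            desc = page.description or ""
            m = re.search(r"MPP\s*=\s*([0-9.eE+-]+)", desc)
            if m:
                return float(m.group(1))
            # generic TIFF: XResolution in pixels per ResolutionUnit
            tags = page.tags
            if "XResolution" in tags and "ResolutionUnit" in tags:
                num, den = tags["XResolution"].value
                unit = tags["ResolutionUnit"].value
                if num and den:
                    px_per_unit = num / den
                    unit_val = getattr(unit, "value", unit)
                    if unit_val == 3 and px_per_unit > 0:  # centimeter
                        return 10_000.0 / px_per_unit
                    if unit_val == 2 and px_per_unit > 0:  # inch
                        return 25_400.0 / px_per_unit
    except Exception:
        return None
    return None


def _mpp_from_png(path: Path) -> float | None:
    try:
        with Image.open(path) as im:
            dpi = im.info.get("dpi")
            if dpi and dpi[0] > 0:
                return 25_400.0 / float(dpi[0])
            # pHYs chunk: pixels per meter
            if "aspect" not in im.info and im.info.get("pHYs"):
                ppm = im.info["pHYs"][0]
                if ppm > 0:
                    return 1_000_000.0 / ppm
    except Exception:
        return None
    return None


def read_mpp(path: str | Path) -> tuple[float, bool]:
    """Microns-per-pixel from embedded metadata.

    Returns ``(mpp, assumed)``; ``assumed`` is True when no usable metadata was
    found and the configured default (:data:`DEFAULT_MPP`) was substituted.
    Non-positive metadata values are treated as absent. Never raises for a
    readable file.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    mpp: float | None = None
    if suffix in {".tif", ".tiff", ".svs"}:
        mpp = _mpp_from_tiff(path)
    elif suffix == ".png":
        mpp = _mpp_from_png(path)
    if mpp is None or not np.isfinite(mpp) or mpp <= 0:
        return DEFAULT_MPP, True
    return float(mpp), False


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_slide(path: str | Path, level: int | None = None) -> SlideImage:
    """Read a pyramidal TIFF/SVS or plain PNG/TIFF raster.

    For pyramidal files ``level`` selects the pyramid level (default 0, full
    resolution); mpp is scaled by that level's downsample factor. Plain rasters
    have a single level 0.

    Raises
    ------
    FormatError
        If the file does not exist or cannot be decoded.
    LevelError
        If the requested pyramid level does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff", ".svs"}:
        return _read_tiff(path, level)
    if suffix == ".png":
        if level not in (None, 0):
            raise LevelError(f"{path} is a plain raster; only level 0 exists")
        try:
            with Image.open(path) as im:
                px = np.asarray(im.convert("RGB"))
        except Exception as exc:
            raise FormatError(f"cannot decode {path}: {exc}") from exc
        mpp, assumed = read_mpp(path)
        return SlideImage(px, mpp=mpp, level=0, source_path=str(path), mpp_assumed=assumed)
    raise FormatError(f"unsupported image format: {path}")


def _read_tiff(path: Path, level: int | None) -> SlideImage:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            levels = series.levels if hasattr(series, "levels") else [series]
            if level is None:
                level = 0
            if not (0 <= level < len(levels)):
                raise LevelError(
                    f"level {level} absent in {path}; available levels: "
                    f"{list(range(len(levels)))}"
                )
            base_w = levels[0].shape[1] if len(levels[0].shape) >= 2 else 1
            lvl = levels[level]
            px = lvl.asarray()
            downsample = base_w / px.shape[1]
    except LevelError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    base_mpp, assumed = read_mpp(path)
    return SlideImage(
        px,
        mpp=base_mpp * downsample,
        level=level,
        source_path=str(path),
        mpp_assumed=assumed,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

#: Overlay colors follow the published rendering: accepted vacuoles green,
#: raw/rejected candidates yellow.
ACCEPTED_COLOR = (0, 200, 0)
REJECTED_COLOR = (230, 220, 0)


def render_overlay(
    image: SlideImage,
    accepted: np.ndarray,
    rejected: np.ndarray,
    blend: float = 0.5,
) -> np.ndarray:
    """Alpha-blend accepted (green) and rejected (yellow) masks over the RGB.

    Pixels outside both masks are returned untouched. Where the masks overlap,
    accepted wins.
    """
    accepted = np.asarray(accepted, dtype=bool)
    rejected = np.asarray(rejected, dtype=bool)
    if accepted.shape != image.shape or rejected.shape != image.shape:
        raise GeometryError(
            f"mask shape {accepted.shape}/{rejected.shape} does not match "
            f"image shape {image.shape}"
        )
    if not (0.0 <= blend <= 1.0):
        raise ValueError("blend must be in [0, 1]")
    out = image.pixels.astype(np.float64)
    for mask, color in ((rejected, REJECTED_COLOR), (accepted, ACCEPTED_COLOR)):
        if mask.any():
            tint = np.asarray(color, dtype=np.float64)
            out[mask] = (1.0 - blend) * out[mask] + blend * tint
    return out.round().astype(np.uint8)


def write_overlay(
    image: SlideImage,
    accepted: np.ndarray,
    rejected: np.ndarray,
    path: str | Path,
    blend: float = 0.5,
) -> Path:
    """Write the blended overlay as a PNG; returns the written path."""
    out = render_overlay(image, accepted, rejected, blend=blend)
    path = Path(path)
    Image.fromarray(out).save(path, format="PNG")
    return path


def write_png(pixels: np.ndarray, path: str | Path) -> Path:
    """Write an RGB or binary array as PNG (masks are saved as 0/255)."""
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    path = Path(path)
    Image.fromarray(arr).save(path, format="PNG")
    return path
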