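"""End-to-end macrovesicular steatosis quantification.

Stages, in order: tissue masking (grayscale, 5x5 mean filter, Otsu), artifact
suppression (closing, selective hole handling, glare removal), adaptive
vacuole candidate detection (local-mean dynamic threshold), shape-descriptor
classification, and area-fraction quantification with ordinal grading.

All physical thresholds are in um^2 and converted to pixels with the slide's
mpp, so the same configuration is scale-consistent across pyramid levels.
The filter defaults below are calibrations against the synthetic generator
(the descriptor thresholds a pathologist would tune interactively); they are
not canonical and every one is configurable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import filters, morphology

from .image_io import FormatError, LevelError, SlideImage, read_slide, write_overlay
from .shape_features import (
    LabeledRegion,
    ShapeFeatures,
    compute_features,
    extract_regions,
    features_table,
)

log = logging.getLogger("steatoquant")

#: Ordinal steatosis bins used for grading and for weighted-kappa agreement.
#: Half-open intervals: {0}, (0,5], (5,10], (10,15], (15,20], (20,30], (30,100].
CATEGORY_LABELS = ["0%", "1-5%", "6-10%", "11-15%", "16-20%", "21-30%", ">30%"]
_CATEGORY_EDGES = [0.0, 5.0, 10.0, 15.0, 20.0, 30.0]


class ConfigurationError(ValueError):
    """Pipeline configuration incompatible with the input image."""


class QuantificationError(RuntimeError):
    """Slide rejected (e.g., contains no tissue)."""


class PipelineError(RuntimeError):
    """A stage failed; the stage name is attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the quantification pipeline.

    Areas are in um^2, window sizes and crops in pixels, gray offsets in
    8-bit gray levels. Ratio descriptor bounds are dimensionless.
    """

    # stage 1: tissue mask
    mean_filter_size: int = 5          # px, smoothing before Otsu
    speckle_min_area: float = 2000.0   # um^2, debris removed from tissue mask
    edge_crop: int = 100               # px border band excluded (scan-edge artifacts)
    # stage 2: artifact suppression
    bridge_span: int = 10              # px, tears narrower than this are bridged
    void_max_area: float = 1.5e6       # um^2, holes larger than this stay excluded
    void_min_convexity: float = 0.85   # holes more ragged than this stay excluded
    glare_saturation_max: float = 0.10  # HSV saturation below => glare candidate
    glare_value_min: float = 0.995      # HSV value above => glare candidate
    glare_keep_low_saturation: bool = False  # literal-intersection polarity variant
    # stage 3: candidate detection
    dyn_window: int = 31               # px, local-mean window (odd)
    dyn_offset: float = 5.0            # gray levels above local mean
    # stage 4: classification
    vacuole_min_area: float = 50.0     # um^2
    vacuole_max_area: float = 12000.0  # um^2
    min_roundness: float = 0.55
    min_circularity: float = 0.45
    max_compactness: float = 2.0
    min_convexity: float = 0.80
    max_anisometry: float = 2.5
    exclude_border_regions: bool = True
    # rendering
    overlay_blend: float = 0.5

    def __post_init__(self) -> None:
        if self.dyn_window < 3 or self.dyn_window % 2 == 0:
            raise ConfigurationError("dyn_window must be odd and >= 3")
        if self.mean_filter_size < 1:
            raise ConfigurationError("mean_filter_size must be >= 1")
        for name in ("speckle_min_area", "void_max_area", "vacuole_min_area",
                     "vacuole_max_area"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.vacuole_min_area > self.vacuole_max_area:
            raise ConfigurationError("vacuole area bounds out of order")
        if self.edge_crop < 0:
            raise ConfigurationError("edge_crop must be >= 0")
        if not (0.0 <= self.overlay_blend <= 1.0):
            raise ConfigurationError("overlay_blend must be in [0, 1]")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yml", ".yaml"}:
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SteatosisResult:
    """Quantification output for one slide."""

    steatosis_pct: float
    tissue_area_um2: float
    vacuole_area_um2: float
    n_accepted: int
    n_rejected: int
    category: str
    per_region: list[tuple[ShapeFeatures, bool, str | None]]
    mpp: float = 1.0
    level: int = 0
    source_path: str = "<memory>"
    # pixel masks for overlay rendering (same geometry as the input image)
    tissue_mask: np.ndarray | None = None
    accepted_mask: np.ndarray | None = None
    rejected_mask: np.ndarray | None = None

    def report_dict(self, config: PipelineConfig | None = None) -> dict:
        d = {
            "input": self.source_path,
            "mpp": self.mpp,
            "level": self.level,
            "tissue_area_um2": round(self.tissue_area_um2, 3),
            "vacuole_area_um2": round(self.vacuole_area_um2, 3),
            "steatosis_pct": round(self.steatosis_pct, 4),
            "category": self.category,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
        }
        if config is not None:
            d["config"] = config.to_dict()
        return d


# ---------------------------------------------------------------------------
# stage 1: tissue mask
# ---------------------------------------------------------------------------

def _grayscale(image: SlideImage) -> np.ndarray:
    """Rec. 601 luminance in [0, 255] float."""
    px = image.pixels.astype(np.float64)
    return 0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2]


def tissue_mask(image: SlideImage, config: PipelineConfig) -> np.ndarray:
    """Binary tissue mask: stained (dark) foreground on bright background.

    Grayscale conversion, mean smoothing, Otsu threshold, speckle removal
    below ``speckle_min_area`` um^2, then exclusion of an ``edge_crop``-pixel
    border band of the frame (scanner edge artifacts).
    """
    h, w = image.shape
    crop = config.edge_crop
    if h <= 2 * crop or w <= 2 * crop:
        raise ConfigurationError(
            f"image {w}x{h} too small for edge_crop={crop}; use a smaller crop"
        )
    gray = _grayscale(image)
    smoothed = ndimage.uniform_filter(gray, size=config.mean_filter_size)
    if smoothed.max() - smoothed.min() < 1.0:
        # featureless image: no tissue/background bimodality
        return np.zeros((h, w), dtype=bool)
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed < thresh  # stained tissue is darker than background
    min_px = max(1, int(np.ceil(config.speckle_min_area / image.mpp**2)))
    mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    if crop > 0:
        mask[:crop, :] = False
        mask[-crop:, :] = False
        mask[:, :crop] = False
        mask[:, -crop:] = False
    return mask


# ---------------------------------------------------------------------------
# stage 2: artifact suppression
# ---------------------------------------------------------------------------

def suppress_artifacts(
    mask: np.ndarray, image: SlideImage, config: PipelineConfig
) -> np.ndarray:
    """Refine the tissue mask: bridge tears, handle voids, remove glare.

    1. Closing with a disk of radius ``bridge_span/2`` bridges gaps narrower
       than the span (thin tears and folds).
    2. Holes in the closed mask are filled back into the tissue denominator —
       unstained vacuoles and vessel lumina are tissue — except holes larger
       than ``void_max_area`` um^2 or with solidity below
       ``void_min_convexity``, which indicate true voids (folds, tears) and
       stay excluded.
    3. Low-saturation, near-maximal-value pixels (coverslip glare) are
       removed from the tissue mask.

    Pathological inputs degrade to pass-through with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        log.warning("suppress_artifacts: empty tissue mask, pass-through")
        return mask

    radius = max(1, config.bridge_span // 2)
    closed = ndimage.binary_closing(
        mask, structure=morphology.disk(radius), border_value=0
    )
    closed |= mask  # closing must never remove tissue

    # selective hole handling
    filled = ndimage.binary_fill_holes(closed)
    holes = filled & ~closed
    if holes.any():
        mpp2 = image.mpp**2
        hole_labels, n_holes = ndimage.label(holes)
        if n_holes:
            areas = ndimage.sum_labels(
                np.ones_like(hole_labels), hole_labels, index=np.arange(1, n_holes + 1)
            )
            for i in np.nonzero(areas * mpp2 > config.void_max_area)[0]:
                filled[hole_labels == i + 1] = False
            # ragged voids: solidity test only on holes big enough to matter
            from skimage.measure import regionprops

            for prop in regionprops(hole_labels):
                if prop.area * mpp2 > config.void_max_area:
                    continue  # already carved
                if prop.area >= 64 and prop.solidity < config.void_min_convexity:
                    filled[hole_labels == prop.label] = False
        result = filled
    else:
        result = closed

    # glare
    hsv = skcolor.rgb2hsv(image.pixels)
    glare = (hsv[..., 1] < config.glare_saturation_max) & (
        hsv[..., 2] >= config.glare_value_min
    )
    if config.glare_keep_low_saturation:
        # literal reading of "intersect with a low-saturation mask"
        result = result & (hsv[..., 1] < config.glare_saturation_max)
    else:
        result = result & ~glare
    # glare removal can strand fragments below the debris threshold
    min_px = max(1, int(np.ceil(config.speckle_min_area / image.mpp**2)))
    return morphology.remove_small_objects(result, max_size=min_px - 1)


# ---------------------------------------------------------------------------
# stage 3: candidate detection
# ---------------------------------------------------------------------------

def detect_candidates(
    image: SlideImage, tissue: np.ndarray, config: PipelineConfig
) -> np.ndarray:
    """Bright-on-dark dynamic threshold restricted to the tissue mask.

    A pixel is a vacuole candidate iff its gray value exceeds the local mean
    (``dyn_window`` x ``dyn_window``) by at least ``dyn_offset`` gray levels
    and it lies inside the tissue mask. Lipid vacuoles are unstained, hence
    bright against eosin-pink tissue.
    """
    tissue = np.asarray(tissue, dtype=bool)
    if not tissue.any():
        log.warning("detect_candidates: empty tissue mask, no candidates")
        return np.zeros_like(tissue)
    gray = _grayscale(image)
    local_mean = ndimage.uniform_filter(gray, size=config.dyn_window)
    return (gray >= local_mean + config.dyn_offset) & tissue


# ---------------------------------------------------------------------------
# stage 4: classification and quantification
# ---------------------------------------------------------------------------

#: Fixed evaluation order; the first failing criterion is the rejection reason.
_CRITERIA_ORDER = ("area", "roundness", "circularity", "compactness",
                   "convexity", "anisometry")


def _rejection_reason(f: ShapeFeatures, config: PipelineConfig) -> str | None:
    if config.exclude_border_regions and f.touches_border:
        return "border"
    if not (config.vacuole_min_area <= f.area_um2 <= config.vacuole_max_area):
        return "area"
    if f.roundness < config.min_roundness:
        return "roundness"
    if f.circularity < config.min_circularity:
        return "circularity"
    if f.compactness > config.max_compactness:
        return "compactness"
    if f.convexity < config.min_convexity:
        return "convexity"
    if f.anisometry > config.max_anisometry:
        return "anisometry"
    return None


def classify_candidates(
    features: list[ShapeFeatures], config: PipelineConfig
) -> list[tuple[ShapeFeatures, bool, str | None]]:
    """Accept vacuole-like regions; tag everything else with the first
    failing criterion (order: area, roundness, circularity, compactness,
    convexity, anisometry)."""
    out = []
    for f in features:
        reason = _rejection_reason(f, config)
        out.append((f, reason is None, reason))
    return out


def bin_category(pct: float) -> str:
    """Ordinal steatosis bin for a percentage in [0, 100]."""
    if not (0.0 <= pct <= 100.0) or not np.isfinite(pct):
        raise ValueError(f"steatosis percentage out of range: {pct}")
    if pct == 0.0:
        return CATEGORY_LABELS[0]
    for edge, label in zip(_CATEGORY_EDGES[1:], CATEGORY_LABELS[1:-1]):
        if pct <= edge:
            return label
    return CATEGORY_LABELS[-1]


def quantify(
    classified: list[tuple[ShapeFeatures, bool, str | None]],
    tissue: np.ndarray,
    mpp: float,
) -> SteatosisResult:
    """Steatosis percentage = 100 x accepted vacuole area / tissue area.

    The denominator is the artifact-suppressed tissue mask, which includes
    vacuole pixels (vacuoles are tissue), so the fraction is bounded by 100.
    """
    tissue = np.asarray(tissue, dtype=bool)
    tissue_area = float(tissue.sum()) * mpp * mpp
    if tissue_area <= 0:
        raise QuantificationError("no tissue detected; slide rejected")
    vac_area = float(sum(f.area_um2 for f, ok, _ in classified if ok))
    pct = 100.0 * vac_area / tissue_area
    return SteatosisResult(
        steatosis_pct=pct,
        tissue_area_um2=tissue_area,
        vacuole_area_um2=vac_area,
        n_accepted=sum(1 for _, ok, _ in classified if ok),
        n_rejected=sum(1 for _, ok, _ in classified if not ok),
        category=bin_category(min(pct, 100.0)),
        per_region=classified,
        mpp=mpp,
    )


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _masks_from_classification(
    regions: list[LabeledRegion],
    classified: list[tuple[ShapeFeatures, bool, str | None]],
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    accepted = np.zeros(shape, dtype=bool)
    rejected = np.zeros(shape, dtype=bool)
    for reg, (_, ok, _) in zip(regions, classified):
        target = accepted if ok else rejected
        r0, c0 = reg.offset
        h, w = reg.mask.shape
        target[r0 : r0 + h, c0 : c0 + w] |= reg.mask
    return accepted, rejected


def run_pipeline(
    source: str | Path | SlideImage,
    config: PipelineConfig | None = None,
    level: int | None = None,
) -> SteatosisResult:
    """Quantify one slide end to end.

    ``source`` is an image path (PNG/TIFF/SVS) or an in-memory
    :class:`SlideImage`. Deterministic for fixed (input, config). Stage
    failures are re-raised as :class:`PipelineError` with the stage name,
    except no-tissue which stays a :class:`QuantificationError`.
    """
    config = config or PipelineConfig()

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except (QuantificationError, ConfigurationError, FormatError, LevelError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(name, exc) from exc

    if isinstance(source, SlideImage):
        image = source
    else:
        image = stage("read_slide", read_slide, source, level)

    tissue = stage("tissue_mask", tissue_mask, image, config)
    tissue = stage("suppress_artifacts", suppress_artifacts, tissue, image, config)
    if not tissue.any():
        raise QuantificationError(
            f"no tissue detected in {image.source_path}; slide rejected"
        )
    candidates = stage("detect_candidates", detect_candidates, image, tissue, config)
    regions = stage("extract_regions", extract_regions, candidates, 8)
    feats = [compute_features(r, image.mpp) for r in regions]
    classified = stage("classify_candidates", classify_candidates, feats, config)
    result = stage("quantify", quantify, classified, tissue, image.mpp)

    result.mpp = image.mpp
    result.level = image.level
    result.source_path = image.source_path
    result.tissue_mask = tissue
    accepted, rejected = _masks_from_classification(regions, classified, image.shape)
    result.accepted_mask = accepted
    result.rejected_mask = rejected
    return result


def write_result(
    result: SteatosisResult,
    image: SlideImage,
    config: PipelineConfig,
    out_dir: str | Path,
    stem: str | None = None,
    manifest: dict | None = None,
) -> dict:
    """Write report JSON, overlay PNG and per-region CSV; returns the report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or (Path(result.source_path).stem or "slide")
    csv_path = out_dir / f"{stem}_regions.csv"
    features_table([f for f, _, _ in result.per_region]).assign(
        accepted=[ok for _, ok, _ in result.per_region],
        rejection_reason=[r or "" for _, _, r in result.per_region],
    ).to_csv(csv_path, index=False)
    overlay_path = out_dir / f"{stem}_overlay.png"
    write_overlay(
        image, result.accepted_mask, result.rejected_mask, overlay_path,
        blend=config.overlay_blend,
    )
    report = result.report_dict(config)
    report["per_region_csv"] = csv_path.name
    report["overlay_png"] = overlay_path.name
    if manifest is not None:
        report["manifest"] = manifest
    report_path = out_dir / f"{stem}_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
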