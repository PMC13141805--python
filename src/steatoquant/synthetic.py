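"""Seeded generator of H&E-like test slides with ground truth.

Renders the structures the classifier must separate — eosin-pink tissue,
bright round lipid vacuoles, elongated bright vessel lumina, background-
colored tears, and desaturated near-maximal glare patches — together with
exact pixel masks. The pipeline is grayscale-driven, so the colors are fixed
RGB anchors with seeded noise rather than physically realistic stain spectra;
what matters is that vacuoles are brighter than tissue by a margin well above
the dynamic-threshold offset.

Vacuoles are placed by rejection sampling without overlap, so the ground-truth
area fraction is exact (within the requested tolerance) and shapes stay
disc-like. Identical spec + seed reproduces the slide bit for bit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .image_io import SlideImage


class GenerationError(RuntimeError):
    """Requested slide is unreachable with the given parameters."""


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic slide.

    Sizes in pixels, diameters in microns; ``target_fraction`` is the vacuole
    area fraction of tissue (0-0.5). Colors are RGB anchors; per-pixel noise
    is seeded Gaussian. ``fraction_tol`` is the placement stopping tolerance
    (0.003 = +/-0.3 percentage points).
    """

    size: tuple[int, int] = (1024, 1024)
    mpp: float = 1.0
    tissue_shape: str = "disc"  # "disc" or "blob"
    tissue_radius_frac: float = 0.40
    tissue_color: tuple[int, int, int] = (230, 160, 180)
    tissue_noise_sd: float = 3.0
    target_fraction: float = 0.10
    vacuole_diameter_um: tuple[float, float] = (15.0, 100.0)
    vacuole_color: tuple[int, int, int] = (244, 242, 243)
    n_vessels: int = 0
    vessel_axis_ratio: tuple[float, float] = (3.0, 6.0)
    vessel_minor_um: tuple[float, float] = (15.0, 40.0)
    n_tears: int = 0
    n_glare: int = 0
    fraction_tol: float = 0.003
    placement_cap: int = 50_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fraction <= 0.5):
            raise ValueError("target_fraction must be in [0, 0.5]")
        lo, hi = self.vacuole_diameter_um
        if lo <= 0 or hi < lo:
            raise ValueError("vacuole diameter range must be positive and ordered")
        if self.tissue_shape not in ("disc", "blob"):
            raise ValueError("tissue_shape must be 'disc' or 'blob'")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")


@dataclasses.dataclass
class GroundTruth:
    """Exact pixel masks consistent with the rendered image.

    ``tissue_mask`` includes vacuole and vessel pixels (they are tissue) and
    excludes tears and glare. ``true_fraction`` is the quantity the pipeline
    estimates.
    """

    tissue_mask: np.ndarray
    vacuole_mask: np.ndarray
    vessel_mask: np.ndarray
    tear_mask: np.ndarray
    glare_mask: np.ndarray

    @property
    def true_fraction(self) -> float:
        t = self.tissue_mask.sum()
        if t == 0:
            return 0.0
        return float((self.vacuole_mask & self.tissue_mask).sum() / t)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _tissue_base(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r0 = spec.tissue_radius_frac * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    if spec.tissue_shape == "disc":
        return dist <= r0
    theta = np.arctan2(dy, dx)
    pert = np.ones_like(theta)
    for k in range(2, 6):
        amp = rng.normal(0.0, 0.05 / k)
        phase = rng.uniform(0, 2 * np.pi)
        pert += amp * np.cos(k * theta + phase)
    return dist <= r0 * pert


def _ellipse_patch(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    angle: float,
) -> np.ndarray:
    """Boolean mask of a rotated ellipse with semi-axes a, b."""
    h, w = shape
    cy, cx = center
    half = int(np.ceil(max(a, b))) + 2
    r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _irregular_disc(radius: float, rng: np.random.Generator) -> np.ndarray:
    """Local mask of a disc with a ~5% low-frequency boundary perturbation."""
    half = int(np.ceil(radius * 1.15)) + 2
    s = 2 * half + 1
    yy, xx = np.mgrid[0:s, 0:s]
    dy, dx = yy - half, xx - half
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    pert = 1.0
    for k in (2, 3):
        pert = pert + rng.uniform(0.01, 0.05) / (k - 1) * np.cos(
            k * theta + rng.uniform(0, 2 * np.pi)
        )
    return dist <= radius * pert


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_vacuoles(
    spec: SyntheticSpec,
    tissue: np.ndarray,
    occupied: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Non-overlapping irregular discs until the target fraction is reached."""
    h, w = tissue.shape
    gap = 3  # px clearance between objects so candidates never merge
    tissue_area = int(tissue.sum())
    target_px = spec.target_fraction * tissue_area
    tol_px = max(spec.fraction_tol * tissue_area, 1.0)
    vac = np.zeros_like(tissue)
    if target_px <= 0:
        return vac

    allowed = ndimage.binary_erosion(tissue, iterations=2, border_value=0)
    forbidden = ~allowed | ndimage.binary_dilation(occupied, iterations=gap)

    rows, cols = np.nonzero(allowed)
    if rows.size == 0:
        raise GenerationError("tissue too small to host vacuoles")
    r_min_px = spec.vacuole_diameter_um[0] / 2.0 / spec.mpp
    placed = 0.0
    attempts = 0
    while placed < target_px - tol_px:
        attempts += 1
        if attempts > spec.placement_cap:
            raise GenerationError(
                f"placement cap reached at fraction {placed / tissue_area:.4f} "
                f"(target {spec.target_fraction}); use smaller vacuoles, a lower "
                "target fraction, or a larger tissue region"
            )
        i = rng.integers(0, rows.size)
        cy, cx = int(rows[i]), int(cols[i])
        if forbidden[cy, cx]:
            continue
        d_um = rng.uniform(*spec.vacuole_diameter_um)
        r = d_um / 2.0 / spec.mpp
        # cap the radius so the target is not overshot
        needed = target_px - placed
        r_cap = np.sqrt((needed + tol_px) / np.pi)
        r = max(min(r, r_cap), r_min_px)
        patch = _irregular_disc(r, rng)
        half = patch.shape[0] // 2
        if cy - half < 0 or cx - half < 0 or cy + half + 1 > h or cx + half + 1 > w:
            continue
        win = (slice(cy - half, cy + half + 1), slice(cx - half, cx + half + 1))
        if (patch & forbidden[win]).any():
            continue
        area = patch.sum()
        if placed + area > target_px + tol_px:
            continue
        vac[win] |= patch
        forbidden[win] |= ndimage.binary_dilation(patch, iterations=gap)
        placed += area
    return vac


def generate_slide(spec: SyntheticSpec) -> tuple[SlideImage, GroundTruth]:
    """Render one synthetic slide and its exact ground-truth masks."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.size

    tissue = _tissue_base(spec, rng)
    if not tissue.any():
        raise GenerationError("empty tissue region; increase tissue_radius_frac")
    t_rows, t_cols = np.nonzero(tissue)

    # vessels: elongated bright lumina inside tissue
    vessel = np.zeros_like(tissue)
    for _ in range(spec.n_vessels):
        i = rng.integers(0, t_rows.size)
        b = rng.uniform(*spec.vessel_minor_um) / 2.0 / spec.mpp
        a = b * rng.uniform(*spec.vessel_axis_ratio)
        vessel |= _ellipse_patch(
            (h, w), (float(t_rows[i]), float(t_cols[i])), a, b,
            rng.uniform(0, np.pi),
        )
    vessel &= tissue

    # tears: thin background-colored bands across the tissue
    tear = np.zeros_like(tissue)
    if spec.n_tears:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(spec.n_tears):
            angle = rng.uniform(0, np.pi)
            offset = rng.uniform(-0.3, 0.3) * min(h, w) * spec.tissue_radius_frac
            width = rng.uniform(3.0, 7.0)
            line = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle) - offset
            tear |= np.abs(line) <= width / 2.0
        tear &= tissue
    vessel &= ~tear

    # glare: desaturated, near-maximal-value elliptical patches
    glare = np.zeros_like(tissue)
    for _ in range(spec.n_glare):
        i = rng.integers(0, t_rows.size)
        a = rng.uniform(25, 70)
        glare |= _ellipse_patch(
            (h, w), (float(t_rows[i]), float(t_cols[i])), a,
            a * rng.uniform(0.5, 1.0), rng.uniform(0, np.pi),
        )

    # final truth tissue: tears and glare are not viable tissue
    tissue_truth = tissue & ~tear & ~glare

    occupied = vessel | tear | glare
    vacuole = _place_vacuoles(spec, tissue_truth, occupied, rng)

    # ---------------- rendering ----------------
    img = np.full((h, w, 3), 255.0)
    texture = 1.0 + rng.normal(0.0, 0.02, (h, w))
    for c in range(3):
        chan = img[..., c]
        noise = rng.normal(0.0, spec.tissue_noise_sd, (h, w))
        chan[tissue_truth] = (
            spec.tissue_color[c] * texture[tissue_truth] + noise[tissue_truth]
        )
        vac_noise = rng.normal(0.0, 1.5, (h, w))
        chan[vacuole] = spec.vacuole_color[c] + vac_noise[vacuole]
        chan[vessel & ~vacuole] = spec.vacuole_color[c] - 2 + vac_noise[vessel & ~vacuole]
    # tears: background-colored cracks
    if tear.any():
        tear_noise = np.clip(rng.normal(252.0, 1.0, (h, w)), 248.0, 253.0)
        for c in range(3):
            img[..., c][tear] = tear_noise[tear]
    # glare: value pinned at 255 (max channel), saturation ~0.01-0.02
    if glare.any():
        blue = rng.uniform(250.0, 253.0, (h, w))
        img[..., 0][glare] = 255.0
        img[..., 1][glare] = 255.0
        img[..., 2][glare] = blue[glare]

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    slide = SlideImage(
        pixels=pixels,
        mpp=spec.mpp,
        level=0,
        source_path=f"<synthetic seed={spec.rng_seed}>",
    )
    truth = GroundTruth(
        tissue_mask=tissue_truth,
        vacuole_mask=vacuole,
        vessel_mask=vessel,
        tear_mask=tear,
        glare_mask=glare,
    )
    return slide, truth


def cohort(
    n: int,
    fraction_grid,
    seed: int,
    base_spec: SyntheticSpec | None = None,
    weights=None,
    sample: bool = True,
) -> list[tuple[SlideImage, GroundTruth]]:
    """Generate ``n`` slides with vacuole fractions drawn from a grid.

    With ``sample=True`` fractions are drawn from ``fraction_grid`` (optionally
    weighted), mimicking a right-skewed clinical spread when the grid is
    skewed; with ``sample=False`` the grid is cycled deterministically. Child
    seeds derive from the master ``seed``, so the cohort is reproducible and
    slides are pairwise distinct.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = np.atleast_1d(np.asarray(fraction_grid, dtype=float))
    rng = np.random.default_rng(seed)
    if sample:
        fractions = rng.choice(grid, size=n, p=weights)
    else:
        fractions = np.resize(grid, n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    base = base_spec or SyntheticSpec()
    out = []
    for frac, child in zip(fractions, child_seeds):
        spec = dataclasses.replace(
            base, target_fraction=float(frac), rng_seed=int(child)
        )
        out.append(generate_slide(spec))
    return out
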