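"""Three-class pixel probability maps and tissue-aware training-crop sampling.

The segmentation stage consumes per-pixel probabilities for three classes —
nuclear center, nucleus contour, background.  Learned providers (UNet- or
random-forest-based) are out of scope here; this module supplies a classical
generator with the same output contract, plus the random-ROI sampler used to
assemble training crops whose tissue fraction passes a global Otsu filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["ProbabilityMaps", "classical_probability_maps", "sample_training_crops"]


@dataclass
class ProbabilityMaps:
    """Per-pixel class probabilities: nuclear center, nucleus contour, background."""

    center: np.ndarray
    contour: np.ndarray
    background: np.ndarray
    source_channel: str = ""
    generator: str = "classical"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.center.shape == self.contour.shape == self.background.shape):
            raise ValueError("the three class maps must share a shape")
        total = self.center + self.contour + self.background
        if np.any(np.abs(total - 1.0) > 1e-6):
            raise ValueError("per-pixel class probabilities must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.center.shape

    def stack(self) -> np.ndarray:
        return np.stack([self.center, self.contour, self.background])

    def save(self, path) -> None:
        tifffile.imwrite(path, self.stack().astype(np.float32), photometric="minisblack")

    @classmethod
    def load(cls, path, **kw) -> "ProbabilityMaps":
        arr = tifffile.imread(path)
        if arr.shape[0] != 3:
            raise ValueError("probability-map TIFF must have 3 pages")
        return cls(arr[0].astype(np.float64), arr[1].astype(np.float64),
                   arr[2].astype(np.float64), **kw)


def _percentile_normalize(image: np.ndarray, lo: float = 1.0, hi: float = 99.0) -> np.ndarray:
    p_lo, p_hi = np.percentile(image, [lo, hi])
    if p_hi - p_lo < 1e-12:
        return np.zeros_like(image, dtype=np.float64)
    return np.clip((image - p_lo) / (p_hi - p_lo), 0, 1)


def classical_probability_maps(
    nuclear_image: np.ndarray,
    nucleus_diameter: float = 12.0,
    source_channel: str = "",
) -> ProbabilityMaps:
    """Generate three-class probability maps from a nuclear-stain image.

    Scores (computed after robust [1st, 99th]-percentile intensity
    normalisation, so they are invariant to affine rescaling of the input):

    - *center*: positive part of the inverted Laplacian-of-Gaussian response at
      sigma = diameter / (2 * sqrt(2)), the blob scale of a nucleus-sized disk;
    - *contour*: Gaussian-gradient magnitude at sigma = 1;
    - *background*: distance below the Otsu threshold of the normalised image.

    The three scores are rescaled to [0, 1] and normalised per pixel to sum
    to 1.  A constant image yields background probability 1 everywhere.
    """
    if nucleus_diameter < 3:
        raise ValueError("nucleus_diameter must be >= 3 px")
    img = _percentile_normalize(np.asarray(nuclear_image, dtype=np.float64))
    shape = img.shape

    if img.max() - img.min() < 1e-12:  # constant input: everything background
        z = np.zeros(shape)
        return ProbabilityMaps(z, z.copy(), np.ones(shape), source_channel,
                               params={"nucleus_diameter": nucleus_diameter})

    sigma = nucleus_diameter / (2 * np.sqrt(2))
    log_resp = -ndimage.gaussian_laplace(img, sigma) * sigma**2
    center = np.clip(log_resp, 0, None)

    # gradient magnitude is symmetric about the edge; gate it by intensity so
    # contour evidence sits on the nucleus side and background stays background
    grad = ndimage.gaussian_gradient_magnitude(img, sigma=1.0)
    contour = grad * img

    thr = threshold_otsu(img)
    background = np.clip(thr - img, 0, None)

    def _rescale(a: np.ndarray) -> np.ndarray:
        m = a.max()
        return a / m if m > 0 else a

    scores = np.stack([_rescale(center), _rescale(contour), _rescale(background)])
    total = scores.sum(axis=0)
    # pixels with no class evidence (e.g. flat bright interior plateaus) get a
    # weak uniform background prior before normalisation
    flat = total < 1e-9
    scores[2, flat] = 1.0
    total = scores.sum(axis=0)
    scores /= total
    return ProbabilityMaps(
        scores[0], scores[1], scores[2], source_channel,
        params={"nucleus_diameter": nucleus_diameter},
    )


def sample_training_crops(
    wsi: np.ndarray,
    crop_h: int,
    crop_w: int,
    n_crops: int,
    min_tissue_fraction: float = 0.0,
    seed: int = 0,
    attempt_budget: int | None = None,
) -> tuple[list[tuple[int, int]], dict]:
    """Sample random crop origins whose tissue fraction passes a global Otsu filter.

    A global Otsu threshold is computed once over the whole image; a random
    crop is kept iff the fraction of its pixels above that threshold is at
    least ``min_tissue_fraction``.  Sampling continues until ``n_crops`` are
    kept or the attempt budget is exhausted (a partial list is returned with a
    warning, never silently).

    Returns (origins, report) where origins are half-open top-left (y, x)
    corners and the report counts attempts and kept crops.
    """
    wsi = np.asarray(wsi)
    H, W = wsi.shape
    if crop_h > H or crop_w > W:
        raise ValueError(f"crop {crop_h}x{crop_w} does not fit in image {H}x{W}")
    if not 0 <= min_tissue_fraction <= 1:
        raise ValueError("min_tissue_fraction must be in [0, 1]")
    if attempt_budget is None:
        attempt_budget = max(1000, 100 * n_crops)

    thr = threshold_otsu(wsi) if min_tissue_fraction > 0 else -np.inf
    rng = np.random.default_rng(seed)
    origins: list[tuple[int, int]] = []
    attempts = 0
    while len(origins) < n_crops and attempts < attempt_budget:
        attempts += 1
        y = int(rng.integers(0, H - crop_h + 1))
        x = int(rng.integers(0, W - crop_w + 1))
        if min_tissue_fraction > 0:
            frac = float(np.mean(wsi[y : y + crop_h, x : x + crop_w] > thr))
            if frac < min_tissue_fraction:
                continue
        origins.append((y, x))
    report = {
        "attempts": attempts,
        "kept": len(origins),
        "requested": n_crops,
        "otsu_threshold": float(thr) if np.isfinite(thr) else None,
    }
    if len(origins) < n_crops:
        warnings.warn(
            f"attempt budget exhausted: kept {len(origins)}/{n_crops} crops "
            f"after {attempts} attempts",
            stacklevel=2,
        )
    return origins, report
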