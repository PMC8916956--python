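"""Retrospective flat-field / dark-field estimation and per-tile correction.

Uneven illumination (vignetting) multiplies every tile of a tiled acquisition
by the same smooth field.  With enough tiles of varied content, a per-pixel
robust statistic across the tile stack cancels the content and retains the
field: this module estimates the flat-field as the Gaussian-smoothed,
mean-normalised per-pixel median (or trimmed mean) of the stack, and the
optional dark-field as the smoothed per-pixel minimum.  Correction is the
standard shading model ``(tile - darkfield) / flatfield``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import trim_mean


@dataclass
class IlluminationModel:
    """Multiplicative flat-field (mean 1) and additive dark-field for one channel."""

    flatfield: np.ndarray
    darkfield: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        if self.flatfield.shape != self.darkfield.shape:
            raise ValueError("flatfield and darkfield shapes differ")
        if np.any(self.flatfield <= 0):
            raise ValueError("flatfield must be strictly positive")
        if abs(float(self.flatfield.mean()) - 1.0) > 1e-6:
            raise ValueError("flatfield mean must be 1 within 1e-6")


def estimate_flatfield(
    tiles: list[np.ndarray],
    channel: str = "",
    smoothing_scale: float | None = None,
    *,
    statistic: str = "median",
    with_darkfield: bool = False,
) -> IlluminationModel:
    """Estimate an illumination model from a stack of single-channel tiles.

    Parameters
    ----------
    tiles:
        2-D arrays of identical shape, one channel of each tile.
    smoothing_scale:
        Gaussian sigma in pixels; defaults to 1/20 of the tile width.
    statistic:
        Per-pixel robust statistic across the stack: ``median`` or
        ``trimmed_mean`` (10% trimmed).
    with_darkfield:
        Also estimate an additive dark-field as the smoothed per-pixel
        minimum; default off (zeros).
    """
    if len(tiles) == 0:
        raise ValueError("need at least one tile to estimate a flatfield")
    shape = tiles[0].shape
    if any(t.shape != shape for t in tiles):
        raise ValueError("all tiles must share one shape")
    if smoothing_scale is None:
        smoothing_scale = shape[1] / 20.0

    stack = np.stack([np.asarray(t, dtype=np.float64) for t in tiles])
    if statistic == "median":
        raw = np.median(stack, axis=0)
    elif statistic == "trimmed_mean":
        raw = trim_mean(stack, 0.1, axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    if len(tiles) == 1:
        warnings.warn(
            "flatfield estimated from a single tile: the result is the tile "
            "itself, smoothed and mean-normalised",
            stacklevel=2,
        )

    def _smooth(a: np.ndarray) -> np.ndarray:
        # one deconvolution step (2S - S^2) cancels the first-order smoothing
        # bias, which otherwise exceeds 1% near tile borders for curved fields
        s1 = ndimage.gaussian_filter(a, smoothing_scale, mode="nearest")
        s2 = ndimage.gaussian_filter(s1, smoothing_scale, mode="nearest")
        return 2 * s1 - s2

    dark = np.zeros(shape)
    if with_darkfield:
        dark = _smooth(stack.min(axis=0))

    flat = _smooth(raw - dark)
    mean = float(flat.mean())
    if mean <= 0 or np.any(flat <= 0):
        raise ValueError(
            "flatfield undefined: tile stack is zero/non-positive after "
            "dark-field subtraction"
        )
    flat = flat / mean
    # exact mean-1 normalisation despite floating-point rounding
    flat = flat / float(flat.mean())
    return IlluminationModel(flatfield=flat, darkfield=dark, channel=channel)


def apply_correction(tile: np.ndarray, model: IlluminationModel) -> np.ndarray:
    """Correct one tile: ``(tile - darkfield) / flatfield``, clipped at 0."""
    if tile.shape != model.flatfield.shape:
        raise ValueError(
            f"tile shape {tile.shape} does not match model {model.flatfield.shape}"
        )
    out = (np.asarray(tile, dtype=np.float64) - model.darkfield) / model.flatfield
    return np.clip(out, 0, None)


def correct_acquisition(acq, smoothing_scale: float | None = None) -> None:
    """Estimate and apply per-cycle, per-channel correction to an acquisition.

    Modifies tile data in place; intended as the first pipeline stage on a
    :class:`~mcmini.synthgen.AcquisitionTruth` or compatible object.
    """
    for cyc in range(acq.n_cycles):
        tiles = acq.tiles_for_cycle(cyc)
        if not tiles:
            continue
        for k, ch in enumerate(tiles[0].channel_names):
            model = estimate_flatfield(
                [t.data[k] for t in tiles], channel=ch, smoothing_scale=smoothing_scale
            )
            for t in tiles:
                t.data[k] = apply_correction(t.data[k], model).astype(t.data.dtype)
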