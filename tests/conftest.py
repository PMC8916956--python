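"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mcmini import synthgen


# ---------------------------------------------------------------- oracles


def bruteforce_ncc_shift(ref: np.ndarray, mov: np.ndarray, max_shift: int,
                         circular: bool = False):
    """Independent oracle: argmax of brute-force normalized cross-correlation
    over all integer shifts within ±max_shift (O(shifts × pixels)).

    For a candidate shift d the correlation is the Pearson coefficient of
    ``mov(p)`` against ``ref(p - d)``, over the circularly wrapped window
    (``circular=True``, exact for rolled arrays) or over the overlapping
    region only (default, correct for windows cut from a larger image).
    """
    h, w = ref.shape
    best, best_s = -np.inf, (0, 0)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            if circular:
                a = ref
                b = np.roll(mov, (-dy, -dx), axis=(0, 1))
            else:
                ys = slice(max(0, dy), h + min(0, dy))
                xs = slice(max(0, dx), w + min(0, dx))
                b = mov[ys, xs]
                a = ref[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
            a = a - a.mean()
            b = b - b.mean()
            denom = np.sqrt((a**2).sum() * (b**2).sum())
            if denom < 1e-12:
                continue
            v = (a * b).sum() / denom
            if v > best:
                best, best_s = v, (dy, dx)
    return best_s, best


def rasterize_disk(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def object_f1(mask, cells, iou_thr: float = 0.5) -> float:
    """Object-level F1 between a label mask and ground-truth disk cells,
    greedily matching each truth disk to its best-IoU unused label."""
    labels = mask.labels
    H, W = labels.shape
    areas = np.bincount(labels.ravel())
    tp, used = 0, set()
    for c in cells:
        y0, y1 = max(0, int(c.y - c.radius - 2)), min(H, int(c.y + c.radius + 3))
        x0, x1 = max(0, int(c.x - c.radius - 2)), min(W, int(c.x + c.radius + 3))
        disk = rasterize_disk(y1 - y0, x1 - x0, c.y - y0, c.x - x0, c.radius)
        sub = labels[y0:y1, x0:x1]
        labs, cnts = np.unique(sub[disk], return_counts=True)
        best_iou, best_lab = 0.0, None
        for lab, inter in zip(labs, cnts):
            if lab == 0 or lab in used:
                continue
            iou = inter / (disk.sum() + areas[lab] - inter)
            if iou > best_iou:
                best_iou, best_lab = iou, lab
        if best_iou >= iou_thr:
            tp += 1
            used.add(best_lab)
    n_pred = int((areas[1:] > 0).sum())
    fp, fn = n_pred - tp, len(cells) - tp
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0


def gauge_removed_errors(positions, true_origins, cycle: int, grid: tuple[int, int]):
    """Per-tile origin errors with the global translation (gauge) removed."""
    errs = np.array(
        [
            np.subtract(positions.origin(cycle, r, c), true_origins[(cycle, r, c)])
            for r in range(grid[0])
            for c in range(grid[1])
        ],
        dtype=float,
    )
    return errs - errs.mean(axis=0)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def tissue_100():
    """100 well-separated nuclei on a 512x512 frame (default soft rim)."""
    return synthgen.make_tissue_truth(100, (512, 512), seed=11, radius_range=(5.0, 8.0))


@pytest.fixture(scope="session")
def tissue_sharp():
    """Hard-edged disks for exactness checks (no rim blur, no noise)."""
    return synthgen.make_tissue_truth(50, (400, 400), seed=13, rim_blur_px=0.0)


@pytest.fixture(scope="session")
def jittered_acquisition():
    """3x3 grid, 10% overlap, 3-px jitter, 2 cycles with (7,7) offset, mild noise.

    The 800-px frame gives ~286-px tiles with ~29-px overlap strips, keeping
    the stage jitter small relative to the strip as in real acquisitions.
    """
    truth = synthgen.make_tissue_truth(140, (800, 800), seed=7, rim_blur_px=0.0)
    return synthgen.render_tiles(
        truth, 3, 3, overlap=0.1, jitter_sd=3.0, cycles=2, cycle_offset=(7, 7),
        noise_sd=5.0, seed=2,
    )
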