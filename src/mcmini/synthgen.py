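"""Synthetic multiplexed tissue and TMA image generation with full ground truth.

Every downstream stage of the pipeline (illumination correction, stitching,
dearraying, segmentation, quantification, spatial analysis) is tested against
rasters produced here, for which cell positions, marker intensities, tile
origins, illumination fields and core centers are known exactly.

Cells are non-overlapping disks with type-dependent marker intensity vectors
(uniform intensity within a cell by default, so mean-intensity checks can be
exact).  Tiled acquisition emulates cyclic immunofluorescence: every cycle
re-images the nuclear stain, per-tile stage jitter and a per-cycle global
offset perturb the nominal grid, a multiplicative vignetting field and
additive Gaussian noise corrupt each tile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

DEFAULT_MARKERS = ("DNA", "CD45", "CK", "Ki67")

__all__ = [
    "CellRecord",
    "TissueTruth",
    "AcquisitionTile",
    "AcquisitionTruth",
    "TMATruth",
    "make_tissue_truth",
    "make_vignette",
    "render_tiles",
    "make_tma_truth",
    "write_acquisition",
    "write_truth",
]


@dataclass
class CellRecord:
    """One ground-truth cell: a disk nucleus with known marker intensities."""

    cell_id: int
    y: float
    x: float
    radius: float
    type_label: int
    intensities: np.ndarray  # expected mean intensity per marker


@dataclass
class TissueTruth:
    """Ground-truth tissue raster plus the cell records that generated it."""

    height: int
    width: int
    cells: list[CellRecord]
    markers: list[str]
    raster: np.ndarray  # (n_markers, height, width) float32
    type_means: np.ndarray  # (n_types, n_markers)
    seed: int
    background: float = 0.0
    nuclear_channel: str = "DNA"

    def cell_table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "cell_id": c.cell_id,
                "y": c.y,
                "x": c.x,
                "radius": c.radius,
                "type_label": c.type_label,
            }
            row.update({m: c.intensities[i] for i, m in enumerate(self.markers)})
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["cell_id", "y", "x", "radius", "type_label", *self.markers],
        )


@dataclass
class AcquisitionTile:
    """One acquired multichannel tile (Level 1 data)."""

    data: np.ndarray  # (n_channels, h, w) float32
    grid_row: int
    grid_col: int
    cycle: int  # 0-based
    nominal_origin: tuple[int, int]  # (y, x) in truth-frame pixels
    channel_names: list[str]


@dataclass
class AcquisitionTruth:
    """A full tiled acquisition plus the hidden truth used to generate it."""

    tiles: list[AcquisitionTile]
    true_origins: dict[tuple[int, int, int], tuple[int, int]]  # (cycle,r,c)->(y,x)
    nominal_origins: dict[tuple[int, int], tuple[int, int]]  # (r,c)->(y,x)
    illum_fields: dict[str, np.ndarray]  # channel -> mean-1 multiplicative field
    noise_sd: float
    overlap: float
    overlap_px: tuple[int, int]
    tile_shape: tuple[int, int]
    grid_shape: tuple[int, int]
    n_cycles: int
    cycle_channels: list[list[str]]  # channel names per cycle
    truth: TissueTruth

    def tiles_for_cycle(self, cycle: int) -> list[AcquisitionTile]:
        return [t for t in self.tiles if t.cycle == cycle]

    def tile_at(self, cycle: int, row: int, col: int) -> AcquisitionTile:
        for t in self.tiles:
            if t.cycle == cycle and t.grid_row == row and t.grid_col == col:
                return t
        raise KeyError((cycle, row, col))


@dataclass
class TMATruth:
    """A rendered tissue-microarray raster plus true core geometry."""

    rows: int
    cols: int
    centers: list[tuple[float, float]]  # surviving core centers (y, x)
    core_diameter: float
    spacing: float
    dropout: list[int]  # grid flat-indices of removed cores
    fragmented: list[int]  # grid flat-indices of fragmented (surviving) cores
    raster: np.ndarray  # (n_markers, H, W)
    markers: list[str]
    seed: int
    core_truths: list[TissueTruth] = field(default_factory=list)


def _disk_mask(h: int, w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _default_type_means(n_types: int, markers: list[str], rng: np.random.Generator) -> np.ndarray:
    """Distinct per-type intensity vectors; channel 0 (nuclear) bright for all."""
    n_markers = len(markers)
    means = np.full((n_types, n_markers), 30.0)
    means[:, 0] = 500.0  # nuclear stain: every cell
    for t in range(n_types):
        if n_markers > 1:
            hot = 1 + (t % (n_markers - 1))
            means[t, hot] = 400.0
    # small deterministic spread so types remain distinct even when they share
    # a hot marker (n_types > n_markers - 1)
    means += rng.uniform(0, 20.0, size=means.shape)
    return means


def make_tissue_truth(
    n_cells: int,
    frame_size: tuple[int, int] = (512, 512),
    n_types: int = 3,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    radius_range: tuple[float, float] = (5.0, 9.0),
    seed: int = 0,
    *,
    background: float = 0.0,
    min_separation: float = 2.0,
    rim_blur_px: float = 1.0,
    type_means: np.ndarray | None = None,
    intensity_cv: float = 0.0,
    max_attempts: int | None = None,
) -> TissueTruth:
    """Generate a ground-truth tissue raster of non-overlapping disk nuclei.

    Parameters
    ----------
    n_cells:
        Number of nuclei to place by rejection sampling.
    frame_size:
        (height, width) of the raster in pixels.
    n_types:
        Number of cell types; each type has a distinct mean intensity vector.
    markers:
        Channel names; the first is the nuclear stain, bright in every cell.
    radius_range:
        Uniform range of nucleus radii in pixels.
    background:
        Constant baseline added to every pixel (default 0).
    min_separation:
        Minimum edge-to-edge distance between disks, pixels.
    rim_blur_px:
        Gaussian sigma for an optional soft rim; 0 keeps disks hard-edged so
        pixel sums and per-cell means are exact.
    type_means:
        Optional (n_types, n_markers) matrix overriding the generated one.
    intensity_cv:
        Lognormal per-cell intensity scatter (coefficient of variation);
        0 means every cell carries exactly its type mean.
    """
    markers = list(markers)
    h, w = frame_size
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    if type_means is None:
        type_means = _default_type_means(n_types, markers, rng)
    type_means = np.asarray(type_means, dtype=float)
    if type_means.shape != (n_types, len(markers)):
        raise ValueError("type_means must have shape (n_types, n_markers)")

    cells: list[CellRecord] = []
    placed = np.empty((0, 3))  # y, x, radius
    budget = max_attempts if max_attempts is not None else min(max(2000, 300 * n_cells), 2_000_000)
    attempts = 0
    while len(cells) < n_cells:
        if attempts >= budget:
            density = sum(np.pi * c.radius**2 for c in cells) / (h * w)
            raise RuntimeError(
                f"placed only {len(cells)}/{n_cells} non-overlapping nuclei in "
                f"{budget} attempts; achievable density here is ~{density:.2f} "
                f"of the frame — enlarge the frame or reduce n_cells/radius"
            )
        attempts += 1
        r = rng.uniform(*radius_range)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if placed.size:
            d = np.hypot(placed[:, 0] - cy, placed[:, 1] - cx)
            if np.any(d < placed[:, 2] + r + min_separation):
                continue
        t = int(rng.integers(n_types))
        inten = type_means[t].copy()
        if intensity_cv > 0:
            sigma = np.sqrt(np.log1p(intensity_cv**2))
            inten = inten * rng.lognormal(-sigma**2 / 2, sigma, size=inten.shape)
        # store at raster precision so recorded truth matches painted pixels
        inten = inten.astype(np.float32).astype(np.float64)
        cells.append(CellRecord(len(cells) + 1, cy, cx, r, t, inten))
        placed = np.vstack([placed, [cy, cx, r]])

    raster = np.full((len(markers), h, w), background, dtype=np.float32)
    for c in cells:
        y0 = max(0, int(np.floor(c.y - c.radius - 1)))
        y1 = min(h, int(np.ceil(c.y + c.radius + 2)))
        x0 = max(0, int(np.floor(c.x - c.radius - 1)))
        x1 = min(w, int(np.ceil(c.x + c.radius + 2)))
        m = _disk_mask(y1 - y0, x1 - x0, c.y - y0, c.x - x0, c.radius)
        for ch in range(len(markers)):
            block = raster[ch, y0:y1, x0:x1]
            block[m] = background + c.intensities[ch]
    if rim_blur_px > 0:
        from scipy.ndimage import gaussian_filter

        for ch in range(len(markers)):
            raster[ch] = gaussian_filter(raster[ch], rim_blur_px)

    return TissueTruth(
        height=h,
        width=w,
        cells=cells,
        markers=markers,
        raster=raster,
        type_means=type_means,
        seed=seed,
        background=background,
    )


def make_vignette(shape: tuple[int, int], strength: float = 0.3) -> np.ndarray:
    """Radial mean-1 multiplicative vignetting field (bright center, dim corners)."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    r2 = ((yy - (h - 1) / 2) / h) ** 2 + ((xx - (w - 1) / 2) / w) ** 2
    v = 1.0 - strength * r2 / r2.max()
    return (v / v.mean()).astype(np.float64)


def _grid_geometry(frame: tuple[int, int], grid: tuple[int, int], overlap: float):
    """Tile size and step so the grid covers the frame at >= requested overlap."""
    if not 0 < overlap < 0.5:
        raise ValueError("overlap fraction must be in (0, 0.5)")
    sizes, steps = [], []
    for extent, n in zip(frame, grid):
        if n == 1:
            sizes.append(extent)
            steps.append(0)
            continue
        size = int(np.ceil(extent / (n - (n - 1) * overlap)))
        step = int(np.ceil((extent - size) / (n - 1)))  # grid covers the frame
        if step <= 0 or size - step < 2:
            raise ValueError("grid too fine for the frame at this overlap")
        sizes.append(size)
        steps.append(step)
    return (sizes[0], sizes[1]), (steps[0], steps[1])


def _assign_cycle_channels(markers: list[str], cycles: int) -> list[list[str]]:
    """Nuclear channel in every cycle; remaining markers split round-robin."""
    rest = markers[1:]
    out: list[list[str]] = [[markers[0]] for _ in range(cycles)]
    for i, m in enumerate(rest):
        out[i % cycles].append(m)
    return out


def render_tiles(
    truth: TissueTruth,
    grid_rows: int,
    grid_cols: int,
    overlap: float = 0.1,
    jitter_sd: float = 0.0,
    cycles: int = 1,
    cycle_offset: tuple[int, int] = (0, 0),
    illum_field: np.ndarray | dict[str, np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AcquisitionTruth:
    """Emulate tiled cyclic acquisition of a ground-truth raster.

    Each tile is the truth raster cropped at (nominal origin + per-tile integer
    jitter + per-cycle global offset), multiplied pixelwise by the illumination
    field, with additive Gaussian noise clipped at zero.  Cycle ``c`` (0-based)
    is displaced by ``c * cycle_offset``.  True origins are recorded in
    truth-frame coordinates.
    """
    rng = np.random.default_rng(seed)
    frame = (truth.height, truth.width)
    tile_shape, step = _grid_geometry(frame, (grid_rows, grid_cols), overlap)
    overlap_px = (tile_shape[0] - step[0] if grid_rows > 1 else 0,
                  tile_shape[1] - step[1] if grid_cols > 1 else 0)

    cycle_channels = _assign_cycle_channels(truth.markers, cycles)
    chan_index = {m: i for i, m in enumerate(truth.markers)}

    if illum_field is None:
        fields = {m: np.ones(tile_shape) for m in truth.markers}
    elif isinstance(illum_field, dict):
        fields = {m: np.asarray(illum_field.get(m, np.ones(tile_shape))) for m in truth.markers}
    else:
        fields = {m: np.asarray(illum_field) for m in truth.markers}
    for m, f in fields.items():
        if f.shape != tile_shape:
            raise ValueError(f"illumination field for {m} has shape {f.shape}, tiles are {tile_shape}")

    # pad the truth raster so jittered/offset crops stay in-bounds
    max_off = int(np.ceil(4 * jitter_sd + (cycles - 1) * max(abs(cycle_offset[0]), abs(cycle_offset[1])) + 2))
    overhang = max(
        (grid_rows - 1) * step[0] + tile_shape[0] - frame[0],
        (grid_cols - 1) * step[1] + tile_shape[1] - frame[1],
    )
    pad = max(max_off, overhang + 2)
    padded = np.pad(
        truth.raster,
        ((0, 0), (pad, pad), (pad, pad)),
        mode="constant",
        constant_values=truth.background,
    )

    nominal = {
        (r, c): (r * step[0], c * step[1])
        for r in range(grid_rows)
        for c in range(grid_cols)
    }
    tiles: list[AcquisitionTile] = []
    true_origins: dict[tuple[int, int, int], tuple[int, int]] = {}
    for cyc in range(cycles):
        off = (cyc * cycle_offset[0], cyc * cycle_offset[1])
        names = cycle_channels[cyc]
        idx = [chan_index[m] for m in names]
        for (r, c), (ny, nx) in nominal.items():
            jy = int(np.rint(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0
            jx = int(np.rint(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0
            ty, tx = ny + jy + off[0], nx + jx + off[1]
            true_origins[(cyc, r, c)] = (ty, tx)
            crop = padded[idx, pad + ty : pad + ty + tile_shape[0], pad + tx : pad + tx + tile_shape[1]].copy()
            for k, m in enumerate(names):
                crop[k] *= fields[m]
            if noise_sd > 0:
                crop += rng.normal(0, noise_sd, size=crop.shape)
                np.clip(crop, 0, None, out=crop)
            tiles.append(
                AcquisitionTile(
                    data=crop.astype(np.float32),
                    grid_row=r,
                    grid_col=c,
                    cycle=cyc,
                    nominal_origin=(ny, nx),
                    channel_names=list(names),
                )
            )

    # adjacent tiles must still overlap after jitter
    for cyc in range(cycles):
        for (r, c) in nominal:
            for (r2, c2) in ((r, c + 1), (r + 1, c)):
                if (r2, c2) not in nominal:
                    continue
                a = true_origins[(cyc, r, c)]
                b = true_origins[(cyc, r2, c2)]
                ov_y = tile_shape[0] - abs(b[0] - a[0])
                ov_x = tile_shape[1] - abs(b[1] - a[1])
                if ov_y < 2 or ov_x < 2:
                    raise ValueError(
                        f"jitter_sd={jitter_sd} destroyed the overlap between "
                        f"tiles {(r, c)} and {(r2, c2)} in cycle {cyc}"
                    )

    return AcquisitionTruth(
        tiles=tiles,
        true_origins=true_origins,
        nominal_origins=nominal,
        illum_fields=fields,
        noise_sd=noise_sd,
        overlap=overlap,
        overlap_px=overlap_px,
        tile_shape=tile_shape,
        grid_shape=(grid_rows, grid_cols),
        n_cycles=cycles,
        cycle_channels=cycle_channels,
        truth=truth,
    )


def make_tma_truth(
    rows: int,
    cols: int,
    core_diameter: float = 60.0,
    spacing: float = 100.0,
    dropout_frac: float = 0.0,
    fragment_frac: float = 0.0,
    seed: int = 0,
    *,
    clump_pairs: int = 0,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    cells_per_core: int = 25,
    tissue_intensity: float = 60.0,
) -> TMATruth:
    """Render a tissue-microarray raster with dropped, fragmented and clumped cores.

    Each surviving core is a disk of tissue (constant autofluorescence-like
    baseline plus disk nuclei generated by :func:`make_tissue_truth`).
    Fragmented cores keep only 2–3 angular sectors of the disk.  ``clump_pairs``
    horizontally adjacent pairs are pulled together to 0.9 x spacing,
    emulating merged neighboring cores.
    """
    if spacing <= core_diameter * 0.8:
        raise ValueError("spacing must exceed 0.8 x core_diameter")
    markers = list(markers)
    rng = np.random.default_rng(seed)
    radius = core_diameter / 2
    margin = int(np.ceil(spacing / 2))
    H = int(2 * margin + (rows - 1) * spacing + core_diameter)
    W = int(2 * margin + (cols - 1) * spacing + core_diameter)

    grid_centers = {}
    for r in range(rows):
        for c in range(cols):
            grid_centers[r * cols + c] = (
                margin + radius + r * spacing,
                margin + radius + c * spacing,
            )

    n_total = rows * cols
    n_drop = int(round(dropout_frac * n_total))
    dropout = sorted(rng.choice(n_total, size=n_drop, replace=False).tolist()) if n_drop else []
    survivors = [i for i in range(n_total) if i not in dropout]

    # clump: pull horizontally adjacent surviving pairs to 0.9 x spacing
    centers = dict(grid_centers)
    done = 0
    for i in survivors:
        if done >= clump_pairs:
            break
        r, c = divmod(i, cols)
        j = i + 1
        if c + 1 < cols and j in survivors:
            pull = 0.05 * spacing
            cy, cx = centers[i]
            centers[i] = (cy, cx + pull)
            cy, cx = centers[j]
            centers[j] = (cy, cx - pull)
            done += 1

    n_frag = int(round(fragment_frac * len(survivors)))
    fragmented = sorted(rng.choice(survivors, size=n_frag, replace=False).tolist()) if n_frag else []

    raster = np.zeros((len(markers), H, W), dtype=np.float32)
    core_truths: list[TissueTruth] = []
    box = int(np.ceil(core_diameter)) + 2
    for i in survivors:
        cy, cx = centers[i]
        sub = make_tissue_truth(
            cells_per_core,
            frame_size=(box, box),
            markers=tuple(markers),
            radius_range=(2.5, 4.0),
            seed=int(rng.integers(2**31)),
            background=0.0,
            rim_blur_px=0.0,
        )
        disk = _disk_mask(box, box, box / 2, box / 2, radius)
        if i in fragmented:
            n_sectors = int(rng.integers(2, 4))
            yy, xx = np.mgrid[:box, :box]
            ang = np.arctan2(yy - box / 2, xx - box / 2)
            keep = np.zeros_like(disk)
            start = rng.uniform(0, 2 * np.pi)
            width = 2 * np.pi * 0.6 / n_sectors  # keep ~60% of the disk
            gap = (2 * np.pi - n_sectors * width) / n_sectors
            for s in range(n_sectors):
                a0 = start + s * (width + gap)
                a = np.mod(ang - a0, 2 * np.pi)
                keep |= a < width
            disk = disk & keep
        content = sub.raster + tissue_intensity
        y0, x0 = int(round(cy - box / 2)), int(round(cx - box / 2))
        region = raster[:, y0 : y0 + box, x0 : x0 + box]
        region[:, disk] = content[:, disk]
        core_truths.append(sub)

    return TMATruth(
        rows=rows,
        cols=cols,
        centers=[centers[i] for i in survivors],
        core_diameter=core_diameter,
        spacing=spacing,
        dropout=dropout,
        fragmented=fragmented,
        raster=raster,
        markers=markers,
        seed=seed,
        core_truths=core_truths,
    )


def write_acquisition(acq: AcquisitionTruth, outdir: str | Path, pixel_size: float = 0.65) -> Path:
    """Write tiles as per-tile multi-page TIFFs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in acq.tiles:
        cyc_dir = outdir / f"cycle_{t.cycle:02d}"
        cyc_dir.mkdir(exist_ok=True)
        fname = f"tile_r{t.grid_row:02d}_c{t.grid_col:02d}.tif"
        tifffile.imwrite(cyc_dir / fname, t.data, photometric="minisblack")
        entries.append(
            {
                "file": f"cycle_{t.cycle:02d}/{fname}",
                "cycle": t.cycle,
                "grid_row": t.grid_row,
                "grid_col": t.grid_col,
                "nominal_origin": list(t.nominal_origin),
                "channel_names": t.channel_names,
            }
        )
    manifest = {
        "pixel_size_um": pixel_size,
        "tile_shape": list(acq.tile_shape),
        "grid_shape": list(acq.grid_shape),
        "overlap": acq.overlap,
        "n_cycles": acq.n_cycles,
        "tiles": entries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir / "manifest.json"


def write_truth(truth: TissueTruth, outdir: str | Path) -> None:
    """Persist ground truth: cells as CSV, geometry as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.cell_table().to_csv(outdir / "cells_truth.csv", index=False)
    with open(outdir / "geometry.json", "w") as fh:
        json.dump(
            {
                "height": truth.height,
                "width": truth.width,
                "markers": truth.markers,
                "seed": truth.seed,
                "background": truth.background,
            },
            fh,
            indent=2,
        )
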