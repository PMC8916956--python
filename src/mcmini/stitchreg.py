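"""Three-step tile stitching and cross-cycle registration.

Strategy (for cyclic multiplexed acquisitions sharing a nuclear-stain
channel):

1. *Mosaicing* — align cycle-1 tiles edge-to-edge with their 4-neighbours by
   phase correlation on the nuclear channel over the nominal overlap strip.
2. *Registration* — align each later-cycle tile to the cycle-1 tile with the
   greatest nominal overlap, again by phase correlation on the nuclear
   channel, retaining corrected stage coordinates rather than merged pixels.
3. *Assembly* — place every tile of every cycle at its corrected coordinates
   on a single canvas covering the imaged area.

Positions are propagated along a maximum-confidence spanning tree from an
anchor tile, which keeps alignment errors from compounding across the grid;
edges whose phase-correlation confidence falls below a noise-calibrated
threshold are discarded and the affected tiles fall back to nominal
coordinates (flagged in the provenance field).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import MosaicImage

__all__ = [
    "ShiftEstimate",
    "TilePositionSet",
    "phase_correlate",
    "calibrate_confidence_threshold",
    "align_cycle1_edges",
    "solve_global_positions",
    "register_cycle",
    "assemble_mosaic",
    "stitch_acquisition",
]


@dataclass
class ShiftEstimate:
    """A relative shift between two windows, with a peak-ratio confidence.

    ``(dy, dx)`` is the content displacement of the moving window relative to
    the reference: ``mov ~= roll(ref, (dy, dx))``.  Confidence is the ratio of
    the correlation peak to the second-highest non-adjacent peak; ~1 for pure
    noise, large for a genuine match.
    """

    dy: float
    dx: float
    confidence: float
    pair: tuple = ()


@dataclass
class TilePositionSet:
    """Corrected tile origins per (cycle, grid_row, grid_col), with provenance."""

    positions: dict[tuple[int, int, int], tuple[float, float]] = field(default_factory=dict)
    provenance: dict[tuple[int, int, int], str] = field(default_factory=dict)

    def origin(self, cycle: int, row: int, col: int) -> tuple[float, float]:
        return self.positions[(cycle, row, col)]


def phase_correlate(ref: np.ndarray, mov: np.ndarray, max_shift: int = 10) -> ShiftEstimate:
    """Phase correlation with subpixel refinement and a peak-ratio confidence.

    Returns the shift (within ``±max_shift`` per axis) maximising the inverse
    transform of the normalised cross-power spectrum, refined to subpixel by a
    3-point parabola per axis.  All-constant windows return shift (0, 0) with
    confidence 0.
    """
    if ref.shape != mov.shape:
        raise ValueError("windows must share a shape")
    if min(ref.shape) < 16:
        raise ValueError("windows must be at least 16 px per side")
    ref = np.asarray(ref, dtype=np.float64)
    mov = np.asarray(mov, dtype=np.float64)
    if ref.std() == 0 or mov.std() == 0:
        return ShiftEstimate(0.0, 0.0, 0.0)

    # no apodization window: spectral whitening equalises the bands already,
    # and a fixed window over moving content biases large shifts toward zero;
    # unreliable wrapped peaks are handled by the confidence threshold instead
    fr = np.fft.fft2(ref - ref.mean())
    fm = np.fft.fft2(mov - mov.mean())
    cross = fm * np.conj(fr)
    mag = np.abs(cross)
    cross /= np.maximum(mag, 1e-12)
    corr = np.fft.ifft2(cross).real

    h, w = corr.shape
    my = min(max_shift, h // 2 - 1)
    mx = min(max_shift, w // 2 - 1)
    dys = np.arange(-my, my + 1)
    dxs = np.arange(-mx, mx + 1)
    window = corr[np.ix_(dys % h, dxs % w)]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy, dx = int(dys[iy]), int(dxs[ix])
    peak = float(window[iy, ix])

    # second-highest peak outside the 3x3 neighbourhood of the main peak
    masked = window.copy()
    y0, y1 = max(0, iy - 1), min(window.shape[0], iy + 2)
    x0, x1 = max(0, ix - 1), min(window.shape[1], ix + 2)
    masked[y0:y1, x0:x1] = -np.inf
    second = float(masked.max()) if np.isfinite(masked).any() else 0.0
    confidence = peak / max(second, 1e-6) if peak > 0 else 0.0

    def _parabola(m1: float, c0: float, p1: float) -> float:
        denom = m1 - 2 * c0 + p1
        if denom >= 0 or abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    sub_y = _parabola(corr[(dy - 1) % h, dx % w], corr[dy % h, dx % w], corr[(dy + 1) % h, dx % w])
    sub_x = _parabola(corr[dy % h, (dx - 1) % w], corr[dy % h, dx % w], corr[dy % h, (dx + 1) % w])
    return ShiftEstimate(dy + sub_y, dx + sub_x, confidence)


def calibrate_confidence_threshold(
    strips: list[np.ndarray], max_shift: int = 10, n_pairs: int = 100, seed: int = 0
) -> float:
    """Confidence threshold as the 99th percentile under pure-noise pairs.

    Pixel-shuffles real overlap strips to destroy structure while keeping the
    intensity histogram, correlates independent shuffles, and takes the 99th
    percentile of the resulting confidences.
    """
    rng = np.random.default_rng(seed)
    confs = []
    for i in range(n_pairs):
        strip = strips[i % len(strips)]
        a = rng.permutation(strip.ravel()).reshape(strip.shape)
        b = rng.permutation(strip.ravel()).reshape(strip.shape)
        confs.append(phase_correlate(a, b, max_shift).confidence)
    return float(np.percentile(confs, 99))


def _overlap_windows(tile_a, tile_b, origin_a, origin_b, shape):
    """Shared-region windows of two tiles under the given origins.

    Returns (ref_window, mov_window) cropped at identical frame coordinates,
    or None if the rectangles do not overlap by at least 16 px per side.
    """
    ya0 = max(origin_a[0], origin_b[0])
    xa0 = max(origin_a[1], origin_b[1])
    ya1 = min(origin_a[0] + shape[0], origin_b[0] + shape[0])
    xa1 = min(origin_a[1] + shape[1], origin_b[1] + shape[1])
    if ya1 - ya0 < 16 or xa1 - xa0 < 16:
        return None
    ref = tile_a[ya0 - origin_a[0] : ya1 - origin_a[0], xa0 - origin_a[1] : xa1 - origin_a[1]]
    mov = tile_b[ya0 - origin_b[0] : ya1 - origin_b[0], xa0 - origin_b[1] : xa1 - origin_b[1]]
    return ref, mov


def _nuclear_plane(tile, nuclear_channel: str) -> np.ndarray:
    return tile.data[tile.channel_names.index(nuclear_channel)]


def align_cycle1_edges(
    acq, nuclear_channel: str = "DNA", max_shift: int = 10
) -> list[ShiftEstimate]:
    """Estimate the offset correction for every 4-adjacent cycle-1 tile pair.

    Each estimate's ``(dy, dx)`` is the correction to the *nominal* relative
    offset of pair (A, B): true(B) - true(A) = nominal(B) - nominal(A) + (dy, dx).
    """
    tiles = {(t.grid_row, t.grid_col): t for t in acq.tiles_for_cycle(0)}
    grid = nx.Graph()
    grid.add_nodes_from(tiles)
    for (r, c) in tiles:
        for nbr in ((r, c + 1), (r + 1, c)):
            if nbr in tiles:
                grid.add_edge((r, c), nbr)
    if tiles and not nx.is_connected(grid):
        comps = [sorted(c) for c in nx.connected_components(grid)]
        raise ValueError(f"tile grid is disconnected: components {comps}")

    edges = []
    for (a, b) in grid.edges:
        a, b = (a, b) if a <= b else (b, a)
        ta, tb = tiles[a], tiles[b]
        wins = _overlap_windows(
            _nuclear_plane(ta, nuclear_channel),
            _nuclear_plane(tb, nuclear_channel),
            ta.nominal_origin,
            tb.nominal_origin,
            acq.tile_shape,
        )
        if wins is None:
            continue
        est = phase_correlate(wins[0], wins[1], max_shift)
        # mov = roll(ref, d) measures d = -(eps_B - eps_A); flip to a correction
        edges.append(ShiftEstimate(-est.dy, -est.dx, est.confidence, pair=(a, b)))
    return edges


def solve_global_positions(
    edges: list[ShiftEstimate],
    acq,
    confidence_threshold: float | None = None,
    seed: int = 0,
    nuclear_channel: str = "DNA",
) -> TilePositionSet:
    """Solve cycle-1 tile origins from pairwise edge corrections.

    Keeps edges above the confidence threshold (calibrated from shuffled
    overlap strips when not given), propagates corrections along the
    maximum-confidence spanning tree from the anchor tile at grid (0, 0), and
    falls back to nominal offsets (flagged) for tiles left disconnected.
    """
    nominal = acq.nominal_origins
    if confidence_threshold is None:
        strips = []
        for e in edges[:4]:
            a, b = e.pair
            ta = acq.tile_at(0, *a)
            tb = acq.tile_at(0, *b)
            wins = _overlap_windows(
                _nuclear_plane(ta, nuclear_channel),
                _nuclear_plane(tb, nuclear_channel),
                ta.nominal_origin,
                tb.nominal_origin,
                acq.tile_shape,
            )
            if wins is not None:
                strips.append(wins[0])
        if not strips:
            strips = [np.zeros((24, 24)) + np.arange(24)]
        confidence_threshold = calibrate_confidence_threshold(strips, seed=seed)

    g = nx.Graph()
    g.add_nodes_from(nominal)
    for e in edges:
        if e.confidence >= confidence_threshold:
            a, b = e.pair
            g.add_edge(a, b, confidence=e.confidence, corr=(e.dy, e.dx), src=a)

    pos = TilePositionSet()
    anchor = min(nominal)
    if g.number_of_edges() == 0:
        warnings.warn("no confident edges: all tiles placed at nominal origins", stacklevel=2)
        for (r, c), o in nominal.items():
            pos.positions[(0, r, c)] = (float(o[0]), float(o[1]))
            pos.provenance[(0, r, c)] = "nominal-fallback"
        return pos

    solved: dict[tuple[int, int], tuple[float, float]] = {}
    for comp in nx.connected_components(g):
        if anchor not in comp:
            continue
        tree = nx.maximum_spanning_tree(g.subgraph(comp), weight="confidence")
        solved[anchor] = (float(nominal[anchor][0]), float(nominal[anchor][1]))
        for parent, child in nx.bfs_edges(tree, anchor):
            data = g.edges[parent, child]
            dy, dx = data["corr"]
            if data["src"] != parent:  # correction was estimated child->parent
                dy, dx = -dy, -dx
            py, px = solved[parent]
            solved[child] = (
                py + nominal[child][0] - nominal[parent][0] + dy,
                px + nominal[child][1] - nominal[parent][1] + dx,
            )
    for node in solved:
        pos.provenance[(0, *node)] = "edge-aligned"

    # attach any leftover tiles at nominal offset from a solved neighbour
    remaining = [n for n in nominal if n not in solved]
    while remaining:
        progressed = False
        for node in list(remaining):
            r, c = node
            for nbr in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if nbr in solved:
                    solved[node] = (
                        solved[nbr][0] + nominal[node][0] - nominal[nbr][0],
                        solved[nbr][1] + nominal[node][1] - nominal[nbr][1],
                    )
                    pos.provenance[(0, *node)] = "nominal-fallback"
                    remaining.remove(node)
                    progressed = True
                    break
        if not progressed:  # no solved neighbour anywhere (isolated block)
            node = remaining.pop(0)
            solved[node] = (float(nominal[node][0]), float(nominal[node][1]))
            pos.provenance[(0, *node)] = "nominal-fallback"

    for (r, c), o in solved.items():
        pos.positions[(0, r, c)] = o
    return pos


def register_cycle(
    acq,
    cycle: int,
    positions: TilePositionSet,
    nuclear_channel: str = "DNA",
    max_shift: int = 15,
    confidence_threshold: float = 3.0,
) -> TilePositionSet:
    """Register the tiles of one later cycle against solved cycle-1 positions.

    For each tile, the cycle-1 tile with the greatest nominal overlap is found,
    the shared region is phase-correlated on the nuclear channel, and the
    corrected origin recorded.  Low-confidence tiles fall back to the median
    shift of the confident ones (flagged ``registered-fallback``).
    """
    if cycle == 0:
        raise ValueError("cycle 0 is solved by solve_global_positions")
    c1 = {(t.grid_row, t.grid_col): t for t in acq.tiles_for_cycle(0)}
    if not c1:
        raise ValueError("no cycle-1 tiles to register against")
    out = TilePositionSet(dict(positions.positions), dict(positions.provenance))
    shape = acq.tile_shape

    pending: list[tuple] = []
    shifts: dict[tuple[int, int], tuple[float, float, float]] = {}
    for t in acq.tiles_for_cycle(cycle):
        nom = t.nominal_origin
        best, best_area = None, 0
        for key, ta in c1.items():
            oy, ox = positions.origin(0, *key)
            oy, ox = int(round(oy)), int(round(ox))
            ay = min(nom[0] + shape[0], oy + shape[0]) - max(nom[0], oy)
            ax = min(nom[1] + shape[1], ox + shape[1]) - max(nom[1], ox)
            if ay > 0 and ax > 0 and ay * ax > best_area:
                best, best_area = key, ay * ax
        if best is None:
            raise ValueError(
                f"cycle-{cycle} tile {(t.grid_row, t.grid_col)} overlaps no cycle-1 tile"
            )
        ta = c1[best]
        oa = tuple(int(round(v)) for v in positions.origin(0, *best))
        wins = _overlap_windows(
            _nuclear_plane(ta, nuclear_channel),
            _nuclear_plane(t, nuclear_channel),
            oa,
            nom,
            shape,
        )
        est = phase_correlate(wins[0], wins[1], max_shift) if wins else ShiftEstimate(0, 0, 0)
        if est.confidence >= confidence_threshold:
            eps = (-est.dy, -est.dx)
            shifts[(t.grid_row, t.grid_col)] = (eps[0], eps[1], est.confidence)
            out.positions[(cycle, t.grid_row, t.grid_col)] = (nom[0] + eps[0], nom[1] + eps[1])
            out.provenance[(cycle, t.grid_row, t.grid_col)] = "registered-to-cycle-1"
        else:
            pending.append(t)

    med = (0.0, 0.0)
    if shifts:
        arr = np.array([(v[0], v[1]) for v in shifts.values()])
        med = (float(np.median(arr[:, 0])), float(np.median(arr[:, 1])))
    for t in pending:
        nom = t.nominal_origin
        out.positions[(cycle, t.grid_row, t.grid_col)] = (nom[0] + med[0], nom[1] + med[1])
        out.provenance[(cycle, t.grid_row, t.grid_col)] = "registered-fallback"
    return out


def assemble_mosaic(
    acq,
    positions: TilePositionSet,
    overlap_policy: str = "last-write-wins",
    pixel_budget: int = 1_000_000_000,
    pixel_size: float = 1.0,
) -> MosaicImage:
    """Assemble all cycles' tiles into one multichannel mosaic.

    Tiles are placed at rounded corrected origins (no interpolation, so
    intensity values stay exact for quantification).  Overlap policy is
    ``last-write-wins`` or ``feather`` (linear distance-to-edge weighting).
    Channel order is cycle order then within-cycle order; nuclear re-scans in
    later cycles get a ``_c<cycle>`` suffix to stay unique.
    """
    if overlap_policy not in ("last-write-wins", "feather"):
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")
    th, tw = acq.tile_shape
    placed = []
    for t in acq.tiles:
        key = (t.cycle, t.grid_row, t.grid_col)
        oy, ox = positions.positions[key]
        placed.append((t, int(round(oy)), int(round(ox))))
    y0 = min(p[1] for p in placed)
    x0 = min(p[2] for p in placed)
    y1 = max(p[1] for p in placed) + th
    x1 = max(p[2] for p in placed) + tw
    H, W = y1 - y0, x1 - x0

    names: list[str] = []
    chan_of: dict[tuple[int, str], int] = {}
    for cyc in range(acq.n_cycles):
        for ch in acq.cycle_channels[cyc]:
            name = ch if ch not in names else f"{ch}_c{cyc + 1}"
            chan_of[(cyc, ch)] = len(names)
            names.append(name)
    if len(names) * H * W > pixel_budget:
        raise ValueError(
            f"mosaic of {len(names)}x{H}x{W} exceeds the pixel budget "
            f"({pixel_budget}); downsample or raise the budget"
        )

    canvas = np.zeros((len(names), H, W), dtype=np.float64)
    if overlap_policy == "feather":
        weight = np.zeros((len(names), H, W), dtype=np.float64)
        yy = np.minimum(np.arange(th) + 1, np.arange(th)[::-1] + 1)
        xx = np.minimum(np.arange(tw) + 1, np.arange(tw)[::-1] + 1)
        ramp = np.minimum.outer(yy, xx).astype(np.float64)
    for t, oy, ox in placed:
        sy, sx = oy - y0, ox - x0
        for k, ch in enumerate(t.channel_names):
            ci = chan_of[(t.cycle, ch)]
            if overlap_policy == "last-write-wins":
                canvas[ci, sy : sy + th, sx : sx + tw] = t.data[k]
            else:
                canvas[ci, sy : sy + th, sx : sx + tw] += t.data[k] * ramp
                weight[ci, sy : sy + th, sx : sx + tw] += ramp
    if overlap_policy == "feather":
        canvas = np.where(weight > 0, canvas / np.maximum(weight, 1e-12), 0.0)
    return MosaicImage(data=canvas.astype(np.float32), channel_names=names, pixel_size=pixel_size)


def stitch_acquisition(
    acq,
    nuclear_channel: str = "DNA",
    max_shift: int = 10,
    register_max_shift: int = 15,
    overlap_policy: str = "last-write-wins",
    confidence_threshold: float | None = None,
    seed: int = 0,
) -> tuple[MosaicImage, TilePositionSet]:
    """Run the full three-step stitch: edges -> positions -> registration -> mosaic."""
    edges = align_cycle1_edges(acq, nuclear_channel, max_shift)
    positions = solve_global_positions(
        acq=acq, edges=edges, confidence_threshold=confidence_threshold, seed=seed,
        nuclear_channel=nuclear_channel,
    )
    for cyc in range(1, acq.n_cycles):
        positions = register_cycle(acq, cyc, positions, nuclear_channel, register_max_shift)
    mosaic = assemble_mosaic(acq, positions, overlap_policy=overlap_policy)
    return mosaic, positions
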