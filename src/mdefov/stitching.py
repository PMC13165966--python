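"""Extended-FOV hologram mosaicking.

Pipeline per axial plane: grid topology from stage coordinates, overlap-ROI
extraction with a +/-10% search margin, patch-wise correlation matching
(pluggable matcher interface), median + 2-D-histogram displacement voting,
global least-squares alignment with loop closure, feathered (linear-ramp)
weighted blending, and auto-cropping to the fully covered rectangle.

Registration is integer-pixel: the stage step is an integer multiple of the
pixel pitch, so the translation model needs no subpixel refinement.

Coordinates are ``(row, col)``; a displacement ``(dy, dx)`` for a tile pair
``(A, B)`` is defined as ``point_in_A - point_in_B`` for corresponding
content, i.e. the position of tile B's window relative to tile A's (a tile
to the right of A at a 1500 px stage step gives ``(dy, dx) = (0, 1500)``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

from .simulate import Hologram

__all__ = [
    "MatchSet",
    "ShiftEstimate",
    "MosaicLayout",
    "StitchInfo",
    "XCorrMatcher",
    "DEFAULT_CONFIDENCE_THRESHOLD",
    "build_topology",
    "extract_overlap_rois",
    "match_rois",
    "estimate_pair_shift",
    "global_align",
    "auto_crop",
    "feather_weights",
    "blend",
    "stitch_plane",
    "stitch_stack",
]

logger = logging.getLogger(__name__)

#: Matches with confidence below this are considered unreliable.
DEFAULT_CONFIDENCE_THRESHOLD = 0.5

#: Minimum fraction of inlier votes before falling back to the nominal shift.
MIN_SUPPORT_FRACTION = 0.2

#: Minimum width of a usable overlap strip, pixels.
MIN_ROI_WIDTH = 16


@dataclass
class MatchSet:
    """Point correspondences between two ROIs (or tiles).

    ``points_a`` and ``points_b`` are ``(N, 2)`` arrays of ``(row, col)``
    coordinates; ``confidences`` are in ``[0, 1]``.
    """

    points_a: np.ndarray
    points_b: np.ndarray
    confidences: np.ndarray
    matcher_name: str = ""

    def __post_init__(self) -> None:
        self.points_a = np.atleast_2d(np.asarray(self.points_a, dtype=np.float64))
        self.points_b = np.atleast_2d(np.asarray(self.points_b, dtype=np.float64))
        self.confidences = np.atleast_1d(np.asarray(self.confidences, dtype=np.float64))
        if len(self) and (
            self.points_a.shape != self.points_b.shape
            or self.points_a.shape[0] != self.confidences.shape[0]
        ):
            raise ValueError("correspondence arrays have inconsistent shapes")
        if len(self) and (np.any(self.confidences < 0) or np.any(self.confidences > 1)):
            raise ValueError("confidences must be in [0, 1]")

    def __len__(self) -> int:
        return 0 if self.points_a.size == 0 else self.points_a.shape[0]

    @classmethod
    def empty(cls, matcher_name: str = "") -> "MatchSet":
        return cls(
            np.empty((0, 2)), np.empty((0, 2)), np.empty((0,)), matcher_name
        )

    def displacements(self) -> np.ndarray:
        """Per-correspondence ``(dy, dx) = point_in_A - point_in_B``."""
        return self.points_a - self.points_b

    def offset(self, origin_a: tuple[int, int], origin_b: tuple[int, int]) -> "MatchSet":
        """Translate ROI-local coordinates into tile coordinates."""
        return MatchSet(
            self.points_a + np.asarray(origin_a, dtype=np.float64),
            self.points_b + np.asarray(origin_b, dtype=np.float64),
            self.confidences,
            self.matcher_name,
        )

    def filter(self, min_confidence: float) -> "MatchSet":
        """Keep only correspondences at or above a confidence level."""
        if len(self) == 0:
            return self
        keep = self.confidences >= min_confidence
        return MatchSet(
            self.points_a[keep], self.points_b[keep],
            self.confidences[keep], self.matcher_name,
        )


@dataclass(frozen=True)
class ShiftEstimate:
    """Voted integer displacement for one adjacent tile pair."""

    dx: int
    dy: int
    votes: int
    support_fraction: float
    pair: tuple = ()

    def __post_init__(self) -> None:
        if self.votes < 1:
            raise ValueError("votes must be >= 1")
        if not (0.0 <= self.support_fraction <= 1.0):
            raise ValueError("support_fraction must be in [0, 1]")


@dataclass
class MosaicLayout:
    """Absolute integer tile positions on a common canvas.

    ``positions`` are anchored coordinates (upper-left tile at ``(0, 0)``,
    possibly negative elsewhere); ``offset`` shifts them into canvas
    coordinates so every tile lies inside ``canvas_shape``.  ``coverage``
    counts contributing tiles per canvas pixel.
    """

    positions: dict
    tile_shape: tuple[int, int]
    offset: tuple[int, int] = (0, 0)
    canvas_shape: tuple[int, int] = (0, 0)
    coverage: np.ndarray = field(default=None, repr=False)

    @classmethod
    def build(cls, positions: Mapping, tile_shape: tuple[int, int]) -> "MosaicLayout":
        pos = {k: (int(v[0]), int(v[1])) for k, v in positions.items()}
        rows = np.array([p[0] for p in pos.values()])
        cols = np.array([p[1] for p in pos.values()])
        offset = (-int(rows.min()), -int(cols.min()))
        canvas_shape = (
            int(rows.max() - rows.min()) + tile_shape[0],
            int(cols.max() - cols.min()) + tile_shape[1],
        )
        coverage = np.zeros(canvas_shape, dtype=np.int32)
        for p in pos.values():
            r, c = p[0] + offset[0], p[1] + offset[1]
            coverage[r : r + tile_shape[0], c : c + tile_shape[1]] += 1
        return cls(pos, tuple(tile_shape), offset, canvas_shape, coverage)

    def canvas_position(self, key) -> tuple[int, int]:
        r, c = self.positions[key]
        return r + self.offset[0], c + self.offset[1]


@dataclass
class StitchInfo:
    """Bookkeeping from one plane stitch: shifts, layout, crop, fallbacks."""

    shifts: dict
    layout: MosaicLayout
    crop_bounds: tuple[int, int, int, int]
    fallback_pairs: list
    matcher_name: str

    def to_dict(self) -> dict:
        return {
            "matcher": self.matcher_name,
            "crop_bounds": list(self.crop_bounds),
            "fallback_pairs": [list(map(list, p)) for p in self.fallback_pairs],
            "shifts": [
                {
                    "pair": [list(s.pair[0]), list(s.pair[1])],
                    "dx": s.dx,
                    "dy": s.dy,
                    "votes": s.votes,
                    "support_fraction": s.support_fraction,
                }
                for s in self.shifts.values()
            ],
            "positions": {
                f"{k[0]},{k[1]}": list(v) for k, v in self.layout.positions.items()
            },
        }


# ---------------------------------------------------------------------------
# topology


def _cells(manifest) -> list[tuple[int, int]]:
    if hasattr(manifest, "itertuples"):  # pandas DataFrame
        return [(int(r.grid_row), int(r.grid_col)) for r in manifest.itertuples()]
    out = []
    for rec in manifest:
        if isinstance(rec, Mapping):
            out.append((int(rec["grid_row"]), int(rec["grid_col"])))
        else:
            out.append((int(rec[0]), int(rec[1])))
    return out


def build_topology(manifest) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """4-neighbour adjacency pairs of a full rows x cols scan lattice.

    ``manifest`` may be a DataFrame with ``grid_row``/``grid_col`` columns,
    a sequence of dicts, or a sequence of ``(row, col)`` tuples for one
    axial plane.  Raises if any lattice cell is missing, listing the holes.
    """
    cells = set(_cells(manifest))
    if not cells:
        raise ValueError("empty manifest")
    rows = max(r for r, _ in cells) + 1
    cols = max(c for _, c in cells) + 1
    missing = sorted(
        (r, c) for r in range(rows) for c in range(cols) if (r, c) not in cells
    )
    if missing:
        raise ValueError(f"scan lattice has missing cells: {missing}")
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                pairs.append(((r, c), (r, c + 1)))
            if r + 1 < rows:
                pairs.append(((r, c), (r + 1, c)))
    return pairs


# ---------------------------------------------------------------------------
# overlap ROIs and matching


def extract_overlap_rois(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    direction: str,
    nominal_overlap: float,
    margin: float = 0.10,
) -> tuple[tuple[int, int, int, int], tuple[int, int, int, int]]:
    """Equal-size search ROIs around the theoretical overlap strip.

    ``direction`` is ``"h"`` (B to the right of A) or ``"v"`` (B below A).
    The strip of width ``round(nominal_overlap * side)`` on the facing
    edges is expanded into each tile by ``round(margin * side)`` on its
    free edge, clamped to the tile.  Bounds are half-open
    ``(r0, r1, c0, c1)`` in each tile's own coordinates.
    """
    if not (0.0 < nominal_overlap <= 1.0):
        raise ValueError(f"nominal_overlap must be in (0, 1], got {nominal_overlap}")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    if tile_a.shape != tile_b.shape:
        raise ValueError("tiles must have equal shape")
    rows, cols = tile_a.shape[:2]
    side = cols if direction == "h" else rows
    strip = int(round(nominal_overlap * side))
    if strip < MIN_ROI_WIDTH:
        raise ValueError(
            f"overlap strip {strip} px is narrower than the minimum "
            f"{MIN_ROI_WIDTH} px"
        )
    width = min(side, strip + int(round(margin * side)))
    if direction == "h":
        return (0, rows, cols - width, cols), (0, rows, 0, width)
    if direction == "v":
        return (rows - width, rows, 0, cols), (0, width, 0, cols)
    raise ValueError(f"direction must be 'h' or 'v', got {direction!r}")


class XCorrMatcher:
    """Classical patch-wise phase-correlation matcher.

    Stands in for learned dense matchers behind the same interface: the ROI
    pair is divided into a grid of patches; each patch yields one
    correspondence from the phase-correlation peak of co-located windows,
    with the normalized cross-correlation after alignment as confidence.
    """

    name = "xcorr"

    def __init__(self, patch_size: int = 96, stride: int | None = None) -> None:
        self.patch_size = int(patch_size)
        self.stride = int(stride) if stride else self.patch_size // 2

    @staticmethod
    def _ncc(a: np.ndarray, b: np.ndarray) -> float:
        denom = a.std() * b.std()
        if denom == 0:
            return 0.0
        return float(np.mean((a - a.mean()) * (b - b.mean())) / denom)

    def _grid(self, extent: int) -> list[int]:
        ps = self.patch_size
        if extent <= ps:
            return [0]
        starts = list(range(0, extent - ps, self.stride))
        starts.append(extent - ps)
        return sorted(set(starts))

    def __call__(self, roi_a: np.ndarray, roi_b: np.ndarray) -> MatchSet:
        if roi_a.shape != roi_b.shape:
            raise ValueError("ROIs must have equal shape")
        rows, cols = roi_a.shape
        ps = min(self.patch_size, rows, cols)
        pts_a, pts_b, confs = [], [], []
        for top in self._grid(rows):
            for left in self._grid(cols):
                a = roi_a[top : top + ps, left : left + ps]
                b = roi_b[top : top + ps, left : left + ps]
                if a.std() == 0 or b.std() == 0:
                    continue
                # phase normalization suits broadband fringes; plain
                # correlation rescues smooth, narrowband content
                shift, conf = None, -1.0
                for normalization in ("phase", None):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cand, _, _ = phase_cross_correlation(
                            a, b, normalization=normalization
                        )
                    cand = cand.astype(int)
                    c = self._ncc(a, np.roll(b, cand, axis=(0, 1)))
                    if c > conf:
                        shift, conf = cand, c
                    if conf >= DEFAULT_CONFIDENCE_THRESHOLD:
                        break
                conf = float(np.clip(conf, 0.0, 1.0))
                center = np.array([top + ps / 2.0, left + ps / 2.0])
                pts_a.append(center)
                pts_b.append(center - shift)
                confs.append(conf)
        if not pts_a:
            return MatchSet.empty(self.name)
        return MatchSet(np.array(pts_a), np.array(pts_b), np.array(confs), self.name)


def match_rois(
    roi_a: np.ndarray,
    roi_b: np.ndarray,
    matcher: Callable[[np.ndarray, np.ndarray], MatchSet] | None = None,
) -> MatchSet:
    """Run a matcher over an ROI pair; constant ROIs give an empty set."""
    roi_a = np.asarray(roi_a, dtype=np.float64)
    roi_b = np.asarray(roi_b, dtype=np.float64)
    if roi_a.shape != roi_b.shape:
        raise ValueError("ROIs must have equal shape")
    matcher = matcher or XCorrMatcher()
    name = getattr(matcher, "name", getattr(matcher, "__name__", "matcher"))
    if roi_a.std() == 0 or roi_b.std() == 0:
        return MatchSet.empty(name)
    return matcher(roi_a, roi_b)


# ---------------------------------------------------------------------------
# displacement voting


def estimate_pair_shift(
    matches: MatchSet,
    bin_px: int = 1,
    pair: tuple = (),
    outlier_mad_factor: float = 3.0,
    min_outlier_radius: float = 5.0,
) -> ShiftEstimate:
    """Robust integer shift from a correspondence set.

    The median displacement vector is the initial estimate; vectors farther
    than ``max(min_outlier_radius, outlier_mad_factor * MAD)`` from it are
    discarded; survivors are binned on a 2-D histogram (``bin_px`` wide
    bins centred on integer multiples) and the max-vote bin wins, ties
    broken toward the median.
    """
    if len(matches) == 0:
        raise ValueError("cannot estimate a shift from an empty MatchSet")
    if bin_px < 1:
        raise ValueError("bin_px must be >= 1")
    disp = matches.displacements()
    total = disp.shape[0]
    med = np.median(disp, axis=0)
    dist = np.hypot(*(disp - med).T)
    mad = float(np.median(dist))
    radius = max(min_outlier_radius, outlier_mad_factor * mad)
    inliers = disp[dist <= radius]
    bins = np.round(inliers / bin_px).astype(np.int64)
    keys, counts = np.unique(bins, axis=0, return_counts=True)
    top = counts.max()
    winners = keys[counts == top]
    centers = winners * bin_px
    # tie-break toward the median estimate, then lexicographically
    d2 = np.hypot(*(centers - med).T)
    order = np.lexsort((centers[:, 1], centers[:, 0], d2))
    dy, dx = (int(round(v)) for v in centers[order[0]])
    return ShiftEstimate(
        dx=dx,
        dy=dy,
        votes=int(top),
        support_fraction=float(top) / total,
        pair=tuple(pair),
    )


# ---------------------------------------------------------------------------
# global alignment


def global_align(
    shifts: Sequence[ShiftEstimate],
    tile_shape: tuple[int, int],
) -> MosaicLayout:
    """Least-squares tile positions from pairwise shifts, anchored at the
    upper-left tile.

    Each shift contributes the constraint ``pos_B - pos_A = (dy, dx)``; the
    per-axis system is solved in the least-squares sense (redundant loops
    reconciled) and rounded to integer pixels.  Raises if the pair graph is
    disconnected, listing the components.
    """
    if not shifts:
        raise ValueError("no pairwise shifts given")
    nodes = sorted({n for s in shifts for n in s.pair})
    index = {n: i for i, n in enumerate(nodes)}
    # connectivity check
    adjacency: dict = {n: set() for n in nodes}
    for s in shifts:
        a, b = s.pair
        adjacency[a].add(b)
        adjacency[b].add(a)
    seen: set = set()
    components = []
    for n in nodes:
        if n in seen:
            continue
        comp, stack = set(), [n]
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adjacency[cur] - comp)
        seen |= comp
        components.append(sorted(comp))
    if len(components) > 1:
        raise ValueError(f"pair graph is disconnected: components {components}")

    n_nodes, n_pairs = len(nodes), len(shifts)
    A = np.zeros((n_pairs + 1, n_nodes))
    b_row = np.zeros(n_pairs + 1)
    b_col = np.zeros(n_pairs + 1)
    for i, s in enumerate(shifts):
        ia, ib = index[s.pair[0]], index[s.pair[1]]
        A[i, ia] = -1.0
        A[i, ib] = 1.0
        b_row[i] = s.dy
        b_col[i] = s.dx
    A[n_pairs, 0] = 1.0  # anchor the first (upper-left) tile at (0, 0)
    rows = np.linalg.lstsq(A, b_row, rcond=None)[0]
    cols = np.linalg.lstsq(A, b_col, rcond=None)[0]
    rows = np.round(rows - rows[0]).astype(int)
    cols = np.round(cols - cols[0]).astype(int)
    positions = {n: (int(rows[i]), int(cols[i])) for n, i in index.items()}
    return MosaicLayout.build(positions, tile_shape)


# ---------------------------------------------------------------------------
# cropping and blending


def auto_crop(
    canvas: np.ndarray, coverage: np.ndarray
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Largest axis-aligned rectangle with coverage >= 1 everywhere.

    Classic maximal-rectangle-in-binary-mask scan (histogram + stack).
    Returns ``(cropped_canvas, (r0, r1, c0, c1))`` with half-open bounds.
    """
    mask = np.asarray(coverage) >= 1
    if not mask.any():
        raise ValueError("coverage mask is empty")
    n_rows, n_cols = mask.shape
    heights = np.zeros(n_cols, dtype=np.int64)
    best_area, best = 0, (0, 0, 0, 0)
    for r in range(n_rows):
        heights = np.where(mask[r], heights + 1, 0)
        stack: list[tuple[int, int]] = []
        for c in range(n_cols + 1):
            h = int(heights[c]) if c < n_cols else 0
            start = c
            while stack and stack[-1][1] >= h:
                s, sh = stack.pop()
                area = sh * (c - s)
                if area > best_area:
                    best_area, best = area, (r - sh + 1, r + 1, s, c)
                start = s
            if not stack or h > stack[-1][1]:
                stack.append((start, h))
    r0, r1, c0, c1 = best
    return canvas[r0:r1, c0:c1], best


def feather_weights(shape: tuple[int, int], ramp: int | None = None) -> np.ndarray:
    """Separable linear-ramp ('feathering') weight profile.

    Rises from a small positive value at the tile edge to 1 on the interior
    plateau over ``ramp`` pixels (default: a quarter of the smaller side).
    Strictly positive everywhere so single-tile regions never divide by 0.
    """
    rows, cols = shape
    if ramp is None:
        ramp = max(1, min(rows, cols) // 4)
    di = np.minimum(np.arange(rows), np.arange(rows)[::-1])[:, None]
    dj = np.minimum(np.arange(cols), np.arange(cols)[::-1])[None, :]
    d = np.minimum(di, dj)
    return np.minimum(1.0, (d + 1.0) / (ramp + 1.0))


def blend(
    tiles: Mapping,
    layout: MosaicLayout,
    weight_profile: np.ndarray | Callable[[tuple[int, int]], np.ndarray] | None = None,
) -> np.ndarray:
    """Weighted accumulation blend over the mosaic canvas.

    Implements ``P(x, y) = sum_i P_i W_i / sum_i W_i``: per tile the pixel
    values times the weight profile are accumulated alongside the weights,
    and the canvas is their ratio.  Pixels covered by exactly one tile are
    copied verbatim from that tile (bit-exact, no weight round-trip).

    ``weight_profile`` may be a single 2-D array or callable (shared by all
    tiles, the default feather ramp) or a mapping of tile key to per-tile
    weight array.
    """
    per_tile: dict = {}
    if isinstance(weight_profile, Mapping):
        per_tile = {
            k: np.asarray(w, dtype=np.float64) for k, w in weight_profile.items()
        }
        missing = set(tiles) - set(per_tile)
        if missing:
            raise ValueError(f"missing weight arrays for tiles {sorted(missing)}")
        shared = None
    elif weight_profile is None:
        shared = feather_weights(layout.tile_shape)
    elif callable(weight_profile):
        shared = np.asarray(weight_profile(layout.tile_shape), dtype=np.float64)
    else:
        shared = np.asarray(weight_profile, dtype=np.float64)
    for weights in ([shared] if shared is not None else per_tile.values()):
        if weights.shape != tuple(layout.tile_shape):
            raise ValueError("weight profile shape does not match tile shape")
        if np.any(weights < 0) or not np.any(weights > 0):
            raise ValueError("weights must be nonnegative and positive somewhere")
    th, tw = layout.tile_shape
    num = np.zeros(layout.canvas_shape, dtype=np.float64)
    den = np.zeros(layout.canvas_shape, dtype=np.float64)
    for key, tile in tiles.items():
        tile = np.asarray(tile, dtype=np.float64)
        if tile.shape != (th, tw):
            raise ValueError(f"tile {key} shape {tile.shape} != {layout.tile_shape}")
        weights = shared if shared is not None else per_tile[key]
        r, c = layout.canvas_position(key)
        num[r : r + th, c : c + tw] += tile * weights
        den[r : r + th, c : c + tw] += weights
    covered = layout.coverage >= 1
    if np.any(covered & (den <= 0)):
        raise ValueError("zero total weight inside the coverage region")
    out = np.zeros(layout.canvas_shape, dtype=np.float64)
    out[covered] = num[covered] / den[covered]
    single = layout.coverage == 1
    for key, tile in tiles.items():
        r, c = layout.canvas_position(key)
        window = (slice(r, r + th), slice(c, c + tw))
        sel = single[window]
        out[window][sel] = np.asarray(tile, dtype=np.float64)[sel]
    return out


# ---------------------------------------------------------------------------
# per-plane driver


def _pair_direction(a: tuple[int, int], b: tuple[int, int]) -> str:
    return "h" if a[0] == b[0] else "v"


def stitch_plane(
    holograms: Sequence[Hologram],
    matcher: Callable | None = None,
    margin: float = 0.10,
    bin_px: int = 1,
    min_support: float = MIN_SUPPORT_FRACTION,
    layout: MosaicLayout | None = None,
    crop_bounds: tuple[int, int, int, int] | None = None,
    weight_profile=None,
) -> tuple[Hologram, StitchInfo]:
    """Stitch one axial plane's tile set into an extended hologram.

    Estimates every adjacent-pair shift (falling back to the manifest's
    nominal shift when the vote support drops below ``min_support``),
    solves the global layout, blends, and crops to full coverage.  Pass a
    precomputed ``layout``/``crop_bounds`` to co-register several planes on
    the reference plane's geometry (see :func:`stitch_stack`).
    """
    if not holograms:
        raise ValueError("no holograms to stitch")
    pitch = holograms[0].pitch
    z = holograms[0].z
    z_index = holograms[0].z_index
    tile_shape = holograms[0].shape
    tiles: dict[tuple[int, int], Hologram] = {}
    for h in holograms:
        if h.shape != tile_shape or h.pitch != pitch or h.z_index != z_index:
            raise ValueError("holograms of one plane must share shape/pitch/plane")
        key = (h.grid_row, h.grid_col)
        if key in tiles:
            raise ValueError(f"duplicate tile at grid cell {key}")
        tiles[key] = h
    matcher = matcher or XCorrMatcher()
    matcher_name = getattr(matcher, "name", "matcher")

    shifts: dict = {}
    fallbacks: list = []
    if layout is None:
        if len(tiles) == 1:
            layout = MosaicLayout.build({next(iter(tiles)): (0, 0)}, tile_shape)
        else:
            pairs = build_topology(list(tiles))
            estimates = []
            for a_key, b_key in pairs:
                a, b = tiles[a_key], tiles[b_key]
                ndy = int(round((b.stage_y - a.stage_y) / pitch))
                ndx = int(round((b.stage_x - a.stage_x) / pitch))
                direction = _pair_direction(a_key, b_key)
                side = tile_shape[1] if direction == "h" else tile_shape[0]
                nominal_shift = ndx if direction == "h" else ndy
                nominal_overlap = 1.0 - nominal_shift / side
                ba, bb = extract_overlap_rois(
                    a.amplitude, b.amplitude, direction, nominal_overlap, margin
                )
                roi_a = a.amplitude[ba[0] : ba[1], ba[2] : ba[3]]
                roi_b = b.amplitude[bb[0] : bb[1], bb[2] : bb[3]]
                matches = match_rois(roi_a, roi_b, matcher)
                # certainty-based match sampling: keep only confident pairs
                reliable = matches.filter(DEFAULT_CONFIDENCE_THRESHOLD)
                estimate = None
                if len(reliable) >= 3:
                    reliable = reliable.offset((ba[0], ba[2]), (bb[0], bb[2]))
                    estimate = estimate_pair_shift(
                        reliable, bin_px=bin_px, pair=(a_key, b_key)
                    )
                if estimate is None or estimate.support_fraction < min_support:
                    logger.warning(
                        "pair %s-%s: unreliable match (support %s); falling "
                        "back to nominal shift (%d, %d)",
                        a_key, b_key,
                        "none" if estimate is None else f"{estimate.support_fraction:.2f}",
                        ndx, ndy,
                    )
                    estimate = ShiftEstimate(
                        dx=ndx, dy=ndy, votes=1, support_fraction=0.0,
                        pair=(a_key, b_key),
                    )
                    fallbacks.append((a_key, b_key))
                estimates.append(estimate)
            shifts = {e.pair: e for e in estimates}
            layout = global_align(estimates, tile_shape)

    canvas = blend(
        {k: h.amplitude for k, h in tiles.items()}, layout, weight_profile
    )
    if crop_bounds is None:
        cropped, crop_bounds = auto_crop(canvas, layout.coverage)
    else:
        r0, r1, c0, c1 = crop_bounds
        cropped = canvas[r0:r1, c0:c1]
    anchor = tiles[min(tiles)]
    stitched = Hologram(
        amplitude=np.clip(cropped, 0.0, None),
        pitch=pitch,
        z=z,
        z_index=z_index,
        stage_x=anchor.stage_x,
        stage_y=anchor.stage_y,
    )
    info = StitchInfo(shifts, layout, tuple(crop_bounds), fallbacks, matcher_name)
    return stitched, info


def stitch_stack(
    holograms: Sequence[Hologram],
    reference_index: int,
    **kwargs,
) -> tuple[list[Hologram], list[StitchInfo]]:
    """Stitch every axial plane with a shared, co-registered geometry.

    The reference plane is stitched first (registration + auto crop); its
    layout and crop bounds are then reused for every other plane, so the
    resulting stack stays pixel-co-registered for multi-depth retrieval.
    """
    by_plane: dict[int, list[Hologram]] = {}
    for h in holograms:
        by_plane.setdefault(h.z_index, []).append(h)
    plane_ids = sorted(by_plane)
    if reference_index not in by_plane:
        raise ValueError(f"reference plane {reference_index} not present")
    ref_stitched, ref_info = stitch_plane(by_plane[reference_index], **kwargs)
    stitched_list: list[Hologram] = []
    infos: list[StitchInfo] = []
    for zi in plane_ids:
        if zi == reference_index:
            stitched_list.append(ref_stitched)
            infos.append(ref_info)
            continue
        s, info = stitch_plane(
            by_plane[zi],
            layout=ref_info.layout,
            crop_bounds=ref_info.crop_bounds,
            **{k: v for k, v in kwargs.items() if k not in ("layout", "crop_bounds")},
        )
        stitched_list.append(s)
        infos.append(info)
    return stitched_list, infos
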