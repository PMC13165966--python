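"""Synthetic forward model for scanned, multi-depth in-line holography.

Generates bar-target / phantom objects and the multi-FOV, multi-depth
hologram sets (with a stage-coordinate manifest) that the stitching and
retrieval stages consume.  Tiles are produced by propagating the full
object wavefront once per axial plane and cropping windows at the stage
offsets, which is the physics of translating the sample under fixed
illumination and guarantees exact tile-overlap consistency for noiseless
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .analysis import usaf_linewidth
from .optics import ComplexField, OpticalConfig, propagate

__all__ = [
    "ScanGrid",
    "Hologram",
    "generate_bar_target",
    "phase_object",
    "element_footprint",
    "element_profile_line",
    "simulate_hologram",
    "simulate_scan",
]


@dataclass(frozen=True)
class ScanGrid:
    """A rows x cols serpentine lateral scan.

    ``step`` is the centre-to-centre stage displacement in metres; tiles of
    ``tile_side_px`` pixels at ``pitch`` metres/pixel must overlap
    (``step < tile_side_px * pitch``).
    """

    rows: int
    cols: int
    step: float
    tile_side_px: int
    pitch: float

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.tile_side_px < 1:
            raise ValueError("tile_side_px must be positive")
        if not (self.pitch > 0):
            raise ValueError("pitch must be positive")
        if not (0 < self.step < self.tile_side_px * self.pitch):
            raise ValueError(
                f"step must be in (0, tile_side) = (0, "
                f"{self.tile_side_px * self.pitch:.4g}) m, got {self.step:.4g}"
            )

    @property
    def tile_side(self) -> float:
        """Physical tile side length in metres."""
        return self.tile_side_px * self.pitch

    @property
    def nominal_overlap(self) -> float:
        """Nominal overlap ratio ``1 - step / tile_side`` in (0, 1)."""
        return 1.0 - self.step / self.tile_side

    @property
    def step_px(self) -> int:
        """Stage step in whole pixels (must divide evenly, see notes).

        The stage step is required to be an integer number of pixels; the
        registration model is integer-pixel translation.
        """
        px = self.step / self.pitch
        if abs(px - round(px)) > 1e-6:
            raise ValueError(
                f"step {self.step:.6g} m is not an integer multiple of the "
                f"pitch {self.pitch:.6g} m"
            )
        return int(round(px))

    @property
    def order(self) -> list[tuple[int, int]]:
        """Serpentine visit order: row-by-row, alternating direction,
        starting at the upper-left cell."""
        cells: list[tuple[int, int]] = []
        for r in range(self.rows):
            cs = range(self.cols) if r % 2 == 0 else range(self.cols - 1, -1, -1)
            cells.extend((r, c) for c in cs)
        return cells

    def stage_position(self, row: int, col: int) -> tuple[float, float]:
        """Stage (x, y) in metres for a grid cell: ``(col*step, row*step)``."""
        return col * self.step, row * self.step

    def scan_extent_px(self) -> tuple[int, int]:
        """Full scanned object extent in pixels (rows, cols)."""
        return (
            self.tile_side_px + (self.rows - 1) * self.step_px,
            self.tile_side_px + (self.cols - 1) * self.step_px,
        )


@dataclass
class Hologram:
    """A recorded (or simulated) amplitude hologram tile with stage metadata."""

    amplitude: np.ndarray
    pitch: float
    z: float
    z_index: int = 0
    grid_row: int = 0
    grid_col: int = 0
    stage_x: float = 0.0
    stage_y: float = 0.0

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.amplitude.ndim != 2:
            raise ValueError("hologram amplitude must be 2-D")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("hologram amplitude contains NaN or Inf")
        if np.any(self.amplitude < 0):
            raise ValueError("hologram amplitude must be nonnegative")
        if not (self.pitch > 0):
            raise ValueError("pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


def element_footprint(group: int, element: int, pitch: float) -> tuple[int, int, int]:
    """Pixel geometry of a drawn chart element.

    Returns ``(bar_width_px, height_px, width_px)`` of the block drawn by
    :func:`generate_bar_target`: a vertical-bar triplet (5w x 5w) and a
    horizontal-bar triplet (5w x 5w) separated by a 1w gutter, i.e. a
    ``5w x 11w`` footprint.
    """
    width_um = usaf_linewidth(group, element)
    w = int(round(width_um * 1e-6 / pitch))
    return w, 5 * w, 11 * w


def generate_bar_target(
    canvas_px: tuple[int, int],
    pitch: float,
    elements: Iterable[tuple[int, int, tuple[int, int]]],
) -> np.ndarray:
    """Draw a three-bar resolution chart as an amplitude transmission map.

    Each entry of ``elements`` is ``(group, element, (row, col))`` with the
    position the top-left pixel of the element block.  Bars have width
    ``w = usaf_linewidth(group, element)`` (rounded to pixels), length
    ``5w`` and gaps ``w``, drawn in both orientations; background
    transmission is 1 and bars are 0.

    Raises if any element's bar width comes out below 2 px at this pitch,
    or if a block does not fit on the canvas.
    """
    canvas = np.ones(tuple(int(s) for s in canvas_px), dtype=np.float64)
    for group, element, (r0, c0) in elements:
        w, height, width = element_footprint(group, element, pitch)
        if w < 2:
            raise ValueError(
                f"element G{group}E{element} unresolvable at pitch "
                f"{pitch * 1e6:.3g} um (bar width {w} px < 2 px)"
            )
        if r0 < 0 or c0 < 0 or r0 + height > canvas.shape[0] or c0 + width > canvas.shape[1]:
            raise ValueError(
                f"element G{group}E{element} at ({r0}, {c0}) does not fit on "
                f"canvas {canvas.shape}"
            )
        # vertical bars: three w-wide columns spanning 5w rows
        for k in range(3):
            c = c0 + 2 * k * w
            canvas[r0 : r0 + 5 * w, c : c + w] = 0.0
        # horizontal bars: three w-tall rows spanning 5w cols, offset 6w right
        ch = c0 + 6 * w
        for k in range(3):
            r = r0 + 2 * k * w
            canvas[r : r + w, ch : ch + 5 * w] = 0.0
    return canvas


def phase_object(transmission: np.ndarray, phase_delay: float) -> np.ndarray:
    """Turn a [0, 1] transmission map into a pure-phase object.

    Where the map is dark (bars), the object imparts ``phase_delay``
    radians; amplitude is 1 everywhere.
    """
    transmission = np.asarray(transmission, dtype=np.float64)
    return np.exp(1j * phase_delay * (1.0 - transmission))


def element_profile_line(
    group: int, element: int, position: tuple[int, int], pitch: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Line across the vertical-bar triplet of an element, for contrast
    measurement: horizontal, through the block centre, extended half a bar
    width beyond the bars on each side."""
    w, _, _ = element_footprint(group, element, pitch)
    r0, c0 = position
    r = r0 + 2.5 * w
    return (r, c0 - 0.5 * w), (r, c0 + 5.0 * w - 0.5 * w)


def simulate_hologram(
    object_map: np.ndarray,
    config: OpticalConfig,
    z: float,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    band_limited: bool = False,
    z_index: int = 0,
) -> Hologram:
    """Record the in-line hologram amplitude of an object at distance ``z``.

    Plane-wave illumination: the recorded amplitude is
    ``|propagate(object_map, z)|``, optionally degraded by additive
    Gaussian noise (std ``noise_sigma``) clipped at 0.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    fld = ComplexField(np.asarray(object_map, dtype=np.complex128),
                       config.pitch, config.wavelength, z=0.0)
    sensor = propagate(fld, z, band_limited=band_limited)
    amplitude = np.abs(sensor.values)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        amplitude = np.clip(amplitude + rng.normal(0.0, noise_sigma, amplitude.shape), 0.0, None)
    return Hologram(amplitude=amplitude, pitch=config.pitch, z=z, z_index=z_index)


def simulate_scan(
    object_map: np.ndarray,
    grid: ScanGrid,
    config: OpticalConfig,
    noise_sigma: float = 0.0,
    seed: int = 0,
    band_limited: bool = False,
) -> tuple[list[Hologram], list[dict]]:
    """Simulate a full serpentine x-y scan at every configured axial plane.

    The full object is propagated once per z plane and each tile is a
    ``tile_side_px`` crop at the tile's stage offset, so any two adjacent
    noiseless tiles agree exactly on their geometric overlap and the
    ground-truth inter-tile shift is ``grid.step_px`` pixels.

    Returns ``(holograms, manifest_records)`` with one record per tile:
    ``{"grid_row", "grid_col", "stage_x_mm", "stage_y_mm", "z_index",
    "z_mm"}``.  With ``noise_sigma == 0`` the output is bitwise
    deterministic; with noise, a fixed ``seed`` makes it reproducible.
    """
    object_map = np.asarray(object_map, dtype=np.complex128)
    if grid.pitch != config.pitch:
        raise ValueError("grid pitch and config pitch disagree")
    need = grid.scan_extent_px()
    if object_map.shape[0] < need[0] or object_map.shape[1] < need[1]:
        raise ValueError(
            f"object map {object_map.shape} too small for scan; needs at "
            f"least {need} pixels"
        )
    rng = np.random.default_rng(seed)
    step_px = grid.step_px
    side = grid.tile_side_px
    holograms: list[Hologram] = []
    records: list[dict] = []
    fld = ComplexField(object_map, config.pitch, config.wavelength, z=0.0)
    for zi, z in enumerate(config.z_planes):
        full = propagate(fld, z, band_limited=band_limited)
        full_amp = np.abs(full.values)
        for r, c in grid.order:
            top, left = r * step_px, c * step_px
            amp = full_amp[top : top + side, left : left + side].copy()
            if noise_sigma > 0:
                amp = np.clip(amp + rng.normal(0.0, noise_sigma, amp.shape), 0.0, None)
            sx, sy = grid.stage_position(r, c)
            holograms.append(
                Hologram(
                    amplitude=amp,
                    pitch=config.pitch,
                    z=z,
                    z_index=zi,
                    grid_row=r,
                    grid_col=c,
                    stage_x=sx,
                    stage_y=sy,
                )
            )
            records.append(
                {
                    "grid_row": r,
                    "grid_col": c,
                    "stage_x_mm": sx * 1e3,
                    "stage_y_mm": sy * 1e3,
                    "z_index": zi,
                    "z_mm": z * 1e3,
                }
            )
    return holograms, records
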