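"""Quantification of fluorescent sediment-profile images (f-SPI).

A profile photograph of an aquarium face shows water above a rough
sediment surface, with pink luminophore tracer particles mixed into the
sediment by burrowing fauna.  Quantification proceeds in three steps:

1. segment the pink luminophore pixels (colour-margin rule),
2. trace the interface per image column — the sediment–water interface in
   stocked aquaria, or the sediment–luminophore-carpet interface in
   control aquaria where an unmixed surface carpet accumulates,
3. flatten the interface and aggregate luminophore pixels into a depth
   profile (mm below the local interface, clipped at zero above it).

Coordinates are 0-based with row index increasing downward; depths are
positive downward in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("fspimix")

#: interface-trace conventions
MODE_TREATMENT = "treatment"  # sediment-water interface
MODE_CONTROL = "control"      # sediment / luminophore-carpet interface


@dataclass(frozen=True)
class ProfileImage:
    """One RGB photograph of an aquarium face with physical metadata."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    resolution_mm_per_px: float
    aquarium_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("ProfileImage requires an RGB (rows, cols, 3) array")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be at least 2 x 2 pixels")
        if self.resolution_mm_per_px <= 0:
            raise ValueError("resolution_mm_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class SegmentationRule:
    """Pink-dominance colour rule for luminophore pixels.

    A pixel is luminophore when its red value exceeds ``r_min`` and red
    dominates green and blue by the given margins.  Defaults are matched
    to the renderer's palette and tolerate additive noise well below the
    margins.
    """

    r_min: int = 120
    rg_margin: int = 60
    rb_margin: int = 30


@dataclass(frozen=True)
class LuminophoreMask:
    mask: np.ndarray  # boolean, aligned with source image
    count: int

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")
        if self.count != int(self.mask.sum()):
            raise ValueError("count does not match mask")


@dataclass(frozen=True)
class InterfaceTrace:
    """Per-column interface elevation (row index), plus its convention."""

    elevations: np.ndarray  # int row index per column
    mode: str
    resolution_mm_per_px: float

    def __post_init__(self) -> None:
        if self.mode not in (MODE_TREATMENT, MODE_CONTROL):
            raise ValueError(f"unknown interface mode {self.mode!r}")
        if self.elevations.ndim != 1:
            raise ValueError("elevations must be one value per column")


@dataclass(frozen=True)
class DepthProfile:
    """Pixel counts of luminophore by depth below the flattened interface."""

    depths_mm: np.ndarray   # sorted unique non-negative depths
    counts: np.ndarray      # pixel count per depth, >= 1
    resolution_mm_per_px: float
    total: int = field(default=0)

    def __post_init__(self) -> None:
        if np.any(self.depths_mm < 0):
            raise ValueError("depths must be non-negative")
        if self.total != int(self.counts.sum()):
            raise ValueError("total does not match counts")

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    def expand(self) -> np.ndarray:
        """All pixel depths as a flat array (one entry per pixel)."""
        return np.repeat(self.depths_mm, self.counts)


def segment_luminophores(
    image: ProfileImage, rule: SegmentationRule | None = None
) -> LuminophoreMask:
    """Mask the pink luminophore pixels of ``image``."""
    rule = rule or SegmentationRule()
    px = image.pixels.astype(np.int16)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    mask = (r >= rule.r_min) & (r - g >= rule.rg_margin) & (r - b >= rule.rb_margin)
    return LuminophoreMask(mask=mask, count=int(mask.sum()))


def _water_mask(image: ProfileImage) -> np.ndarray:
    # water is the only blue-dominant phase of the scene
    px = image.pixels.astype(np.int16)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    return (b > r) & (b > g)


def detect_interface(
    image: ProfileImage,
    mask: LuminophoreMask,
    mode: str = MODE_TREATMENT,
    window: int = 5,
    occupancy: float = 1.0,
) -> InterfaceTrace:
    """Trace the interface row per column.

    For each column the elevation is the topmost row from which a sliding
    vertical window of ``window`` rows has at least ``occupancy`` fraction
    of "solid" pixels.  In treatment mode solid means sediment or
    luminophore (the sediment-water interface); in control mode
    luminophore pixels are excluded, so the trace falls below the unmixed
    surface carpet.  The windowed rule resists isolated particles
    floating in the water column.
    """
    if mode not in (MODE_TREATMENT, MODE_CONTROL):
        raise ValueError(f"unknown interface mode {mode!r}")
    if mask.mask.shape != image.shape:
        raise ValueError("mask is not aligned with the image")
    if window < 1:
        raise ValueError("window must be >= 1")

    solid = ~_water_mask(image)
    if mode == MODE_CONTROL:
        solid = solid & ~mask.mask
    if not solid.any():
        raise ValueError("all-water image: no interface exists")

    h, w = solid.shape
    # sliding-window occupancy via cumulative sums down each column
    occ = np.cumsum(solid.astype(np.int32), axis=0)
    occ = np.vstack([np.zeros((1, w), np.int32), occ])
    n_windows = h - window + 1
    if n_windows < 1:
        raise ValueError("window taller than the image")
    counts = occ[window:] - occ[:-window]  # (n_windows, w)
    ok = counts >= occupancy * window
    if not ok.any(axis=0).all():
        bad = np.nonzero(~ok.any(axis=0))[0]
        raise ValueError(f"no sediment found in column(s) {bad[:5].tolist()}")
    elevations = ok.argmax(axis=0).astype(np.int64)
    return InterfaceTrace(
        elevations=elevations, mode=mode,
        resolution_mm_per_px=image.resolution_mm_per_px,
    )


def flatten_and_profile(mask: LuminophoreMask, interface: InterfaceTrace) -> DepthProfile:
    """Aggregate luminophore pixels by depth below the flattened interface.

    Each masked pixel contributes ``max(0, row - elevation(column))`` times
    the pixel pitch; pixels above the interface are clipped to depth 0 so
    the control carpet carries a defined depth-0 mass.
    """
    if mask.mask.shape[1] != interface.elevations.shape[0]:
        raise ValueError("mask and interface are not from the same image")
    rows, cols = np.nonzero(mask.mask)
    depth_px = np.maximum(0, rows - interface.elevations[cols])
    depths_mm = depth_px * interface.resolution_mm_per_px
    uniq, counts = np.unique(depths_mm, return_counts=True)
    return DepthProfile(
        depths_mm=uniq, counts=counts,
        resolution_mm_per_px=interface.resolution_mm_per_px,
        total=int(counts.sum()),
    )


def quantify_image(
    image: ProfileImage,
    mode: str = MODE_TREATMENT,
    rule: SegmentationRule | None = None,
    window: int = 5,
    occupancy: float = 1.0,
) -> tuple[DepthProfile, InterfaceTrace]:
    """Full quantification: segment, trace the interface, flatten."""
    mask = segment_luminophores(image, rule)
    trace = detect_interface(image, mask, mode=mode, window=window, occupancy=occupancy)
    profile = flatten_and_profile(mask, trace)
    logger.info(
        "quantified %s d%d: %d luminophore px, interface rows %d-%d (%s mode)",
        image.aquarium_id or "<image>", image.day, mask.count,
        int(trace.elevations.min()), int(trace.elevations.max()), mode,
    )
    return profile, trace
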