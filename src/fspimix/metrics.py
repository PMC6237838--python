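"""Per-aquarium bioturbation statistics.

From the pixel-weighted luminophore depth distribution of one image:

* ``l_max`` — deepest luminophore pixel (long-term extent of mixing),
* ``l_med`` — median pixel depth (typical short-term mixing depth),
* ``l_mean`` — mean pixel depth (time-integrated mixing indication),

and from the interface trace the surface boundary roughness

* ``sbr`` — peak-to-trough interface deviation, stocked aquaria only
  (controls have no remobilised sediment-water interface).

All statistics are image-wide and in millimetres; the surface carpet's
depth-0 mass is part of the distribution, so control aquaria have a
defined (zero) mixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import MODE_TREATMENT, DepthProfile, InterfaceTrace


@dataclass(frozen=True)
class MixingMetrics:
    aquarium_id: str
    day: int
    l_max_mm: float
    l_med_mm: float
    l_mean_mm: float
    sbr_mm: float | None  # None for control aquaria

    def __post_init__(self) -> None:
        if not (0 <= self.l_med_mm <= self.l_max_mm + 1e-9):
            raise ValueError("l_med must lie in [0, l_max]")
        if not (0 <= self.l_mean_mm <= self.l_max_mm + 1e-9):
            raise ValueError("l_mean must lie in [0, l_max]")
        if self.sbr_mm is not None and self.sbr_mm < 0:
            raise ValueError("sbr must be >= 0")


def _require_nonempty(profile: DepthProfile) -> None:
    if profile.is_empty:
        raise ValueError("depth profile is empty (no luminophore pixels)")


def l_max(profile: DepthProfile) -> float:
    """Greatest depth with luminophore mass (mm)."""
    _require_nonempty(profile)
    return float(profile.depths_mm[-1])


def l_med(profile: DepthProfile) -> float:
    """Pixel-weighted median depth (mm); even totals use the midpoint of
    the two middle order statistics."""
    _require_nonempty(profile)
    return float(np.median(profile.expand()))


def l_mean(profile: DepthProfile) -> float:
    """Pixel-weighted mean depth (mm)."""
    _require_nonempty(profile)
    return float(np.average(profile.depths_mm, weights=profile.counts))


def sbr(interface: InterfaceTrace) -> float:
    """Surface boundary roughness: (max - min) interface elevation in mm.

    Only defined for the sediment-water interface of stocked aquaria; a
    control-mode trace (sediment/luminophore-carpet boundary) is refused.
    """
    if interface.mode != MODE_TREATMENT:
        raise ValueError("SBR is only defined for treatment-mode interfaces")
    if interface.elevations.shape[0] < 2:
        raise ValueError("SBR needs at least 2 columns")
    span = int(interface.elevations.max() - interface.elevations.min())
    return span * interface.resolution_mm_per_px


def compute_metrics(
    profile: DepthProfile,
    interface: InterfaceTrace,
    is_control: bool,
    aquarium_id: str = "",
    day: int = 0,
) -> MixingMetrics:
    """Bundle the four statistics; SBR is omitted for controls."""
    return MixingMetrics(
        aquarium_id=aquarium_id, day=day,
        l_max_mm=l_max(profile), l_med_mm=l_med(profile),
        l_mean_mm=l_mean(profile),
        sbr_mm=None if is_control else sbr(interface),
    )


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-aquarium metric rows into the standard table layout."""
    cols = ["aquarium_id", "treatment", "n_rd", "n_rp", "replicate", "day",
            "l_max_mm", "l_med_mm", "l_mean_mm", "sbr_mm"]
    return pd.DataFrame(rows, columns=cols)
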