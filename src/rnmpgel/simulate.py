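"""Forward simulator of alkaline-gel lanes and gel images.

Renders a :class:`~rnmpgel.fragmentation.FragmentSet` (or a discrete marker
ladder) into a noisy 1-D densitometric profile under the log-linear
migration law ``d = a + b * ln(size)`` and assembles profiles into a 2-D
grayscale gel image.  The physical premises mirror what the inverse
pipeline assumes:

* migration distance depends log-linearly on fragment size, with ``b < 0``
  so larger fragments run shorter;
* an intercalating stain deposits mass proportional to fragment length
  (one intensity unit per nucleotide), which is exactly why dividing lane
  intensity by fragment size recovers fragment *counts*;
* bands spread as a Gaussian in distance space, and detection adds a
  constant baseline plus seeded Gaussian noise.

Fragments whose migration distance falls outside the lane are dropped and
their stain mass is reported (``clipped_mass``), so mass bookkeeping stays
exact: sum of noiseless profile intensities == total mass - clipped mass.
"""

from __future__ import annotations

import math
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .densitometry import GelImage, LaneProfile
from .fragmentation import FragmentSet

__all__ = [
    "GelSimConfig",
    "MarkerLadder",
    "migrate",
    "render_lane",
    "render_gel_image",
]


class GelSimConfig(BaseModel):
    """Forward-model parameterization of one gel.

    ``migration_a`` (mm) and ``migration_b`` (mm per natural-log size unit,
    negative) define ``d = a + b * ln(size)``.  The defaults place the
    calibratable window 200 nt - 50 knt between roughly 16 mm and 64 mm on a
    100 mm lane.  Noise and baseline are in the same arbitrary intensity
    units as the stain mass: for a 10 Mnt load the peak pixel signal is
    ~6e4 of those units, so the defaults put the detector noise at ~0.2% of
    peak (the regime of a cooled-CCD gel imager) and the constant background
    at a few percent of peak.
    """

    migration_a: float = 110.0
    migration_b: float = -8.686
    lane_length: float = Field(default=100.0, gt=0, description="lane length (mm)")
    pixels_per_mm: float = Field(default=10.0, gt=0)
    band_sigma: float = Field(default=0.5, ge=0, description="band point-spread sigma (mm)")
    noise_sigma: float = Field(default=100.0, ge=0, description="additive noise sigma")
    baseline: float = Field(default=2000.0, ge=0, description="constant background offset")
    wells_at_top: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check_monotone(self) -> "GelSimConfig":
        if self.migration_b >= 0:
            raise ValueError(
                "migration_b must be < 0: distance is measured from the well and "
                "larger fragments migrate less"
            )
        return self


class MarkerLadder(BaseModel):
    """Size-reference ladder: known fragment sizes loaded in one lane."""

    sizes: list[float]
    label: str = "marker"

    @model_validator(mode="after")
    def _check_sizes(self) -> "MarkerLadder":
        s = np.asarray(self.sizes, dtype=float)
        if s.size < 1 or (s < 1).any():
            raise ValueError("ladder sizes must all be >= 1")
        d = np.diff(s)
        if s.size >= 2 and not ((d > 0).all() or (d < 0).all()):
            raise ValueError("ladder sizes must be strictly monotone")
        return self

    def to_csv(self, path: str | Path, distances_mm: Sequence[float] | None = None) -> None:
        data: dict = {"size_nt": self.sizes}
        if distances_mm is not None:
            data["distance_mm"] = list(distances_mm)
        pd.DataFrame(data).to_csv(path, index=False)


def migrate(size, config: GelSimConfig):
    """Migration distance ``a + b * ln(size)`` in mm (natural log).

    Accepts a scalar or array of sizes (nucleotides, >= 1).  Distances may
    fall outside ``[0, lane_length]``; callers decide how to clip.
    """
    size = np.asarray(size, dtype=float)
    if (size < 1).any():
        raise ValueError("fragment size must be >= 1 nt")
    d = config.migration_a + config.migration_b * np.log(size)
    return float(d) if d.ndim == 0 else d


def _grid(config: GelSimConfig) -> np.ndarray:
    n_px = int(round(config.lane_length * config.pixels_per_mm))
    return (np.arange(n_px) + 0.5) / config.pixels_per_mm


def render_lane(
    fragments: FragmentSet | MarkerLadder,
    config: GelSimConfig,
    lane_id: str = "",
    copies: float | None = None,
    mass_per_band: float | None = None,
) -> LaneProfile:
    """Render a fragment collection into a noisy densitometric profile.

    Each fragment of size ``s`` deposits stain mass ``s`` (one intensity
    unit per nucleotide) at ``migrate(s)``, spread by a Gaussian of sigma
    ``band_sigma`` and sampled at ``pixels_per_mm``; baseline and seeded
    Gaussian noise are then added and the result floored at zero.

    For a :class:`MarkerLadder`, band mass is ``copies * size`` per band if
    ``copies`` is given, else ``mass_per_band`` per band (default 1e6 -
    commercial ladders load roughly equal mass per band).

    The profile's ``meta`` records ``clipped_mass`` (stain mass of fragments
    migrating outside the lane) and ``total_mass``.
    """
    if isinstance(fragments, MarkerLadder):
        sizes = np.asarray(fragments.sizes, dtype=float)
        if copies is not None:
            mass = float(copies) * sizes
        else:
            mass = np.full(sizes.size, 1e6 if mass_per_band is None else float(mass_per_band))
        lane_id = lane_id or fragments.label
    else:
        sizes = fragments.lengths.astype(float)
        mass = sizes.copy()
    if sizes.size == 0:
        raise ValueError("empty fragment collection")

    d = np.asarray(migrate(sizes, config), dtype=float).ravel()
    grid = _grid(config)
    inside = (d >= 0.0) & (d < config.lane_length)
    clipped_mass = float(mass[~inside].sum())
    if not inside.any():
        raise ValueError("all fragments migrated outside the lane (empty lane)")

    # Deposit mass on the pixel grid, then apply the band point-spread with a
    # discretely normalized kernel so mass is conserved exactly.
    idx = np.clip((d[inside] * config.pixels_per_mm).astype(int), 0, grid.size - 1)
    profile = np.bincount(idx, weights=mass[inside], minlength=grid.size).astype(float)
    if config.band_sigma > 0:
        sigma_px = config.band_sigma * config.pixels_per_mm
        half = max(1, int(math.ceil(4 * sigma_px)))
        k = np.arange(-half, half + 1, dtype=float)
        kernel = np.exp(-0.5 * (k / sigma_px) ** 2)
        kernel /= kernel.sum()
        padded = np.pad(profile, half, mode="constant")
        profile = np.convolve(padded, kernel, mode="same")[half:-half]

    if config.noise_sigma > 0 or config.baseline > 0:
        # per-lane substream: offset the seed by a stable hash of the lane id
        lane_key = zlib.crc32(lane_id.encode()) % 100003 if lane_id else 0
        rng = np.random.default_rng(int(config.seed) + lane_key)
        noise = rng.normal(0.0, config.noise_sigma, grid.size) if config.noise_sigma > 0 else 0.0
        profile = np.clip(profile + config.baseline + noise, 0.0, None)

    return LaneProfile(
        distance_mm=grid,
        intensity=profile,
        lane_id=lane_id,
        meta={"clipped_mass": clipped_mass, "total_mass": float(mass.sum())},
    )


def render_gel_image(
    lanes: Sequence[LaneProfile],
    config: GelSimConfig,
    lane_width_mm: float = 5.0,
    gap_mm: float = 3.0,
    margin_mm: float = 3.0,
) -> GelImage:
    """Assemble lane profiles into a 2-D grayscale gel image.

    Each lane occupies a vertical stripe with a cosine (Hann) horizontal
    taper whose column weights sum to one, so summing a stripe's columns
    reproduces the lane profile exactly (before quantization).  Stripe
    boundaries are returned in ``lane_regions``.
    """
    if len(lanes) == 0:
        raise ValueError("need at least one lane")
    n_rows = {lane.n_samples for lane in lanes}
    if len(n_rows) != 1:
        raise ValueError("all lane profiles must share one sampling grid")
    rows = n_rows.pop()
    ppm = config.pixels_per_mm
    lane_px = max(3, int(round(lane_width_mm * ppm)))
    gap_px = int(round(gap_mm * ppm))
    margin_px = int(round(margin_mm * ppm))
    width = 2 * margin_px + len(lanes) * lane_px + (len(lanes) - 1) * gap_px
    pixels = np.zeros((rows, width))
    taper = np.hanning(lane_px + 2)[1:-1]
    taper /= taper.sum()
    regions: list[tuple[int, int]] = []
    for i, lane in enumerate(lanes):
        c0 = margin_px + i * (lane_px + gap_px)
        pixels[:, c0 : c0 + lane_px] = lane.intensity[:, None] * taper[None, :]
        regions.append((c0, c0 + lane_px))
    if not config.wells_at_top:
        pixels = pixels[::-1]
    return GelImage(
        pixels=pixels,
        pixels_per_mm=ppm,
        wells_at_top=config.wells_at_top,
        lane_regions=regions,
    )
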