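"""Gel image densitometry: lane profiles, background removal, smoothing, peaks.

A gel lane is reduced to a 1-D densitometric curve by summing pixel
intensities across the lane's width at each migration depth.  The curve is
then cleaned: a background baseline is removed (morphological opening by
default, the standard baseline model for gel traces) and the curve is
smoothed with a Gaussian kernel whose window is a fixed fraction (3% by
default) of the lane length.  Marker-lane band positions are located with a
prominence-based peak detector.

Distances are measured in millimetres from the well, increasing toward the
gel bottom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, signal

__all__ = [
    "LaneProfile",
    "GelImage",
    "load_gel_image",
    "extract_lane_profile",
    "subtract_background",
    "smooth_profile",
    "detect_peaks",
    "find_lanes",
]


@dataclass
class LaneProfile:
    """1-D densitometric curve along a gel lane.

    ``distance_mm`` is a strictly increasing grid measured from the well;
    ``intensity`` is in arbitrary units (non-negative, finite).
    """

    distance_mm: np.ndarray
    intensity: np.ndarray
    lane_id: str = ""
    background_subtracted: bool = False
    smoothed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distance_mm.shape != self.intensity.shape or self.distance_mm.ndim != 1:
            raise ValueError("distance_mm and intensity must be equal-length 1-D arrays")
        if self.distance_mm.size >= 2 and not (np.diff(self.distance_mm) > 0).all():
            raise ValueError("distance_mm must be strictly increasing")
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensities must be finite")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.distance_mm.size

    @property
    def spacing_mm(self) -> float:
        """Median sample spacing in mm."""
        return float(np.median(np.diff(self.distance_mm)))

    @property
    def length_mm(self) -> float:
        """Lane length spanned by the profile."""
        return float(self.distance_mm[-1] - self.distance_mm[0])

    @property
    def total_intensity(self) -> float:
        """Sum of sample intensities (the mass bookkeeping quantity)."""
        return float(self.intensity.sum())

    def replace(self, **kwargs) -> "LaneProfile":
        fields_ = dict(
            distance_mm=self.distance_mm,
            intensity=self.intensity,
            lane_id=self.lane_id,
            background_subtracted=self.background_subtracted,
            smoothed=self.smoothed,
            meta=dict(self.meta),
        )
        fields_.update(kwargs)
        return LaneProfile(**fields_)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"distance_mm": self.distance_mm, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, lane_id: str = "") -> "LaneProfile":
        df = pd.read_csv(path)
        return cls(
            distance_mm=df["distance_mm"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            lane_id=lane_id or Path(path).stem,
        )


@dataclass
class GelImage:
    """2-D grayscale gel image, wells at the top by convention.

    ``pixels[row, col]`` with row 0 at the well; ``lane_regions`` are
    half-open ``(col_start, col_end)`` pixel intervals, one per lane.
    """

    pixels: np.ndarray
    pixels_per_mm: float
    wells_at_top: bool = True
    lane_regions: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if (self.pixels < 0).any():
            raise ValueError("pixel intensities must be non-negative")
        if self.pixels_per_mm <= 0:
            raise ValueError("pixels_per_mm must be > 0")

    @property
    def oriented_pixels(self) -> np.ndarray:
        """Pixels with row 0 at the well (flips if wells are at the bottom)."""
        return self.pixels if self.wells_at_top else self.pixels[::-1]

    def save_tiff(self, path: str | Path) -> None:
        """Write as 16-bit grayscale TIFF, scaled to the full dynamic range."""
        tifffile.imwrite(str(path), _quantize(self.pixels, np.uint16))

    def save_png(self, path: str | Path) -> None:
        """Write as 8-bit grayscale PNG."""
        iio.imwrite(str(path), _quantize(self.pixels, np.uint8))


def _quantize(pixels: np.ndarray, dtype: type) -> np.ndarray:
    top = float(np.iinfo(dtype).max)
    peak = float(pixels.max())
    scale = top / peak if peak > 0 else 1.0
    return np.round(pixels * scale).astype(dtype)


def load_gel_image(
    path: str | Path,
    pixels_per_mm: float,
    wells_at_top: bool = True,
    lane_regions: list[tuple[int, int]] | None = None,
) -> GelImage:
    """Load an 8/16-bit grayscale TIFF or PNG as a :class:`GelImage`.

    Intensities are kept in raw quantized units; the estimator is invariant
    to the overall intensity scale, so no rescaling is applied.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(str(path))
    else:
        raw = iio.imread(str(path))
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 3:  # collapse an RGB(A) scan to luminance
        raw = raw[..., :3].mean(axis=2)
    return GelImage(
        pixels=raw,
        pixels_per_mm=pixels_per_mm,
        wells_at_top=wells_at_top,
        lane_regions=lane_regions,
    )


def extract_lane_profile(
    image: GelImage,
    lane_region: tuple[int, int],
    lane_id: str = "",
    well_row: int = 0,
) -> LaneProfile:
    """Sum pixel columns of one lane into a densitometric curve.

    Intensity at each migration depth is the sum of pixel values across the
    lane's columns; the distance axis places row ``well_row`` at the well and
    uses pixel centres, ``(row + 0.5) / pixels_per_mm``.
    """
    col_start, col_end = int(lane_region[0]), int(lane_region[1])
    pixels = image.oriented_pixels
    if not (0 <= col_start < col_end <= pixels.shape[1]):
        raise ValueError(
            f"lane region ({col_start}, {col_end}) outside image width {pixels.shape[1]}"
        )
    if not (0 <= well_row < pixels.shape[0]):
        raise ValueError(f"well_row={well_row} outside image height {pixels.shape[0]}")
    stripe = pixels[well_row:, col_start:col_end]
    intensity = stripe.sum(axis=1)
    distance = (np.arange(stripe.shape[0]) + 0.5) / image.pixels_per_mm
    return LaneProfile(distance_mm=distance, intensity=intensity, lane_id=lane_id)


def subtract_background(
    profile: LaneProfile,
    method: str = "rolling-minimum",
    window_mm: float = 50.0,
) -> LaneProfile:
    """Remove the baseline from a lane profile.

    ``global-minimum`` subtracts a constant equal to the profile minimum.
    ``rolling-minimum`` subtracts a morphological opening (running minimum
    over ``window_mm`` followed by a same-window running maximum), the
    standard baseline model for gel traces: it follows slow background drift
    but cannot rise into bands narrower than the window.  The opening is
    computed on a median-prefiltered copy (~1 mm window) so that detector
    noise does not drag the running minimum below the true background — the
    same pre-smoothing rolling-ball background removers apply; the baseline
    is then subtracted from the *unfiltered* trace.  Results are floored at
    zero.
    """
    if profile.background_subtracted:
        warnings.warn("profile is already background-subtracted; subtracting again")
    if method == "global-minimum":
        baseline = float(profile.intensity.min())
    elif method == "rolling-minimum":
        if window_mm <= 0:
            raise ValueError("window_mm must be > 0 for the rolling-minimum method")
        size = max(1, int(round(window_mm / profile.spacing_mm)))
        med = max(3, int(round(1.0 / profile.spacing_mm)) | 1)  # odd, ~1 mm
        prefiltered = ndimage.median_filter(profile.intensity, size=med, mode="nearest")
        baseline = ndimage.grey_opening(prefiltered, size=size, mode="nearest")
    else:
        raise ValueError(f"unknown background method {method!r}")
    cleaned = np.clip(profile.intensity - baseline, 0.0, None)
    return profile.replace(intensity=cleaned, background_subtracted=True)


def smooth_profile(profile: LaneProfile, window_fraction: float = 0.03) -> LaneProfile:
    """Smooth by convolution with a normalized Gaussian kernel.

    The kernel window (truncation length) is ``window_fraction`` of the lane
    length with sigma = window / 4, so the kernel extends to about +/-2
    sigma.  Symmetric (reflect) padding at the edges makes the convolution
    conserve the profile integral exactly.
    """
    if profile.n_samples < 10:
        raise ValueError("profile must have at least 10 samples to smooth")
    if window_fraction <= 0:
        raise ValueError("window_fraction must be > 0")
    window_mm = window_fraction * profile.length_mm
    half = int(round(window_mm / profile.spacing_mm / 2.0))
    if half < 1:
        warnings.warn("smoothing window shorter than one sample; profile returned unchanged")
        return profile.replace(smoothed=True)
    sigma = (2.0 * half) / 4.0  # in samples
    k = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(profile.intensity, half, mode="symmetric")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return profile.replace(intensity=np.clip(smoothed, 0.0, None), smoothed=True)


def detect_peaks(
    profile: LaneProfile, min_prominence_fraction: float = 0.05
) -> list[tuple[float, float]]:
    """Locate bands as local maxima with a relative prominence threshold.

    Returns ``(distance_mm, height)`` pairs sorted by distance; an empty
    list if nothing exceeds ``min_prominence_fraction`` of the profile
    maximum.  Used to find marker-ladder bands for migration calibration.
    """
    if not profile.background_subtracted:
        warnings.warn("peak detection on a profile that is not background-subtracted")
    peak_floor = float(profile.intensity.max())
    if peak_floor <= 0:
        return []
    idx, _ = signal.find_peaks(profile.intensity, prominence=min_prominence_fraction * peak_floor)
    return [(float(profile.distance_mm[i]), float(profile.intensity[i])) for i in np.sort(idx)]


def find_lanes(image: GelImage, min_width_px: int = 3) -> list[tuple[int, int]]:
    """Optional automatic lane finding by thresholding column sums.

    Columns whose summed intensity exceeds half the background-corrected
    median-to-max range are grouped into contiguous runs.  Intended as a
    convenience; lane regions are normally supplied in the run config.
    """
    colsum = image.oriented_pixels.sum(axis=0)
    lo, hi = float(np.median(colsum)), float(colsum.max())
    if hi <= lo:
        return []
    mask = colsum > lo + 0.5 * (hi - lo)
    regions: list[tuple[int, int]] = []
    start = None
    for i, on in enumerate(np.concatenate([mask, [False]])):
        if on and start is None:
            start = i
        elif not on and start is not None:
            if i - start >= min_width_px:
                regions.append((start, i))
            start = None
    return regions
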