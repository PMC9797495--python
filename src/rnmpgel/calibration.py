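"""Log-linear migration calibration: fit ``d = a + b * ln(size)`` and invert it.

The marker (size-reference) lane provides known fragment sizes at measured
migration distances.  An ordinary least-squares fit of distance on
log-size yields the per-gel coefficients ``(a, b)``; inverting the fitted
law maps any distance in the calibrated window back to a fragment size,
``size = exp((d - a) / b)``.

Because ``a`` and ``b`` are always re-fitted per gel, the base of the
logarithm is a pure reparameterization (``b`` rescales by ``ln 10`` for
base-10 input); the natural log is used throughout.  Extrapolation outside
the marker hull is off by default: log-linear migration breaks down near
the well and the dye front, so sizes outside the calibrated window are
treated as unresolvable by the gel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "MigrationCalibration",
    "MigrationCalibrator",
    "fit_migration",
    "distance_to_size",
    "read_marker_table",
]


@dataclass(frozen=True)
class MigrationCalibration:
    """Fitted coefficients of the migration law plus the valid size window.

    ``a`` is the intercept (mm), ``b`` the slope (mm per natural-log size
    unit, negative on standard gels).  ``size_min``/``size_max`` bound the
    marker hull; ``residual_rms`` is the root-mean-square distance residual.
    """

    a: float
    b: float
    size_min: float
    size_max: float
    residual_rms: float
    n_points: int

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ValueError("slope b must be nonzero")
        if not self.size_min < self.size_max:
            raise ValueError("size_min must be < size_max")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")

    @property
    def distance_range(self) -> tuple[float, float]:
        """(d_min, d_max) spanned by the calibrated size window."""
        d1 = self.a + self.b * np.log(self.size_min)
        d2 = self.a + self.b * np.log(self.size_max)
        return (min(d1, d2), max(d1, d2))

    def predict_distance(self, size):
        """Forward law ``a + b * ln(size)`` for scalar or array sizes."""
        size = np.asarray(size, dtype=float)
        d = self.a + self.b * np.log(size)
        return float(d) if d.ndim == 0 else d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MigrationCalibration":
        return cls(**json.loads(Path(path).read_text()))


class MigrationCalibrator(BaseEstimator):
    """Least-squares estimator of the log-linear migration law.

    Scikit-learn style: ``fit(sizes, distances)`` stores the fitted state in
    trailing-underscore attributes (``a_``, ``b_``, ``calibration_``);
    ``predict`` maps sizes to distances and ``inverse`` maps distances back
    to sizes within the calibrated window.

    Parameters
    ----------
    allow_extrapolation : bool
        Permit ``inverse`` outside the marker hull (default False).
    """

    def __init__(self, allow_extrapolation: bool = False):
        self.allow_extrapolation = allow_extrapolation

    def fit(self, sizes, distances) -> "MigrationCalibrator":
        sizes = np.asarray(sizes, dtype=float).ravel()
        distances = np.asarray(distances, dtype=float).ravel()
        if sizes.size != distances.size:
            raise ValueError("sizes and distances must have equal length")
        if sizes.size < 2:
            raise ValueError("at least 2 marker points are required to fit the migration law")
        if (sizes <= 0).any():
            raise ValueError("marker sizes must be positive")
        if np.unique(sizes).size != sizes.size or np.unique(distances).size != distances.size:
            raise ValueError("marker sizes and distances must be distinct")

        order = np.argsort(sizes)
        if np.any(np.diff(distances[order]) > 0) and np.any(np.diff(distances[order]) < 0):
            warnings.warn(
                "marker size/distance pairing is not monotone; fitting anyway "
                "(check peak-to-size assignment) — misfit will show in residual_rms"
            )
        log_sz = np.log(sizes)
        if sizes.size == 2:
            b = (distances[1] - distances[0]) / (log_sz[1] - log_sz[0])
            a = distances[0] - b * log_sz[0]
            resid = np.zeros(2)
        else:
            res = stats.linregress(log_sz, distances)
            a, b = float(res.intercept), float(res.slope)
            resid = distances - (a + b * log_sz)
        self.a_ = float(a)
        self.b_ = float(b)
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.size_min_ = float(sizes.min())
        self.size_max_ = float(sizes.max())
        self.n_points_ = int(sizes.size)
        self.calibration_ = MigrationCalibration(
            a=self.a_,
            b=self.b_,
            size_min=self.size_min_,
            size_max=self.size_max_,
            residual_rms=self.residual_rms_,
            n_points=self.n_points_,
        )
        return self

    def predict(self, sizes):
        """Predicted migration distance (mm) for the given sizes."""
        self._check_fitted()
        return self.calibration_.predict_distance(sizes)

    def inverse(self, distances, allow_extrapolation: bool | None = None):
        """Map migration distance(s) back to fragment size(s)."""
        self._check_fitted()
        allow = self.allow_extrapolation if allow_extrapolation is None else allow_extrapolation
        return distance_to_size(self.calibration_, distances, allow_extrapolation=allow)

    def _check_fitted(self) -> None:
        if not hasattr(self, "calibration_"):
            raise AttributeError("MigrationCalibrator is not fitted; call fit() first")


def fit_migration(marker_sizes, marker_distances) -> MigrationCalibration:
    """OLS fit of migration distance on ``ln(size)``; see :class:`MigrationCalibrator`."""
    return MigrationCalibrator().fit(marker_sizes, marker_distances).calibration_


def distance_to_size(
    calibration: MigrationCalibration,
    distance,
    allow_extrapolation: bool = False,
):
    """Invert the migration law: ``size = exp((d - a) / b)``.

    Raises a range error for distances outside the calibrated window unless
    ``allow_extrapolation`` is set; the gel cannot resolve sizes beyond the
    marker hull.
    """
    distance = np.asarray(distance, dtype=float)
    if not allow_extrapolation:
        lo, hi = calibration.distance_range
        tol = 1e-9 * max(1.0, abs(hi))
        if (distance < lo - tol).any() or (distance > hi + tol).any():
            raise ValueError(
                f"distance outside calibrated range [{lo:.4g}, {hi:.4g}] mm; "
                f"pass allow_extrapolation=True to override"
            )
    size = np.exp((distance - calibration.a) / calibration.b)
    return float(size) if size.ndim == 0 else size


def read_marker_table(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a marker CSV with columns ``size_nt`` and optionally ``distance_mm``.

    When ``distance_mm`` is absent the caller must supply distances (e.g.
    from peak detection, paired to sizes by rank order).
    """
    df = pd.read_csv(path)
    sizes = df["size_nt"].to_numpy(float)
    distances = df["distance_mm"].to_numpy(float) if "distance_mm" in df.columns else None
    return sizes, distances
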