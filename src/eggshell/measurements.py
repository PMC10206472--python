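"""Trait derivation from raw measurements.

Three eggshell traits are derived here:

* **Surface roughness S_a** (nm): a second-order polynomial reference
  surface ``z = a x^2 + b x y + c y^2 + d x + e y + f`` is fitted to the
  height map by ordinary least squares over all pixels (pixel indices as
  coordinates), correcting for the eggshell's curvature; S_a is the
  arithmetic mean absolute deviation of heights from that surface (the
  areal roughness parameter of ISO 25178).  Per-egg S_a is the mean over
  replicate scan locations.
* **Wettability** (contact angle, degrees): the contact angle of a sessile
  water droplet once it has settled (the 5 s reading), averaged over the
  left- and right-hand side of the droplet; classified as hydrophilic
  (CA < 90°), hydrophobic (90° <= CA < 150°) or superhydrophobic
  (CA >= 150°), boundaries classifying upward.
* **CaCO3 content** (% of dry mass): ash mass after furnace combustion as
  a percentage of the dried fragment mass, both net of the crucible.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import numpy as np

__all__ = [
    "HeightMap",
    "AshingMeasurement",
    "DegenerateSurfaceError",
    "compute_sa",
    "egg_mean_sa",
    "classify_wettability",
    "ca_at_settle",
    "caco3_percent",
    "read_heightmap",
    "read_ashing_csv",
    "WETTABILITY_CLASSES",
]

WETTABILITY_CLASSES = ("hydrophilic", "hydrophobic", "superhydrophobic")


class DegenerateSurfaceError(ValueError):
    """Height map cannot support a rank-6 quadratic surface fit."""


@dataclass
class HeightMap:
    """Rectangular grid of surface heights in nanometres."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2:
            raise ValueError("height map must be a 2-D grid")
        if grid.size < 6:
            raise DegenerateSurfaceError(
                "at least 6 points are required for a quadratic surface fit"
            )
        if not np.all(np.isfinite(grid)):
            raise ValueError("height map contains non-finite values")
        self.grid = grid

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def read_heightmap(path, delimiter=None) -> HeightMap:
    """Read a delimited numeric grid (one text row per pixel row)."""
    grid = np.loadtxt(path, delimiter=delimiter)
    return HeightMap(np.atleast_2d(grid))


def _quadratic_design(rows: int, cols: int) -> np.ndarray:
    # Centered/scaled pixel indices keep the normal equations well
    # conditioned; the column span (all quadratics in x, y) is unchanged.
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    x = (x - x.mean()) / max(cols - 1, 1)
    y = (y - y.mean()) / max(rows - 1, 1)
    x = x.ravel()
    y = y.ravel()
    return np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])


def compute_sa(heightmap: HeightMap | np.ndarray) -> float:
    """Areal surface roughness S_a (nm) after second-order plane correction.

    Fits the full bivariate quadratic by least squares and returns the mean
    absolute residual.  Exact quadratic surfaces therefore give S_a = 0, and
    an added quadratic trend never changes the result.

    Raises :class:`DegenerateSurfaceError` when the quadratic design is
    rank-deficient (e.g. a single pixel row).
    """
    if not isinstance(heightmap, HeightMap):
        heightmap = HeightMap(np.asarray(heightmap))
    rows, cols = heightmap.shape
    X = _quadratic_design(rows, cols)
    z = heightmap.grid.ravel()
    coef, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < 6:
        raise DegenerateSurfaceError(
            f"quadratic surface fit is rank-deficient (rank {rank} < 6); "
            f"grid shape {rows}x{cols} does not span all quadratic terms"
        )
    residuals = z - X @ coef
    return float(np.mean(np.abs(residuals)))


def egg_mean_sa(scan_values) -> float:
    """Per-egg S_a: arithmetic mean over replicate scan locations."""
    values = list(scan_values)
    if not values:
        raise ValueError("no scan values supplied")
    if any(v <= 0 for v in values):
        raise ValueError("scan S_a values must be positive")
    return fmean(values)


def classify_wettability(ca: float) -> str:
    """Wettability category of a contact angle in degrees.

    hydrophilic < 90° <= hydrophobic < 150° <= superhydrophobic.
    """
    if not (0 < ca < 180):
        raise ValueError(f"contact angle must lie in (0, 180) degrees, got {ca}")
    if ca < 90:
        return "hydrophilic"
    if ca < 150:
        return "hydrophobic"
    return "superhydrophobic"


def ca_at_settle(left_angles, right_angles, settle_second: int = 5) -> float:
    """Contact angle once the droplet has settled.

    ``left_angles``/``right_angles`` are per-second readings starting at
    1 s; the value is the mean of the left and right readings at the
    settle mark (default 5 s).  Readings before the mark are ignored.
    """
    left = list(left_angles)
    right = list(right_angles)
    if len(left) < settle_second or len(right) < settle_second:
        raise ValueError(
            f"need at least {settle_second} per-second readings on each side"
        )
    return (left[settle_second - 1] + right[settle_second - 1]) / 2.0


@dataclass
class AshingMeasurement:
    """Crucible masses (g, 4-decimal balance) from the furnace protocol."""

    crucible_mass: float
    crucible_plus_dry_mass: float
    crucible_plus_ash_mass: float

    def __post_init__(self) -> None:
        if self.crucible_plus_ash_mass < self.crucible_mass:
            raise ValueError("ash mass cannot be negative (crucible+ash < crucible)")
        if self.crucible_plus_dry_mass < self.crucible_plus_ash_mass:
            raise ValueError("ash mass cannot exceed dry mass")

    @property
    def dry_mass(self) -> float:
        return self.crucible_plus_dry_mass - self.crucible_mass

    @property
    def ash_mass(self) -> float:
        return self.crucible_plus_ash_mass - self.crucible_mass


def caco3_percent(measurement: AshingMeasurement) -> float:
    """CaCO3 content: ash mass as a percentage of fragment dry mass."""
    dry = measurement.dry_mass
    if dry <= 0:
        raise ValueError("dry mass must be positive")
    return 100.0 * measurement.ash_mass / dry


def read_ashing_csv(path):
    """CaCO3 percentages from a CSV of crucible masses.

    Columns: ``egg_id, crucible_mass, crucible_plus_dry_mass,
    crucible_plus_ash_mass`` (grams).  Returns a pandas Series of CaCO3
    percentages indexed by egg id.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = [
        "egg_id",
        "crucible_mass",
        "crucible_plus_dry_mass",
        "crucible_plus_ash_mass",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ashing CSV lacks columns: {missing}")
    values = {
        row.egg_id: caco3_percent(
            AshingMeasurement(
                row.crucible_mass,
                row.crucible_plus_dry_mass,
                row.crucible_plus_ash_mass,
            )
        )
        for row in df.itertuples()
    }
    return pd.Series(values, name="caco3_pct")
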