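"""Synthetic landscapes, nests and transect counts with known truth.

The study's field and GIS data are not public, so every downstream stage is
exercised on generated inputs whose generative truth is known: twelve
spatially correlated environmental layers rescaled into realistic ranges, a
known suitability surface, presence cells drawn from it, and per-unit
transect counts from an inhomogeneous Poisson process thinned by
half-normal detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata import EnvStack, PREDICTOR_NAMES, RasterGrid

__all__ = [
    "LandscapeConfig",
    "TruthParams",
    "generate_landscape",
    "true_suitability",
    "simulate_nests",
    "simulate_transects",
    "default_transect_units",
    "truth_population",
]

#: Observed ranges of each predictor in the study areas (min, max).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "altitude": (250.0, 1550.0),
    "slope": (0.0, 260.0),
    "tree_cover": (0.0, 99.0),
    "pine_height": (0.0, 40.0),
    "shrub_cover": (0.0, 75.0),
    "shrub_height": (0.0, 1.25),
    "radiation": (4567.0, 7515.0),
    "t_may": (17.0, 21.2),
    "t_july": (23.6, 25.9),
    "summer_rainfall": (0.0, 34.0),
    "northness": (-1.0, 1.0),
    "westness": (-1.0, 1.0),
}


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator."""

    shape: tuple[int, int] = (100, 100)
    cell_size: float = 50.0
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    correlation_length: float = 8.0  # Gaussian-smoothing sigma, in cells
    pine_cover_correlation: float = 0.6  # cross-correlation of pine height with tree cover
    altitude_coupling: float = 0.8  # |lapse coupling| of temperatures/rainfall to altitude
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {name!r} must be ordered (min < max), got ({lo}, {hi})")
        if not self.correlation_length > 0:
            raise ValueError("correlation_length must be positive")
        if not -1.0 <= self.pine_cover_correlation <= 1.0:
            raise ValueError("pine_cover_correlation must be in [-1, 1]")
        if not 0.0 <= self.altitude_coupling <= 1.0:
            raise ValueError("altitude_coupling must be in [0, 1]")


@dataclass
class TruthParams:
    """Parameters of the generative truth used by the test harness.

    The true suitability is a product of four logistic ramps on pine
    height, tree cover, altitude and summer rainfall; each ramp rises over
    ``(lo, hi)``, its logistic midpoint at the interval centre and scale
    set so the ramp covers ~98% of its rise inside the interval.
    """

    rise_pine_height: tuple[float, float] = (15.0, 20.0)
    rise_tree_cover: tuple[float, float] = (25.0, 37.0)
    rise_altitude: tuple[float, float] = (1100.0, 1280.0)
    rise_summer_rainfall: tuple[float, float] = (13.0, 20.0)
    birds_per_unit_at_suit1: float = 2.0  # expected birds per transect unit at suitability 1
    sigma_true: float = 60.0  # half-normal detection scale, metres
    #: subset of driving variables actually used by the truth (for recovery tests)
    drivers: tuple[str, ...] = ("pine_height", "tree_cover", "altitude", "summer_rainfall")

    def __post_init__(self) -> None:
        if not self.sigma_true > 0:
            raise ValueError("sigma_true must be positive")
        known = {"pine_height", "tree_cover", "altitude", "summer_rainfall"}
        unknown = set(self.drivers) - known
        if unknown:
            raise ValueError(f"unknown driver variables: {sorted(unknown)}")

    @property
    def rises(self) -> dict[str, tuple[float, float]]:
        all_rises = {
            "pine_height": self.rise_pine_height,
            "tree_cover": self.rise_tree_cover,
            "altitude": self.rise_altitude,
            "summer_rainfall": self.rise_summer_rainfall,
        }
        return {k: v for k, v in all_rises.items() if k in self.drivers}


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr_len: float) -> np.ndarray:
    """Standardized smoothed Gaussian random field."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = f.std()
    if sd == 0:  # pragma: no cover - degenerate only for 1-cell grids
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _rescale(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map a standardized field into (lo, hi) via the Gaussian CDF.

    The probit-uniform map keeps every layer's marginal distribution stable
    across realizations (min/max rescaling would tie it to the seed's
    extremes, leaving truth thresholds without support on a new landscape)
    while preserving spatial structure and rank associations.
    """
    if np.ptp(f) == 0:
        return np.full_like(f, 0.5 * (lo + hi))
    from scipy.special import ndtr

    return lo + ndtr(f) * (hi - lo)


def generate_landscape(cfg: LandscapeConfig) -> EnvStack:
    """Generate the 12-layer environmental stack.

    Altitude drives lapse-type trends: temperatures decrease and summer
    rainfall increases with altitude (plus independent smooth noise).
    Pine height and tree cover share a common component with weight
    ``cfg.pine_cover_correlation``.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.shape
    cl = cfg.correlation_length

    fields: dict[str, np.ndarray] = {}

    alt_f = _smooth_field(rng, shape, cl)
    fields["altitude"] = alt_f

    rho = cfg.pine_cover_correlation
    common = _smooth_field(rng, shape, cl)
    for name in ("pine_height", "tree_cover"):
        own = _smooth_field(rng, shape, cl)
        fields[name] = rho * common + np.sqrt(max(0.0, 1 - rho**2)) * own

    # lapse-type coupling to altitude: warm lowlands, wet highlands
    ac = cfg.altitude_coupling
    for name, sign in (("t_may", -1.0), ("t_july", -1.0), ("summer_rainfall", 1.0)):
        own = _smooth_field(rng, shape, cl)
        fields[name] = sign * ac * alt_f + np.sqrt(1 - ac**2) * own

    for name in ("slope", "radiation", "shrub_cover", "shrub_height", "northness", "westness"):
        fields[name] = _smooth_field(rng, shape, cl)

    layers = {
        name: RasterGrid(_rescale(fields[name], *cfg.ranges[name]), cfg.cell_size)
        for name in PREDICTOR_NAMES
    }
    return EnvStack(layers)


def _logistic_ramp(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Logistic rising from ~0.02 at ``lo`` to ~0.98 at ``hi``."""
    mid = 0.5 * (lo + hi)
    # logistic(k*(hi-mid)) = 0.98  =>  k = 2*ln(49)/(hi-lo)
    k = 2.0 * np.log(49.0) / (hi - lo)
    return 1.0 / (1.0 + np.exp(-k * (x - mid)))


def true_suitability(stack: EnvStack, tp: TruthParams) -> RasterGrid:
    """Known suitability surface: product of four logistic ramps.

    Monotone nondecreasing in each of the four driving variables over its
    rise interval; output in [0, 1].
    """
    terms = []
    for name, (lo, hi) in tp.rises.items():
        if name not in stack:
            raise KeyError(f"missing layer {name!r}")
        terms.append(_logistic_ramp(stack[name].values, lo, hi))
    if terms:
        suit = terms[0]
        for t in terms[1:]:
            suit = suit * t
    else:  # zero-signal world: flat suitability (null-calibration harness)
        suit = np.full(stack.shape, 0.5)
    grid = stack.grid
    return RasterGrid(suit, grid.cell_size, grid.origin, stack.combined_nodata())


def true_suitability_point(tp: TruthParams, **values: float) -> float:
    """Closed-form truth at a single point, e.g. ``pine_height=25, ...``."""
    out = 1.0
    for name, (lo, hi) in tp.rises.items():
        out *= float(_logistic_ramp(np.asarray(values[name], dtype=float), lo, hi))
    return out


def simulate_nests(suit: RasterGrid, n: int = 59, seed: int | None = None) -> pd.DataFrame:
    """Draw ``n`` distinct presence cells with probability proportional to suitability.

    Returns a DataFrame with columns row, col, x, y (cell centres).
    """
    rng = np.random.default_rng(seed)
    vals = np.where(suit.nodata_mask, 0.0, suit.values).ravel()
    vals = np.clip(vals, 0.0, None)
    support = int((vals > 0).sum())
    if support < n:
        raise ValueError(f"only {support} cells with positive suitability; cannot draw {n}")
    p = vals / vals.sum()
    idx = rng.choice(vals.size, size=n, replace=False, p=p)
    rows, cols = np.unravel_index(idx, suit.shape)
    x, y = suit.cell_center(rows, cols)
    return pd.DataFrame({"row": rows, "col": cols, "x": x, "y": y})


def default_transect_units(
    grid: RasterGrid, n_units: int = 100, unit_length: float = 229.0
) -> pd.DataFrame:
    """Centroids of ``n_units`` contiguous transect units snaking across the grid.

    The trail is laid out on horizontal lines spaced across the grid
    interior, mimicking a fixed 22.9 km network of field trails.
    """
    nrows, ncols = grid.shape
    width = ncols * grid.cell_size
    height = nrows * grid.cell_size
    per_line = max(1, int(width // unit_length))
    n_lines = int(np.ceil(n_units / per_line))
    ys = np.linspace(0.15, 0.85, n_lines) * height + grid.origin[1]
    units = []
    uid = 0
    for line, y in enumerate(ys):
        for j in range(per_line):
            if uid >= n_units:
                break
            x = grid.origin[0] + (j + 0.5) * unit_length
            units.append((uid, x, y))
            uid += 1
    if uid < n_units:
        raise ValueError(f"grid too small to place {n_units} units of {unit_length} m")
    return pd.DataFrame(units, columns=["unit_id", "x", "y"])


def _unit_suitability(suit: RasterGrid, units: pd.DataFrame) -> np.ndarray:
    rows, cols = suit.cell_at(units["x"].to_numpy(), units["y"].to_numpy())
    nrows, ncols = suit.shape
    if ((rows < 0) | (rows >= nrows) | (cols < 0) | (cols >= ncols)).any():
        raise ValueError("transect units fall outside the grid")
    return np.clip(suit.values[rows, cols], 0.0, 1.0)


def simulate_transects(
    suit: RasterGrid,
    units: pd.DataFrame,
    tp: TruthParams,
    seed: int | None = None,
    n_years: int = 1,
    w_max: float = 125.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate detected birds along transect units.

    Birds arise per unit and replicate "year" from a Poisson process with
    mean ``birds_per_unit_at_suit1 * suitability(unit)``; each bird sits at
    a perpendicular distance uniform on [0, w_max] and is detected with
    probability ``exp(-d^2 / (2 sigma_true^2))``.

    Returns ``(counts, detections)``: per-unit-per-year detected counts and
    the table of detected perpendicular distances.
    """
    rng = np.random.default_rng(seed)
    unit_suit = _unit_suitability(suit, units)
    lam = tp.birds_per_unit_at_suit1 * unit_suit

    count_rows = []
    det_rows = []
    for year in range(n_years):
        n_birds = rng.poisson(lam)
        for uid, k in zip(units["unit_id"].to_numpy(), n_birds):
            detected = 0
            if k > 0:
                d = rng.uniform(0.0, w_max, size=k)
                keep = rng.random(k) < np.exp(-(d**2) / (2.0 * tp.sigma_true**2))
                detected = int(keep.sum())
                for dist in d[keep]:
                    det_rows.append((uid, year, dist))
            count_rows.append((uid, year, detected))
    counts = pd.DataFrame(count_rows, columns=["unit_id", "year", "count"])
    detections = pd.DataFrame(det_rows, columns=["unit_id", "year", "distance_m"])
    return counts, detections


def truth_population(suit200: RasterGrid, tp: TruthParams) -> float:
    """True expected population on the 200 m grid, in transect-unit-equivalent cells.

    Defined on the same per-cell-equivalent scale the estimator uses (one
    200 m cell holds birds like one transect unit), so end-to-end recovery
    is well-posed.
    """
    vals = np.clip(suit200.valid_values(), 0.0, 1.0)
    return float(tp.birds_per_unit_at_suit1 * vals.sum())
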