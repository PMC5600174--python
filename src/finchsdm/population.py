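"""Detectability-corrected population estimate with a bootstrap percentile CI."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geodata import RasterGrid, aggregate_mean

__all__ = [
    "PopulationEstimate",
    "cells_200m",
    "expected_birds",
    "correct_detectability",
    "estimate_population",
    "mean_density",
]

logger = logging.getLogger(__name__)


@dataclass
class PopulationEstimate:
    """Total expected birds with a bootstrap percentile confidence interval."""

    total: float
    ci_low: float
    ci_high: float
    per_cell: np.ndarray
    bootstrap_sums: np.ndarray
    pdet: float | None = None
    intercept: float | None = None
    slope: float | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.total + 1e-9 and self.total <= self.ci_high + 1e-9):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket the estimate {self.total}"
            )


def cells_200m(map50: RasterGrid, factor: int = 4) -> RasterGrid:
    """Aggregate a 50 m suitability map to 200 m cells (block means of 16 cells)."""
    return aggregate_mean(map50, factor)


def expected_birds(
    suit200: RasterGrid, intercept: float, slope: float, area_scale: float = 1.0
) -> np.ndarray:
    """Per-cell expected birds from the suitability-count regression.

    E_cell = max(0, intercept + slope * suitability) * area_scale over
    non-nodata cells; negative linear predictions are clamped to zero
    (count logged).
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    vals = suit200.valid_values()
    linear = intercept + slope * vals
    n_clamped = int((linear < 0).sum())
    if n_clamped:
        logger.info("expected_birds: clamped %d negative cell predictions to 0", n_clamped)
    return np.clip(linear, 0.0, None) * area_scale


def correct_detectability(E: np.ndarray, pdet: float) -> np.ndarray:
    """Divide expected counts by the detection probability."""
    if not 0.0 < pdet <= 1.0:
        raise ValueError(f"pdet must lie in (0, 1], got {pdet}")
    return np.asarray(E, dtype=float) / pdet


def estimate_population(
    per_cell: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    pdet: float | None = None,
    intercept: float | None = None,
    slope: float | None = None,
) -> PopulationEstimate:
    """Sum per-cell expectations; CI from resampling cells with replacement.

    The point estimate is the plain sum; each bootstrap draw resamples the
    cells (same count), sums, and the CI is the empirical 2.5/97.5
    percentile of the ``n_boot`` sums.
    """
    per_cell = np.asarray(per_cell, dtype=float)
    if per_cell.size < 2:
        raise ValueError("need at least 2 cells")
    total = float(per_cell.sum())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, per_cell.size, size=(n_boot, per_cell.size))
    sums = per_cell[idx].sum(axis=1)
    lo, hi = np.percentile(sums, [2.5, 97.5])
    # a zero-variance resample distribution degenerates to the point estimate
    lo = min(lo, total)
    hi = max(hi, total)
    return PopulationEstimate(total, float(lo), float(hi), per_cell, sums,
                              pdet=pdet, intercept=intercept, slope=slope)


def mean_density(total_birds: float, area_km2: float) -> float:
    """Average density (birds/km^2) implied by a total count over an area."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    return total_birds / area_km2
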