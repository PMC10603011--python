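"""Bound curves over the feasible interval and curve-coincidence checks.

Tabulating H_min and H_max over a grid of p_i values produces the
characteristic lens-shaped regions of attainable (p_i, H) pairs.  Several
of those regions touch along whole curves rather than isolated points:

* for any n >= 3, the upper bound conditional on p_{n-1} coincides with
  the lower bound conditional on p_1 on [1/n, 1/(n-1)] — both reduce to
  (n-1) h(p) + h(1-(n-1)p);
* for n = 3, the upper bound conditional on p_2 coincides with the lower
  bound conditional on p_3 on [0, 1/3] and with the lower bound
  conditional on p_1 on [1/3, 1/2] — all reduce to h(1-2p) + 2 h(p).

These identities are verified numerically on dense grids (the closed
forms make exact-grid agreement to ~1e-15 the expected outcome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bounds import (
    BoundQuery,
    entropy_lower_bound,
    entropy_upper_bound,
    feasible_interval,
)

__all__ = [
    "BoundCurve",
    "OverlapReport",
    "bound_curve",
    "check_curve_identity",
    "interval_at_zero",
]

DEFAULT_RESOLUTION = 512


@dataclass(frozen=True)
class BoundCurve:
    """H_min / H_max tabulated over the feasible p_i interval.

    The grid is strictly increasing, covers the whole feasible interval,
    and contains every reciprocal breakpoint 1/k inside it, so the
    piecewise structure of the i = 1 lower bound is sampled exactly at
    its kinks.
    """

    i: int
    n: int
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns i, n, p_i, H_min, H_max."""
        return pd.DataFrame({
            "i": self.i, "n": self.n, "p_i": self.grid,
            "H_min": self.lower, "H_max": self.upper,
        })


@dataclass(frozen=True)
class OverlapReport:
    """Outcome of testing a claimed coincidence between two bound curves.

    ``kind`` is "point" (single shared point), "curve" (coincidence along
    an interval) or "region" (two-dimensional overlap); ``witness`` holds
    representative (p, H) pairs and ``max_identity_gap`` the largest
    absolute difference found for a curve coincidence.
    """

    i1: int
    i2: int
    n: int
    kind: str
    witness: tuple[tuple[float, float], ...]
    max_identity_gap: float | None = None


def _grid_with_breakpoints(lo: float, hi: float, n: int,
                           resolution: int) -> np.ndarray:
    base = np.linspace(lo, hi, resolution)
    # reciprocal breakpoints 1/k: kinks of the i=1 lower bound and the
    # branch split of the i>=2 upper bound; 1/k <= 1/n is never interior
    ks = np.array([1.0 / k for k in range(2, n + 1) if lo < 1.0 / k < hi])
    return np.unique(np.concatenate((base, ks)))


def bound_curve(i: int, n: int, resolution: int = DEFAULT_RESOLUTION) -> BoundCurve:
    """Tabulate both bounds on a grid spanning the feasible p_i interval."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    iv = feasible_interval(i, n)
    grid = _grid_with_breakpoints(iv.lo, iv.hi, n, resolution)
    lower = np.empty(grid.size)
    upper = np.empty(grid.size)
    for j, p in enumerate(grid):
        q = BoundQuery(i=i, p_i=float(p), n=n)
        if i == 1 and q.p_i <= 0.0:
            lower[j] = 0.0
        else:
            lower[j] = entropy_lower_bound(q)
        upper[j] = entropy_upper_bound(q)
    return BoundCurve(i=i, n=n, grid=grid, lower=lower, upper=upper)


def _gap_on_interval(n: int, i_upper: int, i_lower: int,
                     lo: float, hi: float, grid_size: int) -> tuple[float, list]:
    grid = np.linspace(lo, hi, grid_size)
    worst = 0.0
    witness = []
    for p in grid:
        up = entropy_upper_bound(BoundQuery(i=i_upper, p_i=float(p), n=n))
        low = entropy_lower_bound(BoundQuery(i=i_lower, p_i=float(p), n=n))
        worst = max(worst, abs(up - low))
    for p in (lo, 0.5 * (lo + hi), hi):
        h = entropy_upper_bound(BoundQuery(i=i_upper, p_i=float(p), n=n))
        witness.append((float(p), h))
    return worst, witness


def check_curve_identity(n: int, grid_size: int = 1000) -> list[OverlapReport]:
    """Verify the known curve coincidences for richness n numerically.

    Always checks upper(p_{n-1}) == lower(p_1) on [1/n, 1/(n-1)]; for
    n = 3 additionally upper(p_2) == lower(p_3) on [0, 1/3].  (The n = 3
    coincidence of upper(p_2) with lower(p_1) on [1/3, 1/2] is the
    general check with n-1 = 2.)
    """
    if n < 3:
        raise ValueError("curve coincidences require n >= 3")
    reports = []
    gap, wit = _gap_on_interval(n, n - 1, 1, 1.0 / n, 1.0 / (n - 1), grid_size)
    reports.append(OverlapReport(i1=n - 1, i2=1, n=n, kind="curve",
                                 witness=tuple(wit), max_identity_gap=gap))
    if n == 3:
        gap, wit = _gap_on_interval(3, 2, 3, 0.0, 1.0 / 3.0, grid_size)
        reports.append(OverlapReport(i1=2, i2=3, n=3, kind="curve",
                                     witness=tuple(wit), max_identity_gap=gap))
    return reports


def interval_at_zero(i: int, n: int) -> tuple[float, float]:
    """Attainable entropy interval when the rank-i abundance is exactly 0.

    For i >= 2, p_i = 0 means at most i-1 taxa are present, so H ranges
    over [0, ln(i-1)].  p_1 = 0 is infeasible.
    """
    if i == 1:
        raise ValueError("p_1 = 0 is infeasible (largest entry >= 1/n)")
    if not 2 <= i <= n:
        raise ValueError(f"rank i={i} outside [2, n={n}]")
    return 0.0, math.log(i - 1)
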