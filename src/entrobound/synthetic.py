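"""Synthetic communities and the brute-force grid oracle.

Two roles.  First, generators for abundance profiles spanning the
feasible (p_i, H) region — near-uniform Dirichlet draws, geometric
rank-abundance series, and single-dominant communities — plus the small
worked-example fixtures used throughout the documentation.  Second, an
exhaustive oracle that enumerates every discretized abundance vector
(all compositions of a grid denominator m into n non-negative parts)
with a prescribed rank-i entry, against which the closed-form bounds can
be verified on small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .core import AbundanceVector

__all__ = [
    "CommunitySpec",
    "GridOracleResult",
    "FIXTURES",
    "make_fixture",
    "sample_communities",
    "communities_to_table",
    "grid_oracle",
    "oracle_extrema_table",
]

#: Worked-example communities: A and B are ten-taxon communities with
#: nearly identical entropy (~0.75 nats) but opposite structure; "red"
#: (= uniform3) is the perfectly even three-taxon community with
#: H = ln 3, pinned to a single point by p_3 = 1/3.
FIXTURES = {
    "communityA": (0.5, 0.492) + (0.001,) * 8,
    "communityB": (0.85,) + (1.0 / 60.0,) * 9,
    "uniform3": (1 / 3, 1 / 3, 1 / 3),
    "red": (1 / 3, 1 / 3, 1 / 3),
}


@dataclass(frozen=True)
class CommunitySpec:
    """Recipe for random communities.

    kind: "fixture", "dirichlet", "geometric" or "dominant".  params are
    kind-specific: fixture {name}; dirichlet {concentration} (symmetric
    Dirichlet, default 1.0); geometric {ratio} (normalized ratio**k
    series); dominant {mass, concentration} (taxon 1 gets mass, the rest
    is Dirichlet-split; concentration None splits evenly).
    """

    kind: str
    n: int
    params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class GridOracleResult:
    """Extremal entropies over all on-grid vectors with rank-i entry p_i.

    ``feasible`` is False (and the extrema None) when no composition of
    m into n parts has i-th largest part equal to round(p_i * m).
    """

    i: int
    p_i: float
    n: int
    m: int
    feasible: bool
    oracle_max: float | None
    oracle_min: float | None
    argmax: AbundanceVector | None
    argmin: AbundanceVector | None


def make_fixture(name: str) -> AbundanceVector:
    """Return a named worked-example community."""
    try:
        return AbundanceVector(FIXTURES[name])
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(FIXTURES)}") from None


def sample_communities(spec: CommunitySpec, count: int) -> list[AbundanceVector]:
    """Generate ``count`` communities according to ``spec`` (reproducible
    for a fixed seed; a fresh generator is created per call)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if spec.n < 1:
        raise ValueError("richness n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    kind = spec.kind
    if kind == "fixture":
        return [make_fixture(spec.params["name"]) for _ in range(count)]
    if kind == "dirichlet":
        conc = float(spec.params.get("concentration", 1.0))
        if conc <= 0:
            raise ValueError("concentration must be positive")
        draws = rng.dirichlet(np.full(spec.n, conc), size=count)
        return [AbundanceVector(row, renormalize=True) for row in draws]
    if kind == "geometric":
        ratio = float(spec.params.get("ratio", 0.5))
        if not 0 < ratio <= 1:
            raise ValueError("ratio must be in (0, 1]")
        weights = ratio ** np.arange(spec.n)
        vec = AbundanceVector(weights / weights.sum())
        return [vec] * count
    if kind == "dominant":
        mass = float(spec.params.get("mass", 0.85))
        if not 0 < mass < 1:
            raise ValueError("dominant mass must be in (0, 1)")
        if spec.n < 2:
            raise ValueError("dominant profile needs n >= 2")
        conc = spec.params.get("concentration")
        out = []
        for _ in range(count):
            if conc is None:
                rest = np.full(spec.n - 1, (1.0 - mass) / (spec.n - 1))
            else:
                rest = (1.0 - mass) * rng.dirichlet(
                    np.full(spec.n - 1, float(conc)))
            out.append(AbundanceVector(np.concatenate(([mass], rest)),
                                       renormalize=True))
        return out
    raise ValueError(f"unknown community kind {kind!r}")


def communities_to_table(communities: list[AbundanceVector]) -> pd.DataFrame:
    """Stack communities into a taxa-by-samples abundance table."""
    n = max(c.n for c in communities)
    data = {f"sample_{j + 1}": np.pad(c.values, (0, n - c.n))
            for j, c in enumerate(communities)}
    return pd.DataFrame(data, index=[f"taxon_{k + 1}" for k in range(n)])


def _partitions_at_most(total: int, parts: int, cap: int):
    """Non-increasing sequences of `parts` non-negative integers with the
    given total, largest part <= cap."""
    if parts == 0:
        if total == 0:
            yield ()
        return
    if total > parts * cap:
        return
    lo = -(-total // parts)  # ceil: largest part at least the mean
    for first in range(min(cap, total), lo - 1, -1):
        for rest in _partitions_at_most(total - first, parts - 1, first):
            yield (first,) + rest


@lru_cache(maxsize=32)
def _enumerated(n: int, m: int) -> tuple[tuple[tuple[int, ...], float], ...]:
    # entropy from integer parts: H = ln m - (1/m) * sum c*ln c
    logs = np.zeros(m + 1)
    cs = np.arange(1, m + 1)
    logs[1:] = cs * np.log(cs)
    out = []
    for parts in _partitions_at_most(m, n, m):
        h = math.log(m) - sum(logs[c] for c in parts) / m
        out.append((parts, h))
    return tuple(out)


def grid_oracle(i: int, p_i: float, n: int, m: int) -> GridOracleResult:
    """Exhaustively search all m-denominator compositions of length n whose
    i-th largest part equals round(p_i * m), returning extremal entropies
    and witnesses.  Limited to small instances (n <= 8, m <= 120)."""
    if n > 8 or m > 120:
        raise ValueError("grid oracle limited to n <= 8, m <= 120")
    if not 1 <= i <= n:
        raise ValueError(f"rank i={i} outside [1, {n}]")
    c = round(p_i * m)
    if abs(p_i * m - c) > 1e-9 * m:
        raise ValueError(f"p_i={p_i} is not a multiple of 1/{m}")
    best_max = best_min = None
    arg_max = arg_min = None
    for parts, h in _enumerated(n, m):
        if parts[i - 1] != c:
            continue
        if best_max is None or h > best_max:
            best_max, arg_max = h, parts
        if best_min is None or h < best_min:
            best_min, arg_min = h, parts
    if best_max is None:
        return GridOracleResult(i=i, p_i=c / m, n=n, m=m, feasible=False,
                                oracle_max=None, oracle_min=None,
                                argmax=None, argmin=None)
    to_vec = lambda parts: AbundanceVector(np.asarray(parts, dtype=float) / m)
    return GridOracleResult(i=i, p_i=c / m, n=n, m=m, feasible=True,
                            oracle_max=best_max, oracle_min=best_min,
                            argmax=to_vec(arg_max), argmin=to_vec(arg_min))


def oracle_extrema_table(n: int, m: int) -> dict[tuple[int, int], tuple[float, float]]:
    """One pass over all length-n compositions of m, bucketing extremal
    entropies by (rank i, integer part c).  Returns
    {(i, c): (oracle_min, oracle_max)} for every feasible pair —
    the bulk interface behind sweeping verification runs."""
    if n > 8 or m > 120:
        raise ValueError("grid oracle limited to n <= 8, m <= 120")
    table: dict[tuple[int, int], tuple[float, float]] = {}
    for parts, h in _enumerated(n, m):
        for idx, c in enumerate(parts, start=1):
            key = (idx, c)
            cur = table.get(key)
            if cur is None:
                table[key] = (h, h)
            else:
                lo, hi = cur
                table[key] = (min(lo, h), max(hi, h))
    return table
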