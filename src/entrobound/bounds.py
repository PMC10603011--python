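"""Exact entropy bounds conditional on the i-th largest abundance.

Fix the abundance p_i of the i-th most abundant taxon in a community of
n taxa.  Among all relative-abundance vectors consistent with that
constraint, Shannon entropy is maximised by spreading the unconstrained
mass as evenly as possible and minimised by concentrating it on as few
taxa as possible.  Both extremes have closed forms.

For i = 1 (feasible p_1 in [1/n, 1]):

    H_max(p_1, n) = h(p_1) + (n-1) h((1-p_1)/(n-1)),
        attained by p* = (p_1, (1-p_1)/(n-1), ..., (1-p_1)/(n-1));
    H_min(p_1)    = (ceil(1/p_1)-1) h(p_1) + h(1 - (ceil(1/p_1)-1) p_1),
        attained by p** = (p_1, ..., p_1, remainder, 0, ..., 0)
        with ceil(1/p_1)-1 copies of p_1.

For i >= 2 (feasible p_i in [0, 1/i]):

    H_max(p_i, n) = i h(p_i) + (n-i) h((1-i p_i)/(n-i))            if p_i >= 1/n,
                    (i-1) h((1-(n-i+1)p_i)/(i-1)) + (n-i+1) h(p_i) if p_i <  1/n;
    H_min(p_i)    = h(1-(i-1)p_i) + (i-1) h(p_i),
        attained by (1-(i-1)p_i, p_i, ..., p_i, 0, ..., 0).

The lower bound does not depend on n.  h is the single-term entropy
-x ln x.  All values are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import AbundanceVector, term_entropy

__all__ = [
    "BoundQuery",
    "BoundResult",
    "FeasibleInterval",
    "InfeasibleQueryError",
    "feasible_interval",
    "max_entropy_vector",
    "min_entropy_vector",
    "entropy_upper_bound",
    "entropy_lower_bound",
    "bounds",
]

#: Queries violating feasibility by at most this much are clamped to the
#: boundary (renormalized data routinely lands epsilon outside).
FEASIBILITY_TOLERANCE = 1e-9
#: 1/p_1 within this of an integer is snapped before the ceiling, so
#: p_1 = 0.2 stored in floating point yields ceil(1/p_1) = 5, not 6.
CEIL_SNAP = 1e-9


class InfeasibleQueryError(ValueError):
    """The pair (i, p_i) is not achievable by any length-n abundance vector."""


@dataclass(frozen=True)
class FeasibleInterval:
    """Closed interval of achievable p_i values for rank i and richness n."""

    lo: float
    hi: float


@dataclass(frozen=True)
class BoundQuery:
    """A conditional-bound request: rank ``i``, fixed abundance ``p_i``,
    richness ``n``.

    Feasibility (``p_i <= 1/i``, and ``p_i >= 1/n`` when i = 1) is checked
    at construction; violations within 1e-9 are clamped to the boundary.
    """

    i: int
    p_i: float
    n: int

    def __post_init__(self):
        if self.n < 1 or self.i < 1 or self.i > self.n:
            raise InfeasibleQueryError(
                f"rank i={self.i} outside [1, n={self.n}]")
        iv = feasible_interval(self.i, self.n)
        p = float(self.p_i)
        if p < iv.lo:
            if p < iv.lo - FEASIBILITY_TOLERANCE:
                raise InfeasibleQueryError(
                    f"p_{self.i}={p!r} below feasible interval "
                    f"[{iv.lo}, {iv.hi}] for n={self.n}")
            p = iv.lo
        elif p > iv.hi:
            if p > iv.hi + FEASIBILITY_TOLERANCE:
                raise InfeasibleQueryError(
                    f"p_{self.i}={p!r} above feasible interval "
                    f"[{iv.lo}, {iv.hi}] for n={self.n}")
            p = iv.hi
        object.__setattr__(self, "p_i", p)


@dataclass(frozen=True)
class BoundResult:
    """Both bounds plus the extremal vectors attaining them.

    ``branch`` records which construction applied ("i=1", "p_i >= 1/n" or
    "p_i < 1/n"); ``k_copies`` is the number of entries of the relevant
    extremal vector pinned to p_i (ceil(1/p_1)-1 copies in the minimising
    vector for i = 1; i or n-i+1 copies in the maximising vector for
    i >= 2, depending on branch).
    """

    h_min: float
    h_max: float
    argmax: AbundanceVector
    argmin: AbundanceVector
    branch: str
    k_copies: int


def feasible_interval(i: int, n: int) -> FeasibleInterval:
    """Range of values the i-th largest of n entries summing to 1 can take.

    The rank-i entry cannot exceed 1/i (there are i entries at least as
    large); the largest entry cannot be below the mean 1/n.
    """
    if n < 1 or i < 1 or i > n:
        raise InfeasibleQueryError(f"rank i={i} outside [1, n={n}]")
    if i == 1:
        return FeasibleInterval(lo=1.0 / n, hi=1.0)
    return FeasibleInterval(lo=0.0, hi=1.0 / i)


def _h(x: float) -> float:
    # closed-form remainders like 1 - i*p_i can land epsilon outside [0,1]
    if -FEASIBILITY_TOLERANCE <= x < 0.0:
        x = 0.0
    elif 1.0 < x <= 1.0 + FEASIBILITY_TOLERANCE:
        x = 1.0
    return term_entropy(x)


def _snapped_ceil_reciprocal(p1: float) -> int:
    """ceil(1/p_1), snapping 1/p_1 to the nearest integer within 1e-9."""
    r = 1.0 / p1
    nearest = round(r)
    if abs(r - nearest) <= CEIL_SNAP * max(1.0, abs(r)):
        return int(nearest)
    return int(math.ceil(r))


def _coerce(q: BoundQuery | tuple) -> BoundQuery:
    if isinstance(q, BoundQuery):
        return q
    return BoundQuery(*q)


def _vector(entries: np.ndarray) -> AbundanceVector:
    # extremal constructions sum to 1 up to rounding; renormalize absorbs it
    return AbundanceVector(np.clip(entries, 0.0, None), renormalize=True)


def max_entropy_vector(q: BoundQuery | tuple) -> AbundanceVector:
    """The abundance vector with greatest entropy given (i, p_i, n).

    For i = 1 the remaining mass is spread evenly over the other n-1 taxa.
    For i >= 2 either the top i entries are pinned at p_i and the rest
    share the remainder evenly (p_i >= 1/n), or the bottom n-i+1 entries
    are pinned at p_i and the top i-1 share the remainder (p_i < 1/n).
    """
    q = _coerce(q)
    i, p, n = q.i, q.p_i, q.n
    if i == 1:
        if n == 1:
            return _vector(np.array([1.0]))
        rest = (1.0 - p) / (n - 1)
        return _vector(np.concatenate(([p], np.full(n - 1, rest))))
    if p >= 1.0 / n:
        out = np.full(n, p)
        if n > i:
            out[i:] = (1.0 - i * p) / (n - i)
        return _vector(out)
    head = (1.0 - (n - i + 1) * p) / (i - 1)
    return _vector(np.concatenate((np.full(i - 1, head), np.full(n - i + 1, p))))


def min_entropy_vector(q: BoundQuery | tuple) -> AbundanceVector:
    """The abundance vector with least entropy given (i, p_i, n).

    For i = 1 the mass is packed into as few taxa as possible:
    ceil(1/p_1)-1 copies of p_1, one remainder entry, zeros.  For i >= 2
    ranks 2..i are pinned at p_i and everything else goes to the top taxon.
    """
    q = _coerce(q)
    i, p, n = q.i, q.p_i, q.n
    if i == 1:
        if p <= 0.0:
            raise InfeasibleQueryError("p_1 must be positive")
        k = _snapped_ceil_reciprocal(p) - 1
        remainder = max(1.0 - k * p, 0.0)
        out = np.zeros(n)
        out[:k] = p
        out[k] = remainder
        return _vector(out)
    out = np.zeros(n)
    out[0] = 1.0 - (i - 1) * p
    out[1:i] = p
    return _vector(out)


def entropy_upper_bound(q: BoundQuery | tuple) -> float:
    """Largest Shannon entropy (nats) achievable given (i, p_i, n)."""
    q = _coerce(q)
    i, p, n = q.i, q.p_i, q.n
    if i == 1:
        if n == 1:
            return 0.0
        return _h(p) + (n - 1) * _h((1.0 - p) / (n - 1))
    if p >= 1.0 / n:
        tail = 0.0 if n == i else (n - i) * _h((1.0 - i * p) / (n - i))
        return i * _h(p) + tail
    head = (1.0 - (n - i + 1) * p) / (i - 1)
    return (i - 1) * _h(head) + (n - i + 1) * _h(p)


def entropy_lower_bound(q: BoundQuery | tuple) -> float:
    """Smallest Shannon entropy (nats) achievable given (i, p_i, n).

    Independent of n for fixed (i, p_i): n only pads the minimising
    vector with zero entries.
    """
    q = _coerce(q)
    i, p = q.i, q.p_i
    if i == 1:
        if p <= 0.0:
            raise InfeasibleQueryError("p_1 must be positive")
        k = _snapped_ceil_reciprocal(p) - 1
        return k * _h(p) + _h(
            min(max(1.0 - k * p, 0.0), 1.0))
    return _h(1.0 - (i - 1) * p) + (i - 1) * _h(p)


def bounds(q: BoundQuery | tuple) -> BoundResult:
    """Bundle both bounds with their extremal vectors for one query."""
    q = _coerce(q)
    h_max = entropy_upper_bound(q)
    h_min = entropy_lower_bound(q)
    argmax = max_entropy_vector(q)
    argmin = min_entropy_vector(q)
    if q.i == 1:
        branch = "i=1"
        k_copies = _snapped_ceil_reciprocal(q.p_i) - 1
    elif q.p_i >= 1.0 / q.n:
        branch = "p_i >= 1/n"
        k_copies = q.i
    else:
        branch = "p_i < 1/n"
        k_copies = q.n - q.i + 1
    return BoundResult(h_min=h_min, h_max=h_max, argmax=argmax,
                       argmin=argmin, branch=branch, k_copies=k_copies)
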