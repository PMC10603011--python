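"""Relative-abundance vectors and Shannon entropy.

A community is represented by a relative-abundance vector
``p = (p_1, ..., p_n)``: non-negative fractions summing to 1, each the
share of the community belonging to one taxon.  Shannon entropy

    H(p) = -sum_i p_i ln p_i

is measured in nats (natural logarithm) with the usual convention
``-0 ln 0 = 0``.  H ranges from 0 (a single taxon holds everything) to
``ln n`` (all n taxa equally abundant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AbundanceVector",
    "RankedAbundance",
    "ValidationError",
    "term_entropy",
    "shannon_entropy",
    "rank_abundances",
    "ith_abundance",
]

#: Default tolerance on |sum(p) - 1|.
SUM_TOLERANCE = 1e-8
#: Looser tolerance inside which ``renormalize=True`` silently rescales.
RENORMALIZE_TOLERANCE = 1e-3
#: Negative entries no larger than this in magnitude are treated as
#: floating-point dust and clamped to 0.
NEGATIVE_CLAMP = 1e-12


class ValidationError(ValueError):
    """An abundance vector violates one of its invariants."""


@dataclass(frozen=True)
class AbundanceVector:
    """A validated relative-abundance vector.

    Parameters
    ----------
    values
        Non-negative fractions.  Entries more negative than -1e-12 are
        rejected; smaller negative dust is clamped to 0.
    renormalize
        If True, a vector whose sum is within 1e-3 of 1 is divided by its
        sum instead of being rejected.  Raw count tables should go through
        :mod:`entrobound.io` rather than this flag.
    tol
        Tolerance on ``|sum - 1|`` when not renormalizing.
    """

    values: np.ndarray
    n: int = field(init=False)

    def __init__(self, values: Sequence[float] | np.ndarray,
                 *, renormalize: bool = False, tol: float = SUM_TOLERANCE):
        arr = np.asarray(values, dtype=float).reshape(-1).copy()
        if arr.size < 1:
            raise ValidationError("abundance vector must have n >= 1 entries")
        neg = arr < 0
        if neg.any():
            worst = arr[neg].min()
            if worst < -NEGATIVE_CLAMP:
                raise ValidationError(
                    f"negative abundance {worst!r} (entries must be >= 0)")
            arr[neg] = 0.0
        total = arr.sum()
        if abs(total - 1.0) > tol:
            if renormalize and abs(total - 1.0) <= RENORMALIZE_TOLERANCE:
                arr = arr / total
            else:
                raise ValidationError(
                    f"abundances sum to {total!r}, not 1 (tolerance {tol})")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "n", int(arr.size))

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        """Return the underlying (read-only) numpy array."""
        return self.values


@dataclass(frozen=True)
class RankedAbundance:
    """Abundances sorted in non-increasing order, plus the rank permutation.

    ``rank_of[j]`` is the 1-based rank of original entry ``j``; ties keep
    input order (stable sort), so the permutation is well-defined.
    """

    sorted_values: np.ndarray
    rank_of: np.ndarray


def term_entropy(x: float) -> float:
    """Single-taxon entropy contribution ``h(x) = -x ln x`` in nats.

    Defined as 0 at both x = 0 and x = 1.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"abundance {x!r} outside [0, 1]")
    if x == 0.0 or x == 1.0:
        return 0.0
    return float(-x * np.log(x))


def _entropy_of_array(arr: np.ndarray) -> float:
    pos = arr[arr > 0]
    return float(-(pos * np.log(pos)).sum())


def shannon_entropy(p: AbundanceVector | Sequence[float]) -> float:
    """Shannon entropy ``H(p) = -sum p_i ln p_i`` in nats.

    Zero entries contribute 0.  The result lies in ``[0, ln n]``.
    """
    if not isinstance(p, AbundanceVector):
        p = AbundanceVector(p)
    return _entropy_of_array(p.values)


def rank_abundances(p: AbundanceVector | Sequence[float]) -> RankedAbundance:
    """Sort abundances in non-increasing order (stable among ties)."""
    if not isinstance(p, AbundanceVector):
        p = AbundanceVector(p)
    # stable argsort of the negated values keeps input order among ties
    order = np.argsort(-p.values, kind="stable")
    rank_of = np.empty(p.n, dtype=int)
    rank_of[order] = np.arange(1, p.n + 1)
    sorted_values = p.values[order].copy()
    sorted_values.flags.writeable = False
    return RankedAbundance(sorted_values=sorted_values, rank_of=rank_of)


def ith_abundance(p: AbundanceVector | Sequence[float], i: int) -> float:
    """Abundance of the i-th most abundant taxon (1-based rank).

    Always satisfies ``p_i <= 1/i``; for i = 1 also ``p_1 >= 1/n``.
    """
    if not isinstance(p, AbundanceVector):
        p = AbundanceVector(p)
    if not 1 <= i <= p.n:
        raise IndexError(f"rank i={i} outside [1, {p.n}]")
    return float(rank_abundances(p).sorted_values[i - 1])
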