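"""Bounds-based normalized Shannon entropy and richness harmonization.

The normalized entropy places a community's H within the exact interval
allowed by its rank-i abundance:

    H_norm(p, n; i) = (H(p) - H_min(p_i)) / (H_max(p_i, n) - H_min(p_i)),

so 0 means "as uneven as the constraint allows" and 1 "as even as it
allows".  When p_i = 1/i the two bounds coincide (the vector is fully
determined, e.g. (1/3, 1/3, 1/3) at i = 3) and the ratio is undefined;
such communities are flagged as degenerate rather than silently dropped,
so the exclusion happens explicitly at aggregation time.

The richness n used for the bounds is a policy choice, because real
cohorts mix three conventions: each sample's own count of positive taxa,
the literal vector length (zero-count taxa included), or one fixed
cohort-wide N (samples richer than N are truncated to their N most
abundant taxa and renormalized first).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bounds import BoundQuery, entropy_lower_bound, entropy_upper_bound
from .core import AbundanceVector, rank_abundances, shannon_entropy

__all__ = [
    "NormalizedEntropy",
    "normalized_entropy",
    "truncate_renormalize",
    "resolve_n_policy",
]

#: |H_max - H_min| below this marks the query degenerate.
DEGENERACY_TOLERANCE = 1e-12


@dataclass(frozen=True)
class NormalizedEntropy:
    """Result of a bounds-based normalization.

    ``value`` is None exactly when ``degenerate`` is set (coinciding
    bounds); otherwise it lies in [0, 1].  ``i_used`` and ``n_used``
    record the query the bounds were computed for.
    """

    value: float | None
    degenerate: bool
    i_used: int
    n_used: int


def resolve_n_policy(n_policy: str | int) -> tuple[str, int | None]:
    """Parse a richness policy into (kind, fixed_n).

    Accepted: "nonzero" (default elsewhere), "length" / "vector-length",
    "fixed:<N>", or a bare integer (treated as fixed).
    """
    if isinstance(n_policy, int):
        return "fixed", n_policy
    policy = n_policy.strip().lower()
    if policy == "nonzero":
        return "nonzero", None
    if policy in ("length", "vector-length"):
        return "length", None
    if policy.startswith("fixed:"):
        n = int(policy.split(":", 1)[1])
        if n < 1:
            raise ValueError(f"fixed richness must be >= 1, got {n}")
        return "fixed", n
    raise ValueError(
        f"unknown n_policy {n_policy!r}; expected 'nonzero', 'length' "
        "or 'fixed:<N>'")


def _effective(p: AbundanceVector, n_policy: str | int) -> tuple[AbundanceVector, int]:
    kind, fixed_n = resolve_n_policy(n_policy)
    if kind == "nonzero":
        return p, int(np.count_nonzero(p.values))
    if kind == "length":
        return p, p.n
    assert fixed_n is not None
    if int(np.count_nonzero(p.values)) > fixed_n:
        p = truncate_renormalize(p, fixed_n)
    return p, fixed_n


def normalized_entropy(p: AbundanceVector | Sequence[float], i: int,
                       n_policy: str | int = "nonzero") -> NormalizedEntropy:
    """Normalize H(p) by the exact bounds conditional on (i, p_i, n).

    ``n_policy`` selects the richness used for the bounds: "nonzero"
    counts positive entries of p (default), "length" uses len(p), and
    "fixed:N" uses a cohort-wide N, truncating-and-renormalizing p first
    when it has more than N positive taxa.
    """
    if not isinstance(p, AbundanceVector):
        p = AbundanceVector(p)
    p_eff, n = _effective(p, n_policy)
    if not 1 <= i <= n:
        raise IndexError(f"rank i={i} outside [1, {n}] under policy "
                         f"{n_policy!r}")
    p_i = float(rank_abundances(p_eff).sorted_values[i - 1])
    q = BoundQuery(i=i, p_i=p_i, n=n)
    h_min = entropy_lower_bound(q)
    h_max = entropy_upper_bound(q)
    if abs(h_max - h_min) < DEGENERACY_TOLERANCE:
        return NormalizedEntropy(value=None, degenerate=True, i_used=i, n_used=n)
    h = shannon_entropy(p_eff)
    value = (h - h_min) / (h_max - h_min)
    # H may miss a bound by floating-point dust; clamp and snap at the
    # same 1e-12 resolution used for degeneracy, so extremal vectors map
    # to exactly 0 or 1
    value = float(min(max(value, 0.0), 1.0))
    if value < DEGENERACY_TOLERANCE:
        value = 0.0
    elif value > 1.0 - DEGENERACY_TOLERANCE:
        value = 1.0
    return NormalizedEntropy(value=value, degenerate=False, i_used=i, n_used=n)


def truncate_renormalize(p: AbundanceVector | Sequence[float],
                         n_target: int) -> AbundanceVector:
    """Keep the n_target most abundant taxa and rescale to sum 1.

    Retained entries keep their original order; ties at the cutoff are
    broken stably by input position.  A vector that already has at most
    n_target entries is returned unchanged.
    """
    if not isinstance(p, AbundanceVector):
        p = AbundanceVector(p)
    if n_target < 1:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    if p.n <= n_target:
        return p
    order = np.argsort(-p.values, kind="stable")[:n_target]
    keep = np.sort(order)  # preserve original ordering of survivors
    retained = p.values[keep]
    total = retained.sum()
    if total <= 0.0:
        raise ValueError("retained taxa carry zero total abundance")
    return AbundanceVector(retained / total)
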