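"""Count-table I/O and per-sample entropy summaries.

Reads taxon-by-sample count tables (TSV/CSV, the common OTU-table
layout), normalizes each sample to a relative-abundance vector, and
produces one tidy summary row per (sample, rank i): richness, p_i, H,
the conditional bounds, normalized entropy, and a degeneracy flag.
Logging goes to standard error; data only to standard output, so output
can be piped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bounds import BoundQuery, entropy_lower_bound, entropy_upper_bound
from .core import AbundanceVector, rank_abundances, shannon_entropy
from .normalize import normalized_entropy, resolve_n_policy, truncate_renormalize

__all__ = [
    "CountTable",
    "SampleSummary",
    "TableFormatError",
    "read_count_table",
    "write_count_table",
    "to_relative_abundances",
    "summarize_samples",
    "summaries_to_frame",
]

logger = logging.getLogger("entrobound")

SUMMARY_COLUMNS = ["sample_id", "i", "n", "p_i", "H", "H_min", "H_max",
                   "H_norm", "degenerate", "reason", "pielou_j"]


class TableFormatError(ValueError):
    """A count table fails structural validation."""


@dataclass(frozen=True)
class CountTable:
    """Non-negative counts, taxa as rows and samples as columns."""

    counts: pd.DataFrame

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class SampleSummary:
    """Entropy, bounds and normalized entropy for one sample at one rank.

    ``H_norm`` is None when the bounds coincide (``degenerate``) or when
    the rank exceeds the sample's effective richness (``reason`` says
    which).
    """

    sample_id: str
    n_nonzero: int
    i: int
    n_used: int
    p_i: float | None
    H: float
    H_min: float | None
    H_max: float | None
    H_norm: float | None
    pielou_j: float | None
    degenerate: bool
    reason: str | None = None


def _validate_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate taxon labels in {path}: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate sample labels in {path}: {dupes}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableFormatError(
                f"non-numeric cell in {path} at row {row!r}, "
                f"column {col!r}") from exc
    if df.isna().any().any():
        raise TableFormatError(f"missing values in {path}")
    if (df.values < 0).any():
        taxon, sample = next(
            (t, s) for t in df.index for s in df.columns if df.at[t, s] < 0)
        raise TableFormatError(
            f"negative count in {path} at row {taxon!r}, column {sample!r}")
    return df


def read_count_table(path, fmt: str | None = None,
                     orientation: str = "taxa-by-samples") -> CountTable:
    """Read a TSV/CSV count table.

    ``fmt`` is "tsv" or "csv" (inferred from the suffix when None);
    ``orientation`` is "taxa-by-samples" (rows = taxa, the default OTU
    layout) or "samples-by-taxa" (transposed on read).  Samples whose
    counts sum to 0 are dropped with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt.lower() == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = _validate_frame(df, path)
    if orientation == "samples-by-taxa":
        df = df.T
    elif orientation != "taxa-by-samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    zero = df.columns[df.sum(axis=0) <= 0]
    if len(zero):
        logger.warning("dropping %d zero-sum sample(s): %s",
                       len(zero), list(zero))
        df = df.drop(columns=zero)
    if df.shape[1] == 0:
        raise TableFormatError(f"no samples with positive counts in {path}")
    return CountTable(counts=df)


def write_count_table(table: CountTable, path, fmt: str | None = None) -> None:
    """Write a count table back to TSV/CSV (taxa-by-samples)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt.lower() == "csv" else "\t"
    table.counts.to_csv(path, sep=sep)


def to_relative_abundances(table: CountTable) -> list[tuple[str, AbundanceVector]]:
    """Normalize each sample's counts to a relative-abundance vector.

    Vectors keep the table's taxon order; zero-sum samples are skipped
    with a warning (read_count_table already drops them).
    """
    out = []
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy(dtype=float)
        total = col.sum()
        if total <= 0:
            logger.warning("skipping zero-sum sample %r", sample)
            continue
        out.append((sample, AbundanceVector(col / total, renormalize=True)))
    return out


def _summary_for(sample_id: str, p: AbundanceVector, i: int,
                 n_policy: str | int) -> SampleSummary:
    n_nonzero = int(np.count_nonzero(p.values))
    h = shannon_entropy(p)
    pielou = h / math.log(n_nonzero) if n_nonzero > 1 else None
    kind, fixed_n = resolve_n_policy(n_policy)
    if kind == "fixed" and n_nonzero > fixed_n:
        p_eff = truncate_renormalize(p, fixed_n)
        h = shannon_entropy(p_eff)
    else:
        p_eff = p
    n_used = {"nonzero": n_nonzero, "length": p.n, "fixed": fixed_n}[kind]
    if i > n_used:
        return SampleSummary(sample_id=sample_id, n_nonzero=n_nonzero, i=i,
                             n_used=n_used, p_i=None, H=h, H_min=None,
                             H_max=None, H_norm=None, pielou_j=pielou,
                             degenerate=False, reason="i_exceeds_richness")
    p_i = float(rank_abundances(p_eff).sorted_values[i - 1])
    q = BoundQuery(i=i, p_i=p_i, n=n_used)
    h_min = entropy_lower_bound(q)
    h_max = entropy_upper_bound(q)
    norm = normalized_entropy(p, i, n_policy)
    return SampleSummary(
        sample_id=sample_id, n_nonzero=n_nonzero, i=i, n_used=n_used,
        p_i=p_i, H=h, H_min=h_min, H_max=h_max, H_norm=norm.value,
        pielou_j=pielou, degenerate=norm.degenerate,
        reason="degenerate_bounds" if norm.degenerate else None)


def summarize_samples(table: CountTable, i_list: Sequence[int] = (1,),
                      n_policy: str | int = "nonzero") -> list[SampleSummary]:
    """One SampleSummary per sample per requested rank i.

    Degenerate samples are flagged, not dropped; ranks beyond a sample's
    effective richness yield a row with an explicit reason code.
    """
    summaries = []
    for sample_id, p in to_relative_abundances(table):
        for i in i_list:
            summaries.append(_summary_for(sample_id, p, int(i), n_policy))
    return summaries


def summaries_to_frame(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    """Tidy DataFrame with fixed column order; None becomes NA on write."""
    rows = [{
        "sample_id": s.sample_id, "i": s.i, "n": s.n_used, "p_i": s.p_i,
        "H": s.H, "H_min": s.H_min, "H_max": s.H_max, "H_norm": s.H_norm,
        "pielou_j": s.pielou_j, "degenerate": s.degenerate,
        "reason": s.reason,
    } for s in summaries]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
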