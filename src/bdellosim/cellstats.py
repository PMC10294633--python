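"""Summary statistics for single-cell predation measurements.

Reconstructs the study's tabular summaries from per-cell event tables:
mean appearance times of replisome (DnaN), segrosome (ParB) and divisome
(FtsZ) markers with normal-theory 95% confidence intervals, empirical
progeny-count distributions, pooled progeny-length statistics, and the
prey-length vs bdelloplast-diameter correlation.

Event tables are plain :class:`pandas.DataFrame` objects with one row per
predator cell; timing columns are minutes since bdelloplast formation
(time zero) and missing measurements are NaN, never zeros.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .params import Z95, SummaryStat

__all__ = [
    "EVENT_KEYS",
    "ORDER_CHAINS",
    "mean_ci95",
    "summarize_events",
    "pearson",
    "progeny_distribution",
    "progeny_length_stats",
    "validate_event_table",
]

#: Recognised per-cell timing columns (t_* = appearance times since
#: bdelloplast formation; d_* = durations). All optional per species.
EVENT_KEYS = (
    "t_dnaN1", "t_parB2", "d_oric_migration", "t_dnaN2", "t_parB3",
    "t_dnaN3", "t_parB4", "d_replication", "t_ftsZ1", "t_ftsZ2",
    "t_ftsZ3", "d_ftsZ", "t_release",
)

#: Within-cell ordering constraints on appearance times: each marker focus
#: appears after the previous one, and release ends the cycle.
ORDER_CHAINS = (
    ("t_dnaN1", "t_parB2", "t_dnaN2", "t_parB3", "t_dnaN3", "t_parB4"),
    ("t_ftsZ1", "t_ftsZ2", "t_ftsZ3", "t_release"),
)


def mean_ci95(values: Sequence[float]) -> SummaryStat:
    """Sample mean with a normal-theory 95% CI half-width.

    Uses z = 1.96 (normality assumed) and the n−1 sample standard
    deviation: ``ci95_half = 1.96 · sd / √n``. Requires n ≥ 2 finite
    values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    sd = float(np.std(x, ddof=1))
    return SummaryStat(
        mean=float(np.mean(x)),
        ci95_half=Z95 * sd / math.sqrt(x.size),
        n=int(x.size),
    )


def validate_event_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check event-table invariants; returns the table unchanged.

    Present times must be non-negative and respect the within-cell
    ordering chains; progeny counts must be ≥ 2.
    """
    if table.empty:
        raise ValueError("event table is empty")
    timing = [k for k in EVENT_KEYS if k in table.columns]
    for col in timing:
        vals = table[col].dropna()
        if (vals < 0).any():
            raise ValueError(f"negative time in column {col!r}")
    for chain in ORDER_CHAINS:
        present = [k for k in chain if k in table.columns]
        for a, b in zip(present, present[1:]):
            both = table[[a, b]].dropna()
            if (both[a] >= both[b]).any():
                bad = int(both.index[(both[a] >= both[b])][0])
                raise ValueError(
                    f"ordering violated: {a} >= {b} at row {bad}"
                )
    if "progeny_count" in table.columns:
        counts = table["progeny_count"].dropna()
        if (counts < 2).any():
            raise ValueError("progeny_count must be >= 2")
    return table


def summarize_events(table: pd.DataFrame) -> pd.DataFrame:
    """Per species × event summary (mean, 95% CI half-width, n, sd).

    Missing entries are excluded; the reported ``n`` is the count actually
    used. An event observed fewer than twice in a species is omitted with
    a warning rather than summarised from a single cell.
    """
    if table.empty:
        raise ValueError("event table is empty")
    rows = []
    for species, grp in table.groupby("species", sort=False):
        for event in EVENT_KEYS:
            if event not in grp.columns:
                continue
            vals = grp[event].dropna().to_numpy()
            if vals.size == 0:
                continue
            if vals.size < 2:
                warnings.warn(
                    f"{species}/{event}: only {vals.size} observation(s); omitted"
                )
                continue
            stat = mean_ci95(vals)
            rows.append(
                dict(species=species, event=event, mean=stat.mean,
                     ci95_half=stat.ci95_half, n=stat.n, sd=stat.sd)
            )
    return pd.DataFrame(rows)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient in [−1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(np.corrcoef(x, y)[0, 1])


def progeny_distribution(table: pd.DataFrame) -> dict[str, dict]:
    """Empirical progeny-count pmf, mean and raw counts per species."""
    if table.empty:
        raise ValueError("event table is empty")
    out: dict[str, dict] = {}
    for species, grp in table.groupby("species", sort=False):
        counts = grp["progeny_count"].dropna().astype(int)
        freq = counts.value_counts().sort_index()
        n = int(freq.sum())
        out[species] = {
            "pmf": {int(k): v / n for k, v in freq.items()},
            "mean": float(counts.mean()),
            "counts": {int(k): int(v) for k, v in freq.items()},
            "n": n,
        }
    return out


def progeny_length_stats(table: pd.DataFrame) -> dict[str, SummaryStat]:
    """Pooled progeny-length summary (μm) per species.

    ``progeny_lengths`` holds one list of lengths per mother cell; all
    lengths of a species are pooled before summarising.
    """
    if table.empty:
        raise ValueError("event table is empty")
    out: dict[str, SummaryStat] = {}
    for species, grp in table.groupby("species", sort=False):
        pooled: list[float] = []
        for lengths in grp["progeny_lengths"].dropna():
            pooled.extend(float(v) for v in lengths)
        out[species] = mean_ci95(pooled)
    return out
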