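"""Per-position M (log2 ratio) and A (intensity) analysis and site calling.

For each genomic 5'-end position with reads in at least one of two libraries,

    M = log2(reads_a / reads_b),    A = (log2 reads_a + log2 reads_b) / 2,

where a missing side is replaced by a nominal count of 1 (the lowest limit of
detection) and flagged.  Positions absent from both libraries never appear.

The unenriched population forms a dense "cone" whose centre is below zero
whenever the enzyme created new ends (fixed sequencing depth means new ends
dilute old ones).  The baseline is estimated as the mode of the M histogram
over non-nominal positions, and calling thresholds are expressed either as
raw M cut-offs or as enrichment above that baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .core import EndCountTable, EndmapError

MA_COLUMNS = [
    "reference",
    "strand",
    "position",
    "reads_a",
    "reads_b",
    "M",
    "A",
    "nominal_a",
    "nominal_b",
]


def compute_ma(
    table_a: EndCountTable, table_b: EndCountTable, nominal: int = 1
) -> pd.DataFrame:
    """M-A records over the union of positions seen in either library."""
    if nominal <= 0:
        raise ValueError("nominal count must be positive")
    keys = sorted(set(table_a.counts) | set(table_b.counts))
    reads_a = np.array([table_a.counts.get(k, 0) for k in keys], dtype=float)
    reads_b = np.array([table_b.counts.get(k, 0) for k in keys], dtype=float)
    nominal_a = reads_a == 0
    nominal_b = reads_b == 0
    reads_a[nominal_a] = nominal
    reads_b[nominal_b] = nominal
    log_a = np.log2(reads_a)
    log_b = np.log2(reads_b)
    return pd.DataFrame(
        {
            "reference": [k[0] for k in keys],
            "strand": [k[1] for k in keys],
            "position": [k[2] for k in keys],
            "reads_a": reads_a,
            "reads_b": reads_b,
            "M": log_a - log_b,
            "A": (log_a + log_b) / 2.0,
            "nominal_a": nominal_a,
            "nominal_b": nominal_b,
        }
    )


@dataclass
class BaselineEstimate:
    """Centre of the unenriched population of M values."""

    baseline_m: float
    method: str
    bin_width: float
    n_used: int


def estimate_baseline(
    records: pd.DataFrame, bin_width: float = 0.1, exclude_nominal: bool = True
) -> BaselineEstimate:
    """Mode of the M histogram (densest bin centre) over non-nominal records.

    Bins are centred on integer multiples of ``bin_width`` so that symmetric
    data centred on zero yield exactly 0.0; ties between equally dense bins
    are broken toward the smaller M.
    """
    m = records["M"].to_numpy(dtype=float)
    if exclude_nominal:
        keep = ~(records["nominal_a"].to_numpy() | records["nominal_b"].to_numpy())
        m = m[keep]
    if len(m) < 100:
        raise EndmapError(
            f"only {len(m)} usable records (need >= 100); "
            "set exclude_nominal=False or supply the baseline manually"
        )
    bins = np.floor(m / bin_width + 0.5).astype(np.int64)
    uniq, counts = np.unique(bins, return_counts=True)  # uniq ascending
    best = uniq[np.argmax(counts)]  # argmax -> first (smallest M) on ties
    centre = float(best * bin_width)
    centre = float(min(max(centre, m.min()), m.max()))
    return BaselineEstimate(centre, "histogram_mode", bin_width, len(m))


def normalized_fold(m: float, baseline: float) -> float:
    """Fold change of an M value over the unenriched baseline: 2**(M - baseline)."""
    return float(2.0 ** (m - baseline))


def threshold_for_enrichment(enrichment: float, baseline: float) -> float:
    """Raw M threshold equivalent to a log2 enrichment above the baseline."""
    return baseline + enrichment


@dataclass
class SiteCallConfig:
    """Thresholds for calling enriched 5'-end positions.

    Defaults follow the in vitro convention (raw M >= 3.4 over a baseline of
    -1.6, i.e. >= 5 log2 units of enrichment); for in vivo WT-vs-mutant
    comparisons use ``threshold=5.0, baseline=0.0``.  ``min_reads`` guards
    against nominal-value artifacts at singleton positions; set it to 0 for
    threshold-only behaviour.
    """

    threshold: float = 3.4
    baseline: float = -1.6
    min_reads: int = 5
    comparison: str = ""

    def __post_init__(self) -> None:
        if self.threshold <= self.baseline:
            raise ValueError("threshold must exceed baseline")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")


def call_sites(records: pd.DataFrame, config: SiteCallConfig) -> pd.DataFrame:
    """Positions with M >= threshold and numerator reads >= min_reads.

    Sorted by descending M, ties by (reference, strand, position).
    """
    mask = (records["M"] >= config.threshold) & (records["reads_a"] >= config.min_reads)
    calls = records.loc[mask].copy()
    calls["enrichment"] = calls["M"] - config.baseline
    calls["fold"] = 2.0 ** calls["enrichment"]
    calls["comparison"] = config.comparison
    calls = calls.sort_values(
        ["M", "reference", "strand", "position"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return calls


def count_by_threshold(
    records: pd.DataFrame, thresholds: Sequence[float]
) -> Dict[float, int]:
    """Number of records with M strictly greater than each threshold."""
    m = records["M"].to_numpy(dtype=float)
    for t in thresholds:
        if not np.isfinite(t):
            raise ValueError("thresholds must be finite")
    return {float(t): int((m > t).sum()) for t in thresholds}
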