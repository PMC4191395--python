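"""Detection of paired 5'-trimming events in a knockout comparison.

The signature of an RNase-G-like 5'-trimming activity: in the WT-numerator
M-A table of a knockout comparison, the *processed* 5' end is depleted
(M >= depletion threshold) while a 5'-extended *precursor* end accumulates
(M <= -accumulation threshold) within a bounded distance upstream in
transcript orientation.  Precursors that coincide with annotated
transcription start sites point to species whose trimming starts from the
primary transcript after pyrophosphate removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd

from .core import Key
from .io import bed_five_prime, read_bed6

EVENT_COLUMNS = [
    "reference",
    "strand",
    "processed_pos",
    "precursor_pos",
    "distance",
    "M_processed",
    "M_precursor",
    "tss_match",
]


@dataclass
class TrimScanConfig:
    """Window and thresholds for the trim-pair scan.

    ``max_extension`` bounds the precursor distance strictly from above
    (an event requires 1 <= distance < max_extension).
    """

    max_extension: int = 200
    depletion_m: float = 2.0
    accumulation_m: float = 2.0
    min_reads: int = 5

    def __post_init__(self) -> None:
        if self.max_extension < 1:
            raise ValueError("max_extension must be >= 1")
        if self.depletion_m <= 0 or self.accumulation_m <= 0:
            raise ValueError("thresholds must be positive")


def detect_trim_pairs(
    ma_wt_vs_mutant: pd.DataFrame,
    config: TrimScanConfig,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Pair each depleted processed end with an accumulated upstream end.

    The M-A table must have the WT library as numerator, so depletion in the
    mutant appears as positive M and accumulation as negative M.  For each
    depleted position the upstream window of ``max_extension - 1`` nt is
    scanned; with ``all_pairs=False`` (default) the accumulated partner with
    the most negative M wins, ties broken toward the shortest distance.
    Depleted positions with no partner emit nothing.
    """
    ma = ma_wt_vs_mutant
    depleted = ma.loc[(ma["M"] >= config.depletion_m) & (ma["reads_a"] >= config.min_reads)]
    accumulated = ma.loc[
        (ma["M"] <= -config.accumulation_m) & (ma["reads_b"] >= config.min_reads)
    ]
    rows: List[tuple] = []
    acc_by_group: Dict[Tuple[str, str], pd.DataFrame] = {
        key: grp.sort_values("position")
        for key, grp in accumulated.groupby(["reference", "strand"], sort=True)
    }
    for dep in depleted.sort_values(["reference", "strand", "position"]).itertuples(
        index=False
    ):
        grp = acc_by_group.get((dep.reference, dep.strand))
        if grp is None:
            continue
        positions = grp["position"].to_numpy()
        if dep.strand == "+":
            lo, hi = dep.position - (config.max_extension - 1), dep.position - 1
        else:
            lo, hi = dep.position + 1, dep.position + (config.max_extension - 1)
        left = np.searchsorted(positions, lo, side="left")
        right = np.searchsorted(positions, hi, side="right")
        if right <= left:
            continue
        window = grp.iloc[left:right]
        if all_pairs:
            chosen = window
        else:
            dist = (window["position"] - dep.position).abs()
            order = pd.DataFrame({"M": window["M"], "dist": dist}).sort_values(
                ["M", "dist"], kind="mergesort"
            )
            chosen = window.loc[[order.index[0]]]
        for acc in chosen.itertuples(index=False):
            rows.append(
                (
                    dep.reference,
                    dep.strand,
                    dep.position,
                    acc.position,
                    abs(acc.position - dep.position),
                    dep.M,
                    acc.M,
                    False,
                )
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def match_to_tss(
    events: pd.DataFrame,
    tss: Union[str, Path, pd.DataFrame, List[Key]],
    tolerance: int = 1,
) -> pd.DataFrame:
    """Flag events whose precursor end lies within ``tolerance`` of a TSS.

    ``tss`` may be a BED6 path, a frame with reference/strand/position
    columns, or a list of (reference, strand, position) keys.  Matching is
    strand-specific.
    """
    if isinstance(tss, (str, Path)):
        tss_keys = {
            (r.reference, r.strand, r.position)
            for r in bed_five_prime(read_bed6(tss)).itertuples(index=False)
        }
    elif isinstance(tss, pd.DataFrame):
        tss_keys = {
            (r.reference, r.strand, r.position) for r in tss.itertuples(index=False)
        }
    else:
        tss_keys = set(tss)
    out = events.copy()
    flags = []
    for ev in out.itertuples(index=False):
        flags.append(
            any(
                (ev.reference, ev.strand, ev.precursor_pos + d) in tss_keys
                for d in range(-tolerance, tolerance + 1)
            )
        )
    out["tss_match"] = flags
    return out
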