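"""Reproducibility between timepoints and in vivo / in vitro intersection.

The direct-entry candidates are positions both depleted on enzyme
inactivation in vivo (M above the in vivo threshold in the WT/mutant
comparison) and generated by the purified 5'-sensor-mutant enzyme in vitro
(M above the in vitro threshold in the after/before comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import EndmapError, Key

DIRECT_ENTRY = "direct_entry_candidate"
IN_VIVO_ONLY = "in_vivo_only"
IN_VITRO_ONLY = "in_vitro_only"


@dataclass
class ReproducibilityResult:
    rho: float
    p_value: float
    n: int
    m_cutoff: float
    method: str


def spearman_reproducibility(
    ma_1: pd.DataFrame,
    ma_2: pd.DataFrame,
    min_m: float,
    permutation_cutoff: int = 10,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ReproducibilityResult:
    """Spearman correlation of M values between two comparisons.

    Positions with M >= ``min_m`` in the first table are matched by
    (reference, strand, position) in the second; positions absent from the
    second table take M = 0 (both sides at the nominal count).  Ties receive
    average ranks.  The p-value uses the t-distribution approximation on
    n - 2 degrees of freedom, except for n <= ``permutation_cutoff`` where a
    seeded permutation test is used instead.
    """
    sel = ma_1.loc[ma_1["M"] >= min_m]
    n = len(sel)
    if n < 3:
        raise EndmapError(f"only {n} positions with M >= {min_m}; need >= 3")
    lookup: Dict[Key, float] = {
        (r, s, p): m
        for r, s, p, m in zip(
            ma_2["reference"], ma_2["strand"], ma_2["position"], ma_2["M"]
        )
    }
    x = sel["M"].to_numpy(dtype=float)
    y = np.array(
        [
            lookup.get((r, s, p), 0.0)
            for r, s, p in zip(sel["reference"], sel["strand"], sel["position"])
        ]
    )
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    if n <= permutation_cutoff:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm_rho, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(perm_rho) >= abs(rho) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
        method = "permutation"
    else:
        p = float(p_t)
        method = "t_approximation"
    return ReproducibilityResult(rho, p, n, min_m, method)


def intersect_sites(
    in_vivo: pd.DataFrame, in_vitro: pd.DataFrame, tolerance: int = 0
) -> pd.DataFrame:
    """Classify called sites by membership in the two comparisons.

    A pair matches when reference and strand agree and the positions differ
    by at most ``tolerance`` nt.  Each in vivo site is matched at most once:
    the nearest unused in vitro position wins, ties toward the smaller
    coordinate.  Matched pairs become direct-entry candidates; the rest are
    in_vivo_only / in_vitro_only.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    vitro_m: Dict[Key, float] = {
        (r, s, p): m
        for r, s, p, m in zip(
            in_vitro["reference"], in_vitro["strand"], in_vitro["position"], in_vitro["M"]
        )
    }
    used: set = set()
    rows: List[Tuple[str, str, int, float, float, str]] = []
    # offsets ordered nearest-first, ties toward the smaller coordinate
    offsets = sorted(range(-tolerance, tolerance + 1), key=lambda d: (abs(d), d))
    vivo_sorted = in_vivo.sort_values(["reference", "strand", "position"], kind="mergesort")
    for row in vivo_sorted.itertuples(index=False):
        match: Optional[Key] = None
        for d in offsets:
            key = (row.reference, row.strand, row.position + d)
            if key in vitro_m and key not in used:
                match = key
                break
        if match is not None:
            used.add(match)
            rows.append(
                (row.reference, row.strand, row.position, row.M, vitro_m[match], DIRECT_ENTRY)
            )
        else:
            rows.append((row.reference, row.strand, row.position, row.M, np.nan, IN_VIVO_ONLY))
    for key, m in sorted(vitro_m.items()):
        if key not in used:
            rows.append((key[0], key[1], key[2], np.nan, m, IN_VITRO_ONLY))
    return pd.DataFrame(
        rows,
        columns=["reference", "strand", "position", "M_in_vivo", "M_in_vitro", "class"],
    )


def rank_top_sites(
    classified: pd.DataFrame, by: str = "M_in_vitro", k: int = 100
) -> pd.DataFrame:
    """Top-k direct-entry candidates by the chosen M, ties by coordinate."""
    if by not in ("M_in_vitro", "M_in_vivo"):
        raise ValueError("by must be M_in_vitro or M_in_vivo")
    if k < 1:
        raise ValueError("k must be >= 1")
    cand = classified.loc[classified["class"] == DIRECT_ENTRY]
    ordered = cand.sort_values(
        [by, "reference", "strand", "position"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    return ordered.head(k).reset_index(drop=True)


def class_counts(classified: pd.DataFrame) -> Dict[str, int]:
    return classified["class"].value_counts().to_dict()
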