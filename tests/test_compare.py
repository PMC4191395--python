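"""Reproducibility statistics and in vivo / in vitro site intersection."""

import numpy as np
import pandas as pd
import pytest

from endmap import (
    DIRECT_ENTRY,
    IN_VITRO_ONLY,
    IN_VIVO_ONLY,
    EndmapError,
    class_counts,
    intersect_sites,
    rank_top_sites,
    spearman_reproducibility,
)


def ma_frame(values, strand="+", reference="ref1"):
    """Frame keyed by position with given M values."""
    positions = sorted(values)
    return pd.DataFrame(
        {
            "reference": [reference] * len(positions),
            "strand": [strand] * len(positions),
            "position": positions,
            "reads_a": 100.0,
            "reads_b": 100.0,
            "M": [values[p] for p in positions],
            "A": 0.0,
            "nominal_a": False,
            "nominal_b": False,
        }
    )


def average_ranks(values):
    """Hand-rolled average ranks (the brute-force oracle)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    x = np.asarray(x)
    y = np.asarray(y)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


class TestSpearman:
    def test_identical_vectors(self):
        m = {i * 10: float(i) for i in range(1, 21)}
        res = spearman_reproducibility(ma_frame(m), ma_frame(m), min_m=0.0)
        assert res.rho == pytest.approx(1.0)
        assert res.n == 20

    def test_reversed_ranks(self):
        m1 = {i * 10: float(i) for i in range(1, 21)}
        m2 = {i * 10: float(-i) for i in range(1, 21)}
        res = spearman_reproducibility(ma_frame(m1), ma_frame(m2), min_m=0.0)
        assert res.rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        x = [4.1, 6.0, 6.0, 3.4, 8.8, 5.2, 9.7, 3.9, 5.6, 4.3, 7.0, 5.8]
        y = [3.9, 5.5, 6.2, 3.5, 8.1, 5.2, 9.0, 4.4, 5.2, 4.0, 7.7, 6.1]
        m1 = {(i + 1) * 10: v for i, v in enumerate(x)}
        m2 = {(i + 1) * 10: v for i, v in enumerate(y)}
        res = spearman_reproducibility(ma_frame(m1), ma_frame(m2), min_m=0.0)
        expected = pearson(average_ranks(x), average_ranks(y))
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 2, 30)
        y = x + rng.normal(0, 0.5, 30)
        m1 = {(i + 1) * 10: float(v) for i, v in enumerate(x)}
        m2 = {(i + 1) * 10: float(v) for i, v in enumerate(y)}
        m2_cubed = {k: float(v ** 3) for k, v in m2.items()}
        r1 = spearman_reproducibility(ma_frame(m1), ma_frame(m2), min_m=-100.0)
        r2 = spearman_reproducibility(ma_frame(m1), ma_frame(m2_cubed), min_m=-100.0)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)

    def test_missing_positions_take_zero(self):
        m1 = {10: 5.0, 20: 6.0, 30: 7.0, 40: 8.0}
        m2 = {10: 5.0, 20: 6.0, 30: 7.0}  # 40 absent -> 0.0
        res = spearman_reproducibility(ma_frame(m1), ma_frame(m2), min_m=0.0)
        oracle = pearson(average_ranks([5, 6, 7, 8]), average_ranks([5, 6, 7, 0]))
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_small_n_uses_seeded_permutation(self):
        m1 = {10: 1.0, 20: 2.0, 30: 3.0, 40: 4.0, 50: 5.0}
        res1 = spearman_reproducibility(ma_frame(m1), ma_frame(m1), min_m=0.0, seed=3)
        res2 = spearman_reproducibility(ma_frame(m1), ma_frame(m1), min_m=0.0, seed=3)
        assert res1.method == "permutation"
        assert res1.p_value == res2.p_value
        assert 0 < res1.p_value < 0.1  # perfect concordance among 5!=120 orders

    def test_too_few_positions_rejected(self):
        m = {10: 5.0, 20: 6.0}
        with pytest.raises(EndmapError):
            spearman_reproducibility(ma_frame(m), ma_frame(m), min_m=0.0)


def calls_frame(positions, strand="+", m=6.0):
    return pd.DataFrame(
        {
            "reference": "ref1",
            "strand": strand,
            "position": list(positions),
            "M": [m] * len(positions) if np.isscalar(m) else m,
        }
    )


class TestIntersectSites:
    def test_exact_intersection_classes(self):
        out = intersect_sites(calls_frame([100, 200]), calls_frame([100, 300]), 0)
        by_class = {
            row["class"]: row["position"] for _, row in out.iterrows()
        }
        assert by_class == {DIRECT_ENTRY: 100, IN_VIVO_ONLY: 200, IN_VITRO_ONLY: 300}

    def test_tolerance_allows_off_by_one(self):
        out = intersect_sites(calls_frame([100]), calls_frame([101]), 1)
        assert class_counts(out) == {DIRECT_ENTRY: 1}

    def test_strands_never_mix(self):
        out = intersect_sites(
            calls_frame([100], strand="+"), calls_frame([100], strand="-"), 0
        )
        assert class_counts(out) == {IN_VIVO_ONLY: 1, IN_VITRO_ONLY: 1}

    def test_each_vitro_site_used_once_nearest_wins(self):
        # two in vivo sites compete for one in vitro site at 101
        out = intersect_sites(calls_frame([100, 102]), calls_frame([101]), 1)
        matched = out.loc[out["class"] == DIRECT_ENTRY, "position"].tolist()
        assert matched == [100]  # smaller coordinate scanned first

    def test_tie_broken_toward_smaller_coordinate(self):
        out = intersect_sites(calls_frame([100]), calls_frame([99, 101]), 1)
        row = out.loc[out["class"] == DIRECT_ENTRY].iloc[0]
        unmatched = out.loc[out["class"] == IN_VITRO_ONLY, "position"].tolist()
        assert unmatched == [101]

    def test_count_identities_and_tolerance_monotonicity(self):
        rng = np.random.default_rng(5)
        vivo = calls_frame(sorted(rng.choice(5000, 60, replace=False)))
        vitro = calls_frame(sorted(rng.choice(5000, 60, replace=False)))
        previous = -1
        for tol in (0, 1, 2, 5):
            out = intersect_sites(vivo, vitro, tol)
            counts = class_counts(out)
            matched = counts.get(DIRECT_ENTRY, 0)
            assert matched <= min(len(vivo), len(vitro))
            assert len(out) == len(vivo) + len(vitro) - matched
            assert matched >= previous
            previous = matched


class TestRankTopSites:
    def make_classified(self):
        return pd.DataFrame(
            {
                "reference": "ref1",
                "strand": "+",
                "position": [10, 20, 30, 40],
                "M_in_vivo": [5.0, 7.0, 6.0, 9.0],
                "M_in_vitro": [4.0, 9.0, 9.0, 3.5],
                "class": [DIRECT_ENTRY] * 3 + [IN_VIVO_ONLY],
            }
        )

    def test_k_larger_than_list(self):
        out = rank_top_sites(self.make_classified(), "M_in_vitro", 100)
        assert len(out) == 3  # only candidates rank

    def test_k_one_gives_max_with_coordinate_tiebreak(self):
        out = rank_top_sites(self.make_classified(), "M_in_vitro", 1)
        assert out.iloc[0]["position"] == 20

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "reference": "ref1",
                "strand": "+",
                "position": np.arange(1, 51),
                "M_in_vivo": rng.normal(6, 1, 50).round(1),
                "M_in_vitro": rng.normal(6, 1, 50).round(1),
                "class": DIRECT_ENTRY,
            }
        )
        out = rank_top_sites(df, "M_in_vivo", 10)
        oracle = sorted(
            df.itertuples(index=False), key=lambda r: (-r.M_in_vivo, r.position)
        )[:10]
        assert list(out["position"]) == [r.position for r in oracle]
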