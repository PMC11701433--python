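"""Densities, contact profiles, and the two-sample / 2x2 exact tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from tlscape.phenotype import assign_phenotypes
from tlscape.spatial import (compare_groups, compute_densities, contact_profile,
                             fisher_2x2)

from conftest import random_cell_table


def _table(coords, target_mask, query_mask):
    n = len(coords)
    t = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                      "x_um": [c[0] for c in coords],
                      "y_um": [c[1] for c in coords],
                      "Tumor": np.asarray(target_mask, dtype=int),
                      "Q": np.asarray(query_mask, dtype=int)})
    return t


class TestDensities:
    def test_uniform_cells_in_unit_square_mm(self, rng):
        t = random_cell_table(rng, n=100, field=1000.0)
        t["CD8"] = 1
        t, _ = assign_phenotypes(t)
        t["compartment"] = "tumor"
        regions = pd.DataFrame({"label": ["tumor"], "geometry": [box(0, 0, 1000, 1000)]})
        rep = compute_densities(t, regions, ["CD8T"])
        row = rep[(rep["compartment"] == "tumor") & (rep["phenotype"] == "CD8T")]
        assert row["density_cells_per_mm2"].iloc[0] == pytest.approx(100.0)
        assert row["area_mm2"].iloc[0] == pytest.approx(1.0)

    def test_collinear_cells_without_regions_error(self):
        t = random_cell_table(np.random.default_rng(0), n=3)
        t["x_um"] = [0.0, 1.0, 2.0]
        t["y_um"] = [0.0, 1.0, 2.0]
        t, _ = assign_phenotypes(t)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            compute_densities(t, None, ["CD8T"])

    def test_counts_match_brute_force_point_in_polygon(self, rng):
        t = random_cell_table(rng, n=600, field=1500.0)
        t, _ = assign_phenotypes(t)
        regions = pd.DataFrame({"label": ["tumor", "tissue"],
                                "geometry": [box(200, 200, 800, 900),
                                             box(0, 0, 1500, 1500)]})
        from tlscape.io import assign_compartments
        t = assign_compartments(t, regions)
        rep = compute_densities(t, regions, ["CD8T", "Bcell"])
        x, y = t["x_um"].to_numpy(), t["y_um"].to_numpy()
        # brute-force rectangle containment, boundary inclusive
        in_tumor = (200 <= x) & (x <= 800) & (200 <= y) & (y <= 900)
        for ph in ("CD8T", "Bcell"):
            mask = t[ph].to_numpy().astype(bool)
            got = rep[(rep["compartment"] == "tumor") & (rep["phenotype"] == ph)]
            assert got["count"].iloc[0] == int((mask & in_tumor).sum())
            whole = rep[(rep["compartment"] == "whole") & (rep["phenotype"] == ph)]
            assert whole["count"].iloc[0] == mask.sum()

    def test_whole_equals_sum_of_compartments(self, rng):
        t = random_cell_table(rng, n=300, field=1200.0)
        t, _ = assign_phenotypes(t)
        regions = pd.DataFrame({"label": ["tumor", "stroma"],
                                "geometry": [box(0, 0, 500, 1200), box(500, 0, 1000, 1200)]})
        from tlscape.io import assign_compartments
        t = assign_compartments(t, regions)
        rep = compute_densities(t, regions, ["CD8T"]).set_index("compartment")
        unassigned = ((t["CD8T"]) & (t["compartment"] == "unassigned")).sum()
        assert rep.loc["whole", "count"] == \
            rep.loc["tumor", "count"] + rep.loc["stroma", "count"] + unassigned


class TestContactProfile:
    def test_single_close_pair(self):
        t = _table([(0, 0), (5, 0)], [1, 0], [0, 1])
        prof = contact_profile(t, "Tumor", "Q")
        assert prof.bin_counts == [1, 0, 0]
        assert prof.close_fraction == 1.0

    def test_distance_exactly_ten_goes_to_second_bin(self):
        t = _table([(0, 0), (10.0, 0)], [1, 0], [0, 1])
        prof = contact_profile(t, "Tumor", "Q")
        assert prof.bin_counts == [0, 1, 0]
        assert prof.close_fraction == 0.0  # strict < 10

    def test_final_bin_closed(self):
        t = _table([(0, 0), (30.0, 0)], [1, 0], [0, 1])
        assert contact_profile(t, "Tumor", "Q").bin_counts == [0, 0, 1]

    def test_dual_phenotype_cell_never_pairs_with_itself(self):
        t = _table([(0, 0)], [1], [1])
        prof = contact_profile(t, "Tumor", "Q")
        assert prof.bin_counts == [0, 0, 0] and prof.close_fraction == 0.0

    def test_unsorted_edges_rejected(self):
        t = _table([(0, 0)], [1], [0])
        with pytest.raises(ValueError, match="increasing"):
            contact_profile(t, "Tumor", "Q", bin_edges=[0, 20, 10])

    def test_counts_match_all_pairs_oracle(self, rng):
        t = random_cell_table(rng, n=800, field=600.0)
        t, _ = assign_phenotypes(t)
        prof = contact_profile(t, "Tumor", "TCF1_PD1_CD8T")
        xy = t[["x_um", "y_um"]].to_numpy()
        tgt = t["Tumor"].to_numpy().astype(bool)
        qry = t["TCF1_PD1_CD8T"].to_numpy().astype(bool)
        edges = [0.0, 10.0, 20.0, 30.0]
        expected = [0, 0, 0]
        n_close = 0
        for qi in np.flatnonzero(qry):
            close = False
            for ti in np.flatnonzero(tgt):
                if ti == qi:
                    continue
                d = math.hypot(xy[ti, 0] - xy[qi, 0], xy[ti, 1] - xy[qi, 1])
                if d < 10.0:
                    close = True
                for b in range(3):
                    if edges[b] <= d < edges[b + 1] or (b == 2 and d == 30.0):
                        expected[b] += 1
            n_close += close
        assert prof.bin_counts == expected
        assert prof.close_fraction == pytest.approx(n_close / qry.sum())

    def test_counts_monotone_in_outer_edge(self, rng):
        t = random_cell_table(rng, n=400, field=500.0)
        t, _ = assign_phenotypes(t)
        totals = [sum(contact_profile(t, "Tumor", "CD8T", [0.0, hi]).bin_counts)
                  for hi in (10.0, 20.0, 40.0, 80.0)]
        assert totals == sorted(totals)

    def test_union_of_disjoint_queries_adds_up(self, rng):
        t = random_cell_table(rng, n=500, field=500.0)
        # TFH and Treg are mutually exclusive (FoxP3- vs FoxP3+)
        t, _ = assign_phenotypes(t)
        t["either"] = (t["TFH"] | t["Treg"]).astype(int)
        a = contact_profile(t, "Tumor", "TFH").bin_counts
        b = contact_profile(t, "Tumor", "Treg").bin_counts
        u = contact_profile(t, "Tumor", "either").bin_counts
        assert [x + y for x, y in zip(a, b)] == u


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), nbins=st.integers(1, 5))
def test_profile_refining_bins_preserves_totals(seed, nbins):
    """Splitting the same outer radius into more bins never changes the
    total pair count (cumulative consistency of half-open bins)."""
    r = np.random.default_rng(seed)
    t = random_cell_table(r, n=120, field=200.0)
    t, _ = assign_phenotypes(t)
    coarse = contact_profile(t, "Tumor", "CD8T", [0.0, 30.0])
    edges = [0.0] + sorted(np.random.default_rng(seed + 1)
                           .uniform(1, 29, nbins).tolist()) + [30.0]
    fine = contact_profile(t, "Tumor", "CD8T", edges)
    assert sum(fine.bin_counts) == sum(coarse.bin_counts)
    assert fine.close_fraction == coarse.close_fraction


def _mw_exact_enumeration(a, b):
    """Full enumeration of rank arrangements: two-sided exact p for U."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for comb in itertools.combinations(range(n), n1):
        r = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    mean_u = n1 * (n - n1) / 2
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return float(min(p, 1.0))


class TestCompareGroups:
    def test_identical_constant_samples_p_one(self):
        assert compare_groups([3, 3, 3], [3, 3])["p"] == 1.0

    def test_separated_triples_exact(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(0.1)  # 2 * (1/20)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 7)))
            b = rng.normal(size=int(rng.integers(3, 7)))
            res = compare_groups(a, b)
            assert res["p"] == pytest.approx(_mw_exact_enumeration(a, b), abs=1e-12)

    def test_large_sample_matches_hand_normal_approximation(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.5, 1, size=30)
        res = compare_groups(a, b)
        # independent derivation: tie-corrected normal approximation
        n1, n2 = len(a), len(b)
        ranks = pd.Series(np.concatenate([a, b])).rank().to_numpy()
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)  # no ties in continuous data
        from scipy.stats import norm
        z = (u - mu - 0.5 * np.sign(u - mu)) / sd  # continuity corrected
        p = 2 * norm.sf(abs(z))
        assert res["p"] == pytest.approx(p, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups([], [1.0])


def _fisher_enumeration(a, b, c, d):
    """Conditional hypergeometric enumeration over all tables with the
    observed margins; two-sided p sums probabilities <= observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_perfect_split(self):
        res = fisher_2x2(5, 0, 0, 5)
        assert res["odds_ratio"] == np.inf
        assert res["p"] == pytest.approx(2 / 252)

    def test_balanced_table(self):
        res = fisher_2x2(2, 2, 2, 2)
        assert res["odds_ratio"] == 1.0 and res["p"] == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            res = fisher_2x2(int(a), int(b), int(c), int(d))
            assert res["p"] == pytest.approx(_fisher_enumeration(int(a), int(b),
                                                                 int(c), int(d)),
                                             abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fisher_2x2(0, 0, 0, 0)
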