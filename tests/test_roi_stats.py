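"""Volume of activation, composite maps, Kruskal-Wallis tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phmri import (
    RegionResponse,
    activation_map,
    composite_map,
    composite_region_counts,
    kruskal_wallis_region,
    pairwise_group_tables,
    significant_region_table,
    volume_of_activation,
)
from phmri.data import reported_voa_table

from conftest import make_session


@pytest.fixture(scope="module")
def null_map(small_atlas, null_session):
    return activation_map(null_session, small_atlas.labels)


@pytest.fixture(scope="module")
def responsive_map(small_atlas, full_cfg):
    s = make_session(small_atlas, full_cfg, {2: RegionResponse(51, 0, 4.0)})
    return activation_map(s, small_atlas.labels)


class TestVolumeOfActivation:
    def test_empty_mask_gives_all_zero_counts(self, null_map, small_atlas):
        voa = volume_of_activation(null_map, small_atlas.labels)
        assert (voa["activated_voxels"] == 0).all()
        assert (voa["mean_pct_change"] == 0.0).all()

    def test_counts_confined_to_responsive_region(self, responsive_map, small_atlas):
        voa = volume_of_activation(responsive_map, small_atlas.labels)
        w = voa[voa["window"] == "15-25"].set_index("region_id")
        region_size = int((small_atlas.labels == 2).sum())
        assert w.loc[2, "activated_voxels"] == region_size
        assert w.loc[2, "mean_pct_change"] == pytest.approx(4.0, abs=1e-9)
        others = w.drop(index=2)
        assert (others["activated_voxels"] == 0).all()

    def test_counts_conserve_total_activated_voxels(self, responsive_map, small_atlas):
        voa = volume_of_activation(responsive_map, small_atlas.labels, sign=+1)
        for w in responsive_map.scheme.names:
            total = responsive_map.activated_count(w, sign=+1)
            assert voa.loc[voa["window"] == w, "activated_voxels"].sum() == total

    def test_monotone_under_mask_growth(self, small_atlas, full_cfg):
        s = make_session(
            small_atlas, full_cfg, {2: RegionResponse(51, 0, 4.0)}, noise_sd=1.0, seed=4
        )
        m = activation_map(s, small_atlas.labels)
        voa_before = volume_of_activation(m, small_atlas.labels)
        grown = m.windows["15-25"].activated.copy()
        extra = (small_atlas.labels == 3) & ~grown
        m.windows["15-25"].activated |= extra
        m.windows["15-25"].sign[extra] = 1
        voa_after = volume_of_activation(m, small_atlas.labels)
        merged = voa_before.merge(
            voa_after, on=["region_id", "window"], suffixes=("_a", "_b")
        )
        assert (merged["activated_voxels_b"] >= merged["activated_voxels_a"]).all()


class TestCompositeMap:
    def test_single_subject_composite_is_its_map(self, responsive_map, small_atlas):
        comp = composite_map([responsive_map], "15-25", min_frequency=0.5)
        act = responsive_map.windows["15-25"].activated
        np.testing.assert_array_equal(comp.retained, act)
        np.testing.assert_allclose(
            comp.mean_pct[act], responsive_map.windows["15-25"].pct_change[act]
        )

    def test_mean_of_two_subjects(self, small_atlas, full_cfg):
        m2 = activation_map(
            make_session(small_atlas, full_cfg, {2: RegionResponse(51, 0, 2.0)}),
            small_atlas.labels,
        )
        m4 = activation_map(
            make_session(small_atlas, full_cfg, {2: RegionResponse(51, 0, 4.0)}),
            small_atlas.labels,
        )
        comp = composite_map([m2, m4], "15-25")
        region = small_atlas.labels == 2
        assert comp.mean_pct[region] == pytest.approx(3.0, abs=1e-9)
        assert comp.retained[region].all()

    def test_low_frequency_voxels_dropped(self, small_atlas, full_cfg, null_session):
        responsive = activation_map(
            make_session(small_atlas, full_cfg, {2: RegionResponse(51, 0, 4.0)}),
            small_atlas.labels,
        )
        nulls = [activation_map(null_session, small_atlas.labels)] * 3
        comp = composite_map([responsive, *nulls], "15-25", min_frequency=0.5)
        assert not comp.retained.any()  # activated in 1/4 subjects only
        counts = composite_region_counts(comp, small_atlas.labels)
        assert all(v == 0 for v in counts.values())

    def test_grid_mismatch_rejected(self, responsive_map, small_atlas, full_cfg):
        from phmri import generate_atlas

        other = generate_atlas((16, 16, 8), n_regions=3, seed=0)
        m_other = activation_map(
            make_session(other, full_cfg, None, shape=(16, 16, 8)),
            other.labels,
            scheme=responsive_map.scheme,
        )
        with pytest.raises(ValueError, match="common grid"):
            composite_map([responsive_map, m_other], "15-25")


def _kw_bruteforce(groups):
    """Rank-based H with tie correction, computed from first principles."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank of the tie block
        i = j
    offsets = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (ranks[a:b].mean() - (n + 1) / 2.0) ** 2
        for g, a, b in zip(groups, offsets[:-1], offsets[1:])
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    return h / correction


class TestKruskalWallis:
    def test_all_tied_returns_null(self):
        assert kruskal_wallis_region({"A": [3, 3, 3], "B": [3, 3, 3]}) == (0.0, 1.0)

    def test_matches_bruteforce_rank_oracle(self):
        groups = {"A": [0, 0, 0], "B": [5, 6, 7]}
        h, p = kruskal_wallis_region(groups)
        h_ref = _kw_bruteforce([np.array(v, float) for v in groups.values()])
        assert h == pytest.approx(h_ref, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(h_ref, df=1), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_with_heavy_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = {k: rng.integers(0, 4, size=rng.integers(4, 9)) for k in "ABC"}
        h, p = kruskal_wallis_region({k: v.astype(float) for k, v in groups.items()})
        h_ref = _kw_bruteforce([v.astype(float) for v in groups.values()])
        assert h == pytest.approx(h_ref, abs=1e-10)

    def test_chi_square_reference_tracks_exact_permutation_tail(self):
        """The chi-square p is an asymptotic approximation; for a 3x3 design
        its tail probability sits within a few hundredths of the exact
        permutation enumeration."""
        groups = [
            np.array([1.0, 2.0, 3.0]),
            np.array([4.0, 5.0, 6.0]),
            np.array([7.0, 8.0, 9.0]),
        ]
        h_obs, p_chi2 = kruskal_wallis_region(
            {"A": groups[0], "B": groups[1], "C": groups[2]}
        )
        pooled = np.concatenate(groups)
        count = 0
        total = 0
        idx = range(9)
        for g1 in itertools.combinations(idx, 3):
            rem = [i for i in idx if i not in set(g1)]
            for g2 in itertools.combinations(rem, 3):
                g3 = [i for i in rem if i not in set(g2)]
                parts = [pooled[list(g1)], pooled[list(g2)], pooled[list(g3)]]
                total += 1
                if _kw_bruteforce(parts) >= h_obs - 1e-9:
                    count += 1
        p_exact = count / total
        assert p_chi2 == pytest.approx(p_exact, abs=0.05)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis_region({"A": [1, 2, 3]})


class TestSignificantRegionTable:
    @pytest.mark.parametrize(
        "treatment, window, expected",
        [("idalopirdine", "35-45", 8), ("donepezil", "15-25", 19), ("combination", "25-35", 36)],
    )
    def test_published_table_filters(self, treatment, window, expected):
        table = reported_voa_table(treatment)
        sig = significant_region_table(table, window=window, alpha=0.05)
        assert len(sig) == expected
        assert sig["p_value"].is_monotonic_increasing

    def test_requires_p_value_column(self):
        with pytest.raises(ValueError, match="p_value"):
            significant_region_table(pd.DataFrame({"x": [1]}))


def test_pairwise_group_tables_flags_responsive_region(small_atlas, full_cfg):
    drug_maps = [
        activation_map(
            make_session(
                small_atlas, full_cfg, {2: RegionResponse(51, 0, 4.0)},
                noise_sd=1.0, seed=100 + i,
            ),
            small_atlas.labels,
        )
        for i in range(5)
    ]
    veh_maps = [
        activation_map(
            make_session(small_atlas, full_cfg, None, treatment="vehicle",
                         noise_sd=1.0, seed=200 + i),
            small_atlas.labels,
        )
        for i in range(5)
    ]
    tables = pairwise_group_tables(
        veh_maps + drug_maps, small_atlas.labels, small_atlas, control="vehicle"
    )
    table = tables["drug"]
    sig = significant_region_table(table, window="25-35")
    assert sig["region_id"].tolist() == [2]
    row = table[(table.region_id == 2) & (table.window == "25-35")].iloc[0]
    assert row["count_drug"] > 0 and row["count_vehicle"] == 0
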