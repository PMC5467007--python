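"""Circuit time courses, mixed-design ANOVA and Dunnett post-hoc tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phmri import (
    Atlas,
    RegionResponse,
    WindowScheme,
    dunnett_vs_control,
    network_series,
    rm_anova_interaction,
)

from conftest import make_session


def _single_region_network(atlas: Atlas, rid: int) -> Atlas:
    return Atlas(
        labels=atlas.labels,
        voxel_size=atlas.voxel_size,
        regions=atlas.regions,
        networks={**dict(atlas.networks), "solo": frozenset({rid})},
    )


class TestNetworkSeries:
    def test_null_session_gives_zero_series(self, small_atlas, null_session):
        name = next(iter(small_atlas.networks))
        tc = network_series(
            null_session, small_atlas.labels, small_atlas, name, WindowScheme()
        )
        assert tc.series == pytest.approx(0.0, abs=1e-12)
        assert len(tc.series) == 450
        assert tc.acquisitions[0] == 51 and tc.acquisitions[-1] == 500

    def test_single_region_step_response(self, small_atlas, full_cfg):
        atlas = _single_region_network(small_atlas, 2)
        s = make_session(atlas, full_cfg, {2: RegionResponse(51, 0, 4.0)})
        tc = network_series(s, atlas.labels, atlas, "solo", WindowScheme())
        assert tc.series == pytest.approx(4.0, abs=1e-9)
        assert tc.window_means == pytest.approx({"15-25": 4.0, "25-35": 4.0, "35-45": 4.0})

    def test_window_means_recompute_from_series(self, small_atlas, full_cfg):
        name = next(iter(small_atlas.networks))
        s = make_session(
            small_atlas, full_cfg, {1: RegionResponse(51, 40, 3.0)}, noise_sd=1.0, seed=2
        )
        scheme = WindowScheme()
        tc = network_series(s, small_atlas.labels, small_atlas, name, scheme)
        for w, (w0, w1) in scheme.windows.items():
            # series index 0 is acquisition 51
            seg = tc.series[w0 - 51 : w1 - 51]
            assert tc.window_means[w] == pytest.approx(seg.mean(), abs=1e-12)

    def test_union_network_is_voxel_weighted_mean(self, small_atlas, full_cfg):
        atlas = Atlas(
            labels=small_atlas.labels,
            voxel_size=small_atlas.voxel_size,
            regions=small_atlas.regions,
            networks={"a": frozenset({1}), "b": frozenset({2}), "ab": frozenset({1, 2})},
        )
        s = make_session(
            atlas, full_cfg,
            {1: RegionResponse(51, 0, 2.0), 2: RegionResponse(51, 0, 6.0)},
            noise_sd=1.0, seed=8,
        )
        scheme = WindowScheme()
        tc_a = network_series(s, atlas.labels, atlas, "a", scheme)
        tc_b = network_series(s, atlas.labels, atlas, "b", scheme)
        tc_ab = network_series(s, atlas.labels, atlas, "ab", scheme)
        n_a = int((atlas.labels == 1).sum())
        n_b = int((atlas.labels == 2).sum())
        weighted = (n_a * tc_a.series + n_b * tc_b.series) / (n_a + n_b)
        np.testing.assert_allclose(tc_ab.series, weighted, atol=1e-9)

    def test_empty_network_rejected(self, small_atlas, null_session):
        with pytest.raises(KeyError, match="unknown network"):
            network_series(
                null_session, small_atlas.labels, small_atlas, "nonesuch", WindowScheme()
            )


def _long_frame(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "window", "value"])


class TestRmAnovaInteraction:
    def test_identical_cells_give_zero_interaction(self):
        rows = [
            (f"{g}{s}", g, w, 5.0)
            for g in "AB"
            for s in range(3)
            for w in "XYZ"
        ]
        res = rm_anova_interaction(_long_frame(rows))
        assert res.F == 0.0
        assert res.p == 1.0

    def test_toy_table_matches_sums_of_squares_oracle(self):
        """2 groups x 3 windows x 3 subjects; expected value frozen from an
        independent mixed-ANOVA decomposition."""
        cells = {
            ("A", 0): [1, 2, 3], ("A", 1): [2, 3, 4], ("A", 2): [0, 1, 2],
            ("B", 0): [1, 1, 1], ("B", 1): [3, 2, 1], ("B", 2): [2, 2, 2],
        }
        rows = [
            (f"{g}{s}", g, w, v)
            for (g, s), vals in cells.items()
            for w, v in zip("XYZ", vals)
        ]
        res = rm_anova_interaction(_long_frame(rows))
        assert res.F == pytest.approx(16.0, abs=1e-8)
        assert (res.df1, res.df2) == (2, 8)
        assert res.p == pytest.approx(0.0016, abs=1e-4)

    @pytest.mark.parametrize("sizes", [(8, 8, 8), (6, 9)])
    def test_matches_pingouin_mixed_anova(self, sizes):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        rows = []
        for gi, n in enumerate(sizes):
            for s in range(n):
                base = rng.normal(0, 1)
                for wi, w in enumerate("XYZ"):
                    rows.append(
                        (f"g{gi}s{s}", f"g{gi}", w, base + 0.3 * gi * wi + rng.normal())
                    )
        df = _long_frame(rows)
        res = rm_anova_interaction(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="window", subject="subject", between="group"
        ).set_index("Source")
        assert res.F == pytest.approx(float(ref.loc["Interaction", "F"]), abs=1e-8)
        assert res.df1 == int(ref.loc["Interaction", "DF1"])
        assert res.df2 == int(ref.loc["Interaction", "DF2"])

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"{g}{s}", g, w, rng.normal())
            for g in "AB" for s in range(4) for w in "XY"
        ]
        df = _long_frame(rows)
        shifted = df.assign(value=df["value"] + 100.0)
        a, b = rm_anova_interaction(df), rm_anova_interaction(shifted)
        assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_missing_window_rejected(self):
        rows = [("A0", "A", "X", 1.0), ("A0", "A", "Y", 2.0),
                ("B0", "B", "X", 1.0)]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova_interaction(_long_frame(rows))


class TestDunnett:
    def test_identical_groups_give_p_near_one(self):
        vals = np.arange(9.0)
        res = dunnett_vs_control(
            {"vehicle": vals, "a": vals.copy(), "b": vals.copy()}, control="vehicle"
        )
        assert (res["p_adj"] > 0.99).all()
        np.testing.assert_allclose(res["statistic"].to_numpy(), 0.0, atol=1e-12)

    def test_single_treatment_collapses_to_pooled_t_test(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 9), rng.normal(0.7, 1, 9)
        res = dunnett_vs_control({"vehicle": a, "drug": b}, control="vehicle")
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert res.loc[0, "p_adj"] == pytest.approx(ref.pvalue, abs=1e-6)
        assert res.loc[0, "statistic"] == pytest.approx(ref.statistic, abs=1e-9)

    def test_adjusted_p_exceeds_unadjusted_with_many_treatments(self):
        rng = np.random.default_rng(6)
        ctrl = rng.normal(0, 1, 9)
        groups = {"vehicle": ctrl}
        groups.update({f"t{i}": rng.normal(0.8, 1, 9) for i in range(3)})
        res = dunnett_vs_control(groups, control="vehicle")
        for r in res.itertuples():
            single = dunnett_vs_control(
                {"vehicle": ctrl, r.treatment: groups[r.treatment]}, control="vehicle"
            )
            # multiplicity can only make a comparison less significant
            assert r.p_adj >= single.loc[0, "p_adj"] - 1e-3

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            dunnett_vs_control({"a": [1, 2], "b": [3, 4]}, control="vehicle")

    def test_long_frame_window_selection_matches_explicit_subsetting(self):
        rng = np.random.default_rng(7)
        rows = []
        for g in ["vehicle", "drug"]:
            for s in range(6):
                for w in ["15-25", "25-35"]:
                    shift = 1.0 if (g == "drug" and w == "25-35") else 0.0
                    rows.append(
                        {"group": g, "window": w, "value": rng.normal(shift, 0.3)}
                    )
        df = pd.DataFrame(rows)
        for w in ["15-25", "25-35"]:
            from_frame = dunnett_vs_control(df, control="vehicle", window=w)
            sub = df[df["window"] == w]
            explicit = dunnett_vs_control(
                {g: grp["value"].to_numpy() for g, grp in sub.groupby("group")},
                control="vehicle",
            )
            pd.testing.assert_frame_equal(from_frame, explicit)
        late = dunnett_vs_control(df, control="vehicle", window="25-35")
        assert late.loc[0, "p_adj"] < 0.01  # the injected late-window effect
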