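"""Split-plot ANOVA, Box/GG epsilon, Šidák adjustment and Levene's test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import box_epsilon_literal, brute_levene_w, brute_split_plot_ss
from punctakit import (
    DesignError,
    ParameterError,
    gg_epsilon,
    levene_test,
    rm_mixed_anova,
    rm_mixed_anova_matrix,
    sidak_adjust,
    simple_effects,
    simulate_group_table,
)


def random_design(rng, n_cond=None, k=None, n_per=None):
    n_cond = n_cond or int(rng.integers(2, 5))
    k = k or int(rng.integers(3, 7))
    rows = []
    for g in range(n_cond):
        n = n_per or int(rng.integers(3, 9))
        for i in range(n):
            y = rng.normal(g * 0.3, 1.0, size=k) + rng.normal(0, 0.5)
            rows.append(
                pd.DataFrame(
                    {
                        "condition": f"c{g}",
                        "dendrite_id": f"c{g}-s{i}",
                        "time_s": np.arange(k) * 30.0,
                        "rel_fluor": y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


class TestMixedAnova:
    def test_no_within_variation_gives_zero_time_effects(self):
        rows = []
        for g, vals in enumerate([(1.0, 2.0, 3.0), (4.0, 5.0, 6.0)]):
            for i, v in enumerate(vals):
                rows.append(
                    pd.DataFrame(
                        {
                            "condition": f"c{g}",
                            "dendrite_id": f"c{g}-s{i}",
                            "time_s": [0.0, 30.0, 60.0, 90.0],
                            "rel_fluor": v,
                        }
                    )
                )
        res = rm_mixed_anova(pd.concat(rows, ignore_index=True))
        assert res.table.loc["time", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.loc["condition_x_time", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.loc["time", "F"] == 0.0
        assert res.table.loc["time", "p_gg"] == 1.0

    def test_ss_match_brute_force_oracle_on_random_designs(self, rng):
        for _ in range(20):
            table = random_design(rng)
            res = rm_mixed_anova(table)
            wide = table.pivot(index="dendrite_id", columns="time_s", values="rel_fluor")
            wide = wide.sort_index()
            groups = (
                table.drop_duplicates("dendrite_id")
                .set_index("dendrite_id")["condition"]
                .reindex(wide.index)
                .to_numpy()
            )
            want = brute_split_plot_ss(wide.to_numpy(), groups)
            for effect in ("condition", "subject_error", "time", "condition_x_time", "time_error"):
                assert res.table.loc[effect, "ss"] == pytest.approx(
                    want[effect], rel=1e-10, abs=1e-10
                )

    def test_total_ss_conserved(self, rng):
        table = random_design(rng)
        res = rm_mixed_anova(table)
        y = table["rel_fluor"].to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        assert res.table["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_f_invariant_to_shift_and_scale(self, rng):
        table = random_design(rng)
        base = rm_mixed_anova(table)
        for a, b in ((1.0, 5.0), (3.5, 0.0), (0.2, -7.0)):
            t2 = table.copy()
            t2["rel_fluor"] = a * t2["rel_fluor"] + b
            res = rm_mixed_anova(t2)
            for effect in ("condition", "time", "condition_x_time"):
                assert res.table.loc[effect, "F"] == pytest.approx(
                    base.table.loc[effect, "F"], rel=1e-9
                )

    def test_unbalanced_design_rejected(self, rng):
        table = random_design(rng)
        with pytest.raises(DesignError):
            rm_mixed_anova(table.iloc[:-1])

    def test_minimum_design_requirements(self):
        table = simulate_group_table({"a": 1, "b": 2}, {"a": 1.0, "b": 1.0}, n_frames=3)
        with pytest.raises(DesignError):
            rm_mixed_anova(table)

    def test_agrees_with_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        table = simulate_group_table(
            {"a": 8, "b": 8}, {"a": 1.5, "b": 1.0}, n_frames=5, seed=42
        )
        res = rm_mixed_anova(table)
        aov = pg.mixed_anova(
            data=table, dv="rel_fluor", within="time_s", subject="dendrite_id",
            between="condition", correction=True,
        ).set_index("Source")
        assert res.table.loc["condition", "F"] == pytest.approx(
            float(aov.loc["condition", "F"]), rel=1e-8
        )
        assert res.table.loc["time", "F"] == pytest.approx(
            float(aov.loc["time_s", "F"]), rel=1e-8
        )
        assert res.table.loc["condition_x_time", "F"] == pytest.approx(
            float(aov.loc["Interaction", "F"]), rel=1e-8
        )
        # pingouin estimates epsilon from the raw covariance over all
        # subjects; our estimate uses the pooled *within-group* covariance.
        # On group-mean-centered data the two conventions coincide
        # (epsilon is invariant to the scalar df divisor).
        wide = table.pivot(index="dendrite_id", columns="time_s", values="rel_fluor")
        groups = table.drop_duplicates("dendrite_id").set_index("dendrite_id")["condition"]
        centered = wide.groupby(groups.reindex(wide.index)).transform(lambda c: c - c.mean())
        assert res.epsilon == pytest.approx(float(pg.epsilon(centered, correction="gg")), rel=1e-8)

    def test_matrix_and_table_paths_agree(self, rng):
        table = random_design(rng, n_cond=2, k=4, n_per=5)
        wide = table.pivot(index="dendrite_id", columns="time_s", values="rel_fluor").sort_index()
        groups = (
            table.drop_duplicates("dendrite_id")
            .set_index("dendrite_id")["condition"]
            .reindex(wide.index)
            .to_numpy()
        )
        a = rm_mixed_anova(table)
        b = rm_mixed_anova_matrix(wide.to_numpy(), groups)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestGGEpsilon:
    def test_k2_is_always_one(self, rng):
        for _ in range(10):
            A = rng.normal(size=(2, 2))
            S = A @ A.T + np.eye(2)
            assert gg_epsilon(S) == 1.0

    def test_compound_symmetry_is_one(self):
        for k in (3, 5, 13):
            S = np.full((k, k), 0.5) + np.eye(k) * 0.5
            assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_matches_literal_box_formula(self, rng):
        for k in (3, 4, 5, 6):
            for _ in range(5):
                A = rng.normal(size=(k, k + 3))
                S = A @ A.T / (k + 3)
                want = np.clip(box_epsilon_literal(S), 1.0 / (k - 1), 1.0)
                assert gg_epsilon(S) == pytest.approx(want, rel=1e-12)

    def test_bounds_hold(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 8))
            A = rng.normal(size=(k, k + 2))
            eps = gg_epsilon(A @ A.T)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_asymmetric_rejected(self):
        with pytest.raises(ParameterError):
            gg_epsilon(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestSimpleEffects:
    def test_sidak_closed_forms(self):
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2)
        assert sidak_adjust(0.0, 5) == 0.0
        assert sidak_adjust(0.01, 3) == pytest.approx(1 - 0.99**3)
        assert sidak_adjust(0.01, 3) == pytest.approx(0.029701)

    def test_adjusted_p_dominates_raw_p(self, rng):
        p = rng.uniform(0, 1, 50)
        adj = sidak_adjust(p, 4)
        assert np.all(adj >= p)
        assert np.all((adj >= 0) & (adj <= 1))

    def test_omnibus_matches_scipy_per_timepoint(self):
        table = simulate_group_table(
            {"a": 6, "b": 6, "c": 6}, {"a": 1.5, "b": 1.2, "c": 1.0}, n_frames=13, seed=1
        )
        res = simple_effects(table, [90.0, 240.0, 360.0])
        assert len(res.omnibus) == 3
        for _, row in res.omnibus.iterrows():
            sub = table[table["time_s"] == row["time_s"]]
            F, p = sps.f_oneway(
                *[g["rel_fluor"].to_numpy() for _, g in sub.groupby("condition")]
            )
            assert row["F"] == pytest.approx(F, rel=1e-10)
            assert row["p_sidak"] == pytest.approx(float(sidak_adjust(p, 3)), rel=1e-10)
        assert len(res.pairwise) == 3 * 3  # 3 pairs per time point

    def test_absent_timepoint_rejected(self):
        table = simulate_group_table({"a": 3, "b": 3}, {"a": 1.0, "b": 1.0}, n_frames=3)
        with pytest.raises(ParameterError):
            simple_effects(table, [999.0])


class TestLevene:
    def _table(self, groups_of_obs):
        rows = []
        for g, obs in enumerate(groups_of_obs):
            for i, y in enumerate(obs):
                rows.append({"condition": f"c{g}", "dendrite_id": f"c{g}-s{i}",
                             "time_s": 0.0, "rel_fluor": y})
        return pd.DataFrame(rows)

    def test_equal_spread_gives_w_zero(self):
        W, (df1, df2), p = levene_test(self._table([(1.0, 3.0), (5.0, 7.0)]))
        assert W == pytest.approx(0.0, abs=1e-12)
        assert (df1, df2) == (1, 2)

    def test_matches_brute_force_transcription(self, rng):
        for _ in range(20):
            groups = [list(rng.normal(0, 1, size=rng.integers(4, 12))) for _ in range(3)]
            W, _, _ = levene_test(self._table(groups))
            assert W == pytest.approx(brute_levene_w(groups), rel=1e-12)

    def test_detects_gross_variance_ratio(self, rng):
        # SD ratio 10, n = 50/group: p < 0.01 nearly always
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            a = list(rng.normal(0, 1, 50))
            b = list(rng.normal(0, 10, 50))
            _, _, p = levene_test(self._table([a, b]))
            hits += p < 0.01
        assert hits / n_sim >= 0.99

    def test_tiny_group_rejected(self):
        with pytest.raises(DesignError):
            levene_test(self._table([(1.0,), (2.0, 3.0)]))
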