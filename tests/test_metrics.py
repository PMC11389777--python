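"""Exposure and disparity metrics: hand-computed oracles, partition
identities, homogeneity, quantile and decile conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from roadpm import (
    ConfigError,
    MetricError,
    decile_composition,
    exposure_inequality,
    exposure_summary,
    percent_change,
    percentile_disparity,
    pwm,
    relative_disparity,
    weighted_quantile,
)
from roadpm.metrics import fractional_contribution, pwm_total, source_relative_disparity


def pairs_of(conc, **group_pops):
    data = {"concentration": np.asarray(conc, float)}
    for g, p in group_pops.items():
        data[g] = np.asarray(p, float)
    return pd.DataFrame(data)


class TestPWM:
    def test_uniform_field_gives_constant(self):
        p = pairs_of([4.2, 4.2, 4.2], A=[1, 5, 3], B=[2, 0, 1])
        assert pwm(p, "A") == pytest.approx(4.2)
        assert pwm(p, "B") == pytest.approx(4.2)

    def test_hand_weighted_example(self):
        # P=(1,2,1), C=(1,2,3) -> (1 + 4 + 3)/4 = 2.0
        p = pairs_of([1.0, 2.0, 3.0], A=[1, 2, 1])
        assert pwm(p, "A") == pytest.approx(2.0)

    def test_zero_population_undefined(self):
        p = pairs_of([1.0], A=[0.0])
        with pytest.raises(MetricError):
            pwm(p, "A")

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_by_field_range(self, seed):
        rng = np.random.default_rng(seed)
        conc = rng.uniform(0, 10, 8)
        pop = rng.uniform(0, 5, 8)
        pop[rng.integers(0, 8)] += 0.5  # ensure some population
        p = pairs_of(conc, A=pop)
        v = pwm(p, "A")
        occ = conc[pop > 0]
        assert occ.min() - 1e-12 <= v <= occ.max() + 1e-12


class TestDisparities:
    def test_whole_population_group_has_zero_disparity(self):
        # when one group IS the whole population, D_A = D_R = 0
        p = pairs_of([1.0, 5.0], A=[2, 3])
        s = exposure_summary(p, ["A"])
        assert s.loc["A", "d_abs"] == 0.0
        assert s.loc["A", "d_rel"] == 0.0
        assert pwm_total(p, ["A"]) == s.attrs["pwm_total"]

    def test_printed_pwm_pair_gives_45_percent(self):
        # a flagged-community PWM of 1.6 against a statewide 1.1 µg/m³
        assert relative_disparity(1.6, 1.1) == pytest.approx(0.4545, abs=5e-4)

    def test_two_cell_toy_matches_direct_arithmetic(self):
        # all of group A in the high cell
        p = pairs_of([1.0, 3.0], A=[0, 10], B=[10, 0])
        s = exposure_summary(p, ["A", "B"])
        pwm_t = (10 * 1.0 + 10 * 3.0) / 20
        assert s.attrs["pwm_total"] == pytest.approx(pwm_t)
        assert s.loc["A", "d_rel"] == pytest.approx((3.0 - pwm_t) / pwm_t)

    def test_summary_identities_exact(self, small_scenario):
        from roadpm import apply_srm, default_srm_set, exposure_join
        from roadpm import intersect_tracts_with_grid

        scn = small_scenario
        srm = default_srm_set(scn.grid, scn.config.species)
        pop = intersect_tracts_with_grid(scn.tracts, scn.demographics, scn.grid)
        pairs = exposure_join(apply_srm(srm, scn.emissions, 2000), pop)
        s = exposure_summary(pairs, scn.demographics.groups)
        pwm_t = s.attrs["pwm_total"]
        assert np.array_equal(s["d_abs"].to_numpy(), (s["pwm"] - pwm_t).to_numpy())
        assert np.array_equal(s["d_rel"].to_numpy(),
                              (s["d_abs"] / pwm_t).to_numpy())
        # zero-sum: population-weighted mean disparity over the partition
        assert np.sum(s["population"] * s["d_abs"]) == pytest.approx(
            0.0, abs=1e-9 * pwm_t * s["population"].sum()
        )


class TestFractionalContribution:
    def make_summaries(self, das, pops=(10.0, 20.0)):
        """Build source summaries with prescribed per-source D_A for group A."""
        total_da = sum(das)
        idx = pd.Index(["A"], name="group")
        total = pd.DataFrame({"population": [pops[0]], "pwm": [1 + total_da],
                              "d_abs": [total_da], "d_rel": [total_da]}, index=idx)
        total.attrs["pwm_total"] = 1.0
        sources = {}
        for j, da in enumerate(das):
            s = pd.DataFrame({"population": [pops[0]], "pwm": [da],
                              "d_abs": [da], "d_rel": [da]}, index=idx)
            s.attrs["pwm_total"] = 1.0
            sources[f"s{j}"] = s
        return sources, total

    def test_single_source_fraction_is_one(self):
        sources, total = self.make_summaries([0.4])
        ft = fractional_contribution(sources, total)
        assert ft["fraction"].iloc[0] == pytest.approx(1.0)

    def test_equal_sources_split_evenly(self):
        sources, total = self.make_summaries([0.3, 0.3])
        ft = fractional_contribution(sources, total)
        assert np.allclose(ft["fraction"], 0.5)

    def test_three_source_fractions_match_arithmetic_and_sum_to_one(self):
        das = [0.5, -0.1, 0.2]
        sources, total = self.make_summaries(das)
        ft = fractional_contribution(sources, total)
        assert np.allclose(ft["fraction"], np.array(das) / sum(das))
        assert ft["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_near_zero_denominator_flagged_unstable(self):
        sources, total = self.make_summaries([1e-14])
        ft = fractional_contribution(sources, total)
        assert ft["unstable"].all()
        assert ft["fraction"].isna().all()


class TestSourceRelativeDisparity:
    def test_uniform_source_field_zero_for_every_group(self):
        p = pairs_of([2.0, 2.0], A=[1, 0], B=[0, 3])
        s = exposure_summary(p, ["A", "B"])
        assert source_relative_disparity(s, "A") == pytest.approx(0.0)
        assert source_relative_disparity(s, "B") == pytest.approx(0.0)

    def test_full_inventory_reduces_to_relative_disparity(self):
        p = pairs_of([1.0, 3.0], A=[0, 10], B=[10, 0])
        s = exposure_summary(p, ["A", "B"])
        assert source_relative_disparity(s, "A") == pytest.approx(
            relative_disparity(s.loc["A", "pwm"], s.attrs["pwm_total"])
        )

    def test_freight_corridor_group_more_disparately_hit_by_hdv(self):
        # construct the freight corridor inside group-A territory: the
        # group concentrated there sees a larger relative disparity from
        # heavy-duty traffic than from light-duty traffic
        from roadpm import (
            ScenarioConfig, additive_decomposition, default_srm_set,
            exposure_join, generate_scenario, intersect_tracts_with_grid,
        )
        from tests.conftest import SMALL

        cfg = ScenarioConfig(seed=5, segregation=1.0, **SMALL)
        scn = generate_scenario(cfg, coarsest=8000)
        # place all of group A on the freight corridor: reassign counts so
        # A gets B's freight-proximate distribution
        df = scn.demographics.df.copy()
        df["A"], df["B"] = df["B"], df["A"].copy()
        from roadpm import DemographicTable

        demo = DemographicTable(df, scn.demographics.groups)
        srm = default_srm_set(scn.grid, cfg.species)
        pop = intersect_tracts_with_grid(scn.tracts, demo, scn.grid)
        fields = additive_decomposition(srm, scn.emissions, 2000, "fleet")
        drs = {}
        for fleet in ("LDV", "HDV"):
            s = exposure_summary(exposure_join(fields[fleet], pop), demo.groups)
            drs[fleet] = source_relative_disparity(s, "A")
        assert drs["HDV"] > drs["LDV"]


class TestExposureInequality:
    def test_equal_pwms_give_zero(self):
        p = pairs_of([2.0, 2.0], A=[1, 1], B=[1, 1])
        s = exposure_summary(p, ["A", "B"])
        assert exposure_inequality(s, "A", "B") == pytest.approx(0.0)

    def test_factor_of_two(self):
        p = pairs_of([1.0, 2.0], A=[0, 5], B=[5, 0])
        s = exposure_summary(p, ["A", "B"])
        assert exposure_inequality(s, "A", "B") == pytest.approx(1.0)

    def test_equivalent_disparity_ratio_form(self):
        p = pairs_of([1.0, 2.0, 5.0], A=[1, 2, 3], B=[3, 1, 1])
        s = exposure_summary(p, ["A", "B"])
        dr_a = s.loc["A", "d_rel"]
        dr_b = s.loc["B", "d_rel"]
        assert exposure_inequality(s, "A", "B") == pytest.approx(
            (1 + dr_a) / (1 + dr_b) - 1, rel=1e-12
        )


class TestDeciles:
    def test_single_group_population(self):
        rng = np.random.default_rng(0)
        p = pairs_of(rng.uniform(0, 4, 30), A=rng.uniform(1, 2, 30))
        t = decile_composition(p, ["A"])
        assert np.allclose(t["share_A"], 1.0)
        assert np.allclose(t["population"], p["A"].sum() / 10)

    def test_uniform_exposure_gives_overall_composition(self):
        p = pairs_of([3.0] * 4, A=[1, 2, 3, 4], B=[4, 3, 2, 1])
        t = decile_composition(p, ["A", "B"])
        assert np.allclose(t["share_A"], 0.5)
        assert np.allclose(t["share_B"], 0.5)

    def test_twenty_fragments_match_sort_and_cut_oracle(self):
        # 20 equal-population fragments, distinct exposures, alternating
        # groups: each decile holds exactly two fragments
        conc = np.arange(20, dtype=float)
        a = np.tile([1.0, 0.0], 10)
        b = 1.0 - a
        p = pairs_of(conc, A=a, B=b)
        t = decile_composition(p, ["A", "B"])
        assert np.allclose(t["population"], 2.0)
        assert np.allclose(t["share_A"], 0.5)
        # exposure ranges are the consecutive pairs
        assert np.array_equal(t["exposure_min"], conc[::2])
        assert np.array_equal(t["exposure_max"], conc[1::2])

    def test_bins_equal_population_with_fragment_splitting(self):
        rng = np.random.default_rng(3)
        p = pairs_of(rng.uniform(0, 9, 57), A=rng.uniform(0, 3, 57),
                     B=rng.uniform(0, 3, 57))
        t = decile_composition(p, ["A", "B"])
        total = (p["A"] + p["B"]).sum()
        assert np.allclose(t["population"], total / 10, rtol=1e-9)
        # bin exposure ranges are non-overlapping up to ties
        assert (t["exposure_min"].to_numpy()[1:]
                >= t["exposure_max"].to_numpy()[:-1] - 1e-12).all()


class TestQuantiles:
    def test_uniform_field_every_percentile_constant(self):
        p = pairs_of([7.0] * 5, A=np.ones(5))
        q, rel = percentile_disparity(p, "A", 90, ["A"])
        assert q == 7.0
        assert rel == pytest.approx(0.0)

    def test_left_continuous_step_convention(self):
        # two equal fragments C=1, C=3: the 90th percentile is 3, the
        # 50th is 1 (no interpolation)
        assert weighted_quantile([1.0, 3.0], [1.0, 1.0], 90) == 3.0
        assert weighted_quantile([1.0, 3.0], [1.0, 1.0], 50) == 1.0

    def test_against_brute_force_cumulative_scan(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0, 100, 100)
        w = rng.uniform(0, 2, 100)
        for q in (10, 25, 50, 75, 90, 99):
            got = weighted_quantile(v, w, q)
            order = np.argsort(v)
            cum = 0.0
            expected = None
            for i in order:
                cum += w[i]
                if cum >= q / 100 * w.sum():
                    expected = v[i]
                    break
            assert got == expected

    def test_out_of_range_percentile_rejected(self):
        with pytest.raises(ConfigError):
            weighted_quantile([1.0], [1.0], 0.0)
        with pytest.raises(ConfigError):
            weighted_quantile([1.0], [1.0], 100.0)


class TestPercentChange:
    def test_printed_statewide_examples(self):
        assert percent_change(15.0, 9.0) == pytest.approx(-40.0)
        assert percent_change(3.2, 1.1) == pytest.approx(-65.6, abs=0.1)

    def test_identity_and_zero_baseline(self):
        assert percent_change(4.2, 4.2) == 0.0
        with pytest.raises(MetricError):
            percent_change(0.0, 1.0)


class TestHomogeneity:
    def test_scaling_concentrations_scales_pwm_and_leaves_ratios(self):
        rng = np.random.default_rng(2)
        conc = rng.uniform(0, 5, 12)
        p1 = pairs_of(conc, A=rng.uniform(0, 3, 12), B=rng.uniform(0, 3, 12))
        p2 = p1.copy()
        p2["concentration"] = 4.0 * p2["concentration"]  # exact in binary fp
        s1 = exposure_summary(p1, ["A", "B"])
        s2 = exposure_summary(p2, ["A", "B"])
        assert np.array_equal(4.0 * s1["pwm"].to_numpy(), s2["pwm"].to_numpy())
        assert np.array_equal(s1["d_rel"].to_numpy(), s2["d_rel"].to_numpy())
        t1 = decile_composition(p1, ["A", "B"])
        t2 = decile_composition(p2, ["A", "B"])
        assert np.array_equal(t1["share_A"].to_numpy(), t2["share_A"].to_numpy())
        assert exposure_inequality(s1, "A", "B") == exposure_inequality(s2, "A", "B")
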