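import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_block_annual
from oracles import corrected_relative_yield, loreau_hector

from overyield import (
    build_reference_set,
    effects_table,
    partition_effects,
    relative_yields,
)
from overyield.effects import CLOVER_N1_PROVENANCE


class TestReferenceSet:
    @staticmethod
    def _annual_with_grass_blocks(yields, n_level="N0"):
        rows = []
        for i, y in enumerate(yields, start=1):
            rows.append(dict(site="R", block=f"B{i}", plot=f"g{i}",
                             composition="pure_grass", population="",
                             n_level=n_level, replicate_id=1, year=1,
                             yield_clover=0.0, yield_grass=y, yield_chicory=0.0,
                             yield_nonsown=0.0, total_sown_yield=y))
        return pd.DataFrame(rows)

    def test_cross_block_mean(self):
        annual = self._annual_with_grass_blocks([8.0, 10.0, 9.0, 9.0])
        refs = build_reference_set(annual, "N0", "R", 1)
        assert refs.m("grass") == pytest.approx(9.0)

    def test_constant_blocks_give_constant_mean(self):
        annual = self._annual_with_grass_blocks([7.5] * 4)
        refs = build_reference_set(annual, "N0", "R", 1)
        assert refs.m("grass") == pytest.approx(7.5)

    def test_n1_clover_reference_flagged_as_unfertilized(self):
        annual = make_block_annual()
        refs = build_reference_set(annual, "N1", "R", 1)
        prov = refs.block_refs
        clover_prov = prov.loc[prov["species"] == "clover", "provenance"].unique()
        assert list(clover_prov) == [CLOVER_N1_PROVENANCE]
        # grass/chicory must come from fertilized stands, absent here
        assert np.isnan(refs.block_ref("grass", "B1"))
        assert "no grass pure-stand reference in block B1" in refs.issues

    def test_population_matched_clover_reference(self):
        a1 = make_block_annual(population="T1", clover_pure=8.0)
        a2 = make_block_annual(population="T2", clover_pure=6.0)
        a2 = a2.assign(plot=a2["plot"] + "x")
        annual = pd.concat([a1, a2], ignore_index=True)
        refs = build_reference_set(annual, "N0", "R", 1)
        assert refs.block_ref("clover", "B1", "T1") == pytest.approx(8.0)
        assert refs.block_ref("clover", "B1", "T2") == pytest.approx(6.0)


class TestRelativeYields:
    def test_hand_example(self):
        ry = relative_yields(6.0, 10.0, 0.4)
        assert ry.ry_o == pytest.approx(0.6, abs=1e-12)
        assert ry.delta_ry == pytest.approx(0.2, abs=1e-12)
        assert ry.ry_c == pytest.approx(1.5, abs=1e-12)

    def test_proportional_yield_identity(self):
        ry = relative_yields(0.4 * 12.0, 12.0, 0.4)
        assert ry.ry_c == pytest.approx(1.0, abs=1e-12)
        assert ry.delta_ry == pytest.approx(0.0, abs=1e-12)

    def test_absent_species(self):
        ry = relative_yields(0.0, 9.0, 0.6)
        assert ry.ry_o == 0.0
        assert ry.delta_ry == pytest.approx(-0.6)
        assert ry.ry_c == 0.0

    def test_zero_reference_flagged_not_imputed(self):
        ry = relative_yields(3.0, 0.0, 0.4)
        assert ry.flag is not None
        assert np.isnan(ry.ry_c)


class TestPartition:
    def test_worked_example_exact(self):
        eff = partition_effects(
            {"a": 6.0, "b": 4.0}, {"a": 10.0, "b": 6.0}, {"a": 0.4, "b": 0.6}
        )
        assert eff.ne == pytest.approx(2.4, abs=1e-12)
        assert eff.ce == pytest.approx(32.0 / 15.0, abs=1e-12)
        assert eff.se == pytest.approx(4.0 / 15.0, abs=1e-12)
        oracle = loreau_hector([6.0, 4.0], [10.0, 6.0], [0.4, 0.6])
        assert eff.ce == pytest.approx(oracle["CE"], abs=1e-12)
        assert eff.se == pytest.approx(oracle["SE"], abs=1e-12)
        rys = [corrected_relative_yield(6.0, 10.0, 0.4),
               corrected_relative_yield(4.0, 6.0, 0.6)]
        assert rys[0]["RY_C"] == pytest.approx(1.5, abs=1e-12)
        assert rys[1]["RY_C"] == pytest.approx(10.0 / 9.0, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 3),
        data=st.data(),
    )
    def test_identity_and_oracle_on_random_yields(self, n, data):
        pos = st.floats(0.05, 30.0, allow_nan=False)
        y = [data.draw(pos) for _ in range(n)]
        m = [data.draw(pos) for _ in range(n)]
        rye = [0.4, 0.6] if n == 2 else [0.4, 0.3, 0.3]
        sp = [f"s{i}" for i in range(n)]
        eff = partition_effects(dict(zip(sp, y)), dict(zip(sp, m)), dict(zip(sp, rye)))
        scale = max(abs(eff.ne), abs(eff.ce), abs(eff.se), 1e-6)
        assert abs(eff.ne - (eff.ce + eff.se)) <= 1e-12 * scale
        oracle = loreau_hector(y, m, rye)
        assert eff.ce == pytest.approx(oracle["CE"], rel=1e-12, abs=1e-12)
        assert eff.se == pytest.approx(oracle["SE"], rel=1e-12, abs=1e-12)
        assert eff.ne == pytest.approx(oracle["NE"], rel=1e-12, abs=1e-12)

    def test_equal_deviations_zero_selection(self):
        # dRY identical for both species -> zero covariance -> SE = 0
        m = {"a": 10.0, "b": 6.0}
        rye = {"a": 0.4, "b": 0.6}
        y = {"a": (0.1 + 0.4) * 10.0, "b": (0.1 + 0.6) * 6.0}
        eff = partition_effects(y, m, rye)
        assert eff.se == pytest.approx(0.0, abs=1e-12)
        assert eff.ne == pytest.approx(eff.ce, abs=1e-12)
        assert np.sign(eff.ce) == 1.0

    def test_null_case_all_zero(self):
        m = {"a": 10.0, "b": 6.0}
        rye = {"a": 0.4, "b": 0.6}
        y = {k: rye[k] * m[k] for k in m}
        eff = partition_effects(y, m, rye)
        for v in (eff.ne, eff.ce, eff.se):
            assert v == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100.0), data=st.data())
    def test_scale_equivariance(self, c, data):
        pos = st.floats(0.1, 20.0)
        y = {s: data.draw(pos) for s in ("a", "b")}
        m = {s: data.draw(pos) for s in ("a", "b")}
        rye = {"a": 0.4, "b": 0.6}
        eff = partition_effects(y, m, rye)
        eff_c = partition_effects({k: c * v for k, v in y.items()},
                                  {k: c * v for k, v in m.items()}, rye)
        assert eff_c.ne == pytest.approx(c * eff.ne, rel=1e-9)
        assert eff_c.ce == pytest.approx(c * eff.ce, rel=1e-9)
        assert eff_c.se == pytest.approx(c * eff.se, rel=1e-9)
        # relative yields are scale-free
        ry = relative_yields(y["a"], m["a"], 0.4)
        ry_c = relative_yields(c * y["a"], c * m["a"], 0.4)
        assert ry_c.ry_c == pytest.approx(ry.ry_c, rel=1e-9)

    def test_sign_law(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            y = rng.uniform(0.1, 20, 2)
            m = rng.uniform(0.1, 20, 2)
            rye = np.array([0.4, 0.6])
            eff = partition_effects(dict(zip("ab", y)), dict(zip("ab", m)),
                                    dict(zip("ab", rye)))
            mean_dry = (y / m - rye).mean()
            if abs(mean_dry) > 1e-12:
                assert np.sign(eff.ce) == np.sign(mean_dry)


class TestEffectsTable:
    def test_single_tl_plot_year(self):
        annual = make_block_annual(tl=(2.4, 5.2))
        eff, spc = effects_table(annual, baselines=("N0",))
        assert len(eff) == 1
        assert len(spc) == 2
        row = eff.iloc[0]
        # single block: M equals the within-block reference
        oracle = loreau_hector([2.4, 5.2], [8.0, 10.0], [0.4, 0.6])
        assert row["NE"] == pytest.approx(oracle["NE"], abs=1e-12)
        assert row["CE"] == pytest.approx(oracle["CE"], abs=1e-12)
        assert row["SE"] == pytest.approx(oracle["SE"], abs=1e-12)

    def test_full_design_row_counts(self, null_study):
        eff, spc = null_study
        counts = eff.groupby("baseline").size()
        # 2 sites x 4 blocks x 8 populations x 3 mixture types x 5 years
        assert (counts == 960).all()

    def test_identity_holds_across_noisy_full_design(self, facilitation_study):
        eff, _ = facilitation_study
        ok = eff[eff["flags"] == ""]
        scale = ok[["NE", "CE", "SE"]].abs().to_numpy().max()
        err = (ok["NE"] - ok["CE"] - ok["SE"]).abs().max()
        assert err <= 1e-9 * scale

    def test_table_matches_per_plot_brute_force(self):
        # independent path: loop over plots, rebuild references by hand,
        # evaluate the partition with the loop oracle
        rng = np.random.default_rng(11)
        blocks = ["B1", "B2"]
        frames = []
        for b in blocks:
            a = make_block_annual(
                clover_pure=rng.uniform(4, 10), grass_pure=rng.uniform(4, 10),
                chicory_pure=rng.uniform(4, 10),
                tl=(rng.uniform(1, 4), rng.uniform(2, 6)), block=b,
            )
            a["plot"] = a["plot"] + b
            frames.append(a)
        annual = pd.concat(frames, ignore_index=True)
        eff, spc = effects_table(annual, baselines=("N0",))
        m_clover = annual.loc[annual["composition"] == "pure_clover",
                              "yield_clover"].mean()
        m_grass = annual.loc[annual["composition"] == "pure_grass",
                             "yield_grass"].mean()
        for b in blocks:
            row = eff[(eff["block"] == b)].iloc[0]
            tl = annual[(annual["composition"] == "TL") & (annual["block"] == b)]
            y = [tl["yield_clover"].iloc[0], tl["yield_grass"].iloc[0]]
            oracle = loreau_hector(y, [m_clover, m_grass], [0.4, 0.6])
            for key in ("NE", "CE", "SE", "Y_O", "Y_E"):
                assert row[key] == pytest.approx(oracle[key], rel=1e-12)
            block_pure = annual[(annual["block"] == b)
                                & (annual["composition"] == "pure_grass")]
            ry = corrected_relative_yield(
                y[1], block_pure["yield_grass"].iloc[0], 0.6
            )
            g = spc[(spc["block"] == b) & (spc["species"] == "grass")].iloc[0]
            assert g["RY_C"] == pytest.approx(ry["RY_C"], rel=1e-12)
            assert g["RY_O"] == pytest.approx(ry["RY_O"], rel=1e-12)

    def test_missing_chicory_reference_flags_only_its_mixtures(self):
        a = make_block_annual()
        tc = a[a["composition"] == "TL"].assign(
            composition="TC", plot="p5",
            yield_grass=0.0, yield_chicory=3.0,
            total_sown_yield=lambda d: d["yield_clover"] + 3.0,
        )
        annual = pd.concat([a[a["composition"] != "pure_chicory"], tc],
                           ignore_index=True)
        eff, _ = effects_table(annual, baselines=("N0",))
        tl_row = eff[eff["mixtype"] == "TL"].iloc[0]
        tc_row = eff[eff["mixtype"] == "TC"].iloc[0]
        assert tl_row["flags"] == ""
        assert "chicory" in tc_row["flags"]
        assert np.isnan(tc_row["CE"])

    def test_zero_pure_stand_flagged(self):
        annual = make_block_annual(grass_pure=0.0)
        eff, spc = effects_table(annual, baselines=("N0",))
        assert "grass" in eff.iloc[0]["flags"]
        g = spc[spc["species"] == "grass"].iloc[0]
        assert g["flags"] != ""

    def test_clover_ryc_absent_under_n1_by_default(self, facilitation_study):
        _, spc = facilitation_study
        n1 = spc[spc["baseline"] == "N1"]
        assert set(n1["species"]) == {"grass", "chicory"}

    def test_clover_ryc_n1_opt_in_with_provenance(self):
        annual = make_block_annual()
        grass_n1 = annual[annual["composition"] == "pure_grass"].assign(
            n_level="N1", plot="p2f", yield_grass=18.0, total_sown_yield=18.0
        )
        annual = pd.concat([annual, grass_n1], ignore_index=True)
        _, spc = effects_table(annual, clover_ryc_n1=True)
        n1_clover = spc[(spc["baseline"] == "N1") & (spc["species"] == "clover")]
        assert len(n1_clover) == 1
        assert n1_clover.iloc[0]["reference_provenance"] == CLOVER_N1_PROVENANCE

    def test_baseline_monotonicity_for_nonlegumes(self, facilitation_study):
        # fertilized references yield more, so non-legume RY_C under N1 must
        # not exceed RY_C under N0 anywhere the references are ordered
        _, spc = facilitation_study
        piv = spc[spc["species"].isin(["grass", "chicory"])].pivot_table(
            index=["site", "block", "plot", "year", "species"],
            columns="baseline", values="RY_C",
        ).dropna()
        assert (piv["N1"] <= piv["N0"] + 1e-12).all()
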