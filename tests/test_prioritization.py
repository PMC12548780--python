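"""Chain merging, preventable-deaths scoring and sunburst conservation."""

import numpy as np
import pandas as pd
import pytest

from fbdrank import prioritization as prio
from fbdrank.errors import PrioritizationError
from fbdrank.prioritization import (
    SCCP, PointAllocation, ValueChain, preventable_deaths, rank_sccps,
    select_top_chains, sunburst_hierarchy,
)
from fbdrank.synthetic import generate_sccp_scenario, preventable_deaths_oracle

CATS = prio.CATEGORIES


def simple_chain(n_sccps=3, chain_id="c"):
    sccps = tuple(SCCP(f"s{i}", "stage1", "") for i in range(n_sccps))
    return ValueChain(chain_id=chain_id, food_groups=("g",),
                      stages=("stage1",), sccps=sccps)


def table_from(rows):
    t = pd.DataFrame.from_dict(rows, orient="index",
                               columns=list(CATS)).astype(float)
    t["total"] = t.sum(axis=1)
    t.index.name = "food_group"
    return t


class TestMergeFoodGroups:
    def test_merged_rows_sum_members(self):
        table = table_from({
            "poultry": (897, 683, 4), "eggs": (298, 228, 2)})
        chain = ValueChain(chain_id="poultry_eggs",
                           food_groups=("poultry", "eggs"),
                           stages=("s",), sccps=())
        merged = prio.merge_food_groups(table, [chain])
        assert merged.loc["poultry_eggs", "anthroponotic"] == 1195
        assert merged.loc["poultry_eggs", "zoonotic"] == 911
        assert merged.loc["poultry_eggs", "total"] == 2112

    def test_single_member_identity(self):
        table = table_from({"veg": (1560, 235, 125)})
        chain = ValueChain(chain_id="veg_chain", food_groups=("veg",),
                           stages=("s",), sccps=())
        merged = prio.merge_food_groups(table, [chain])
        assert merged.loc["veg_chain"].tolist() == table.loc["veg"].tolist()

    def test_empty_member_list_rejected(self):
        with pytest.raises(PrioritizationError):
            ValueChain(chain_id="x", food_groups=(), stages=(), sccps=())

    def test_missing_member_group_errors(self):
        table = table_from({"veg": (1, 1, 1)})
        chain = ValueChain(chain_id="x", food_groups=("beef",),
                           stages=("s",), sccps=())
        with pytest.raises(PrioritizationError, match="beef"):
            prio.merge_food_groups(table, [chain])


class TestSelectTopChains:
    @staticmethod
    def ethiopia_chain_table():
        return table_from({
            "vegetables": (1560, 235, 125),
            "dairy": (1478, 371, 13),
            "poultry_eggs": (1195, 911, 6),
            "beef_small_ruminant": (1841, 401, 19),
        })

    @staticmethod
    def chains():
        return [simple_chain(chain_id=c) for c in
                ("vegetables", "dairy", "poultry_eggs", "beef_small_ruminant")]

    def test_published_totals_order(self):
        top = select_top_chains(self.ethiopia_chain_table(), self.chains(), 4)
        assert [c.chain_id for c in top] == [
            "beef_small_ruminant", "poultry_eggs", "vegetables", "dairy"]

    def test_k1_largest(self):
        top = select_top_chains(self.ethiopia_chain_table(), self.chains(), 1)
        assert [c.chain_id for c in top] == ["beef_small_ruminant"]

    def test_k_too_large_rejected(self):
        with pytest.raises(PrioritizationError):
            select_top_chains(self.ethiopia_chain_table(), self.chains(), 5)


class TestPreventableDeaths:
    def test_point_share_arithmetic(self):
        # 30/20/50 split of the published 1560 anthroponotic vegetable deaths
        chain = simple_chain(3)
        alloc = PointAllocation("c", {
            ("s0", "anthroponotic"): 30, ("s1", "anthroponotic"): 20,
            ("s2", "anthroponotic"): 50})
        p = preventable_deaths(chain, alloc, {"anthroponotic": 1560},
                               categories=("anthroponotic",))
        assert p.values[("s0", "anthroponotic")] == pytest.approx(468)
        assert p.values[("s1", "anthroponotic")] == pytest.approx(312)
        assert p.values[("s2", "anthroponotic")] == pytest.approx(780)

    def test_single_sccp_gets_everything(self):
        chain = simple_chain(1)
        alloc = PointAllocation("c", {("s0", c): 5.0 for c in CATS})
        deaths = {"anthroponotic": 10.0, "zoonotic": 20.0, "chemical": 5.0}
        p = preventable_deaths(chain, alloc, deaths)
        assert p.total == pytest.approx(35.0)
        assert p.sccp_total("s0") == pytest.approx(35.0)

    def test_point_scale_invariance(self):
        chain = simple_chain(3)
        pts = {(f"s{i}", c): float(i + 1) for i in range(3) for c in CATS}
        deaths = {c: 100.0 for c in CATS}
        p1 = preventable_deaths(chain, PointAllocation("c", pts), deaths)
        p10 = preventable_deaths(
            chain, PointAllocation("c", {k: 10 * v for k, v in pts.items()}),
            deaths)
        for key in p1.values:
            assert p1.values[key] == pytest.approx(p10.values[key])

    def test_zero_points_with_deaths_names_category(self):
        chain = simple_chain(2)
        alloc = PointAllocation("c", {("s0", "anthroponotic"): 1.0})
        with pytest.raises(PrioritizationError, match="zoonotic"):
            preventable_deaths(chain, alloc,
                               {"anthroponotic": 5.0, "zoonotic": 5.0})

    def test_category_conservation(self):
        chain, alloc, _ = generate_sccp_scenario(seed=4)
        deaths = {c: 100.0 * (i + 1) for i, c in enumerate(CATS)}
        p = preventable_deaths(chain, alloc, deaths)
        for c in CATS:
            assert p.category_total(c) == pytest.approx(deaths[c], rel=1e-12)


class TestRankSccps:
    def test_descending_totals(self):
        chain = simple_chain(2)
        alloc = PointAllocation("c", {("s0", "anthroponotic"): 5,
                                      ("s1", "anthroponotic"): 2})
        p = preventable_deaths(chain, alloc, {"anthroponotic": 700},
                               categories=("anthroponotic",))
        ranked = rank_sccps(p)
        assert ranked[0][0] == "s0" and ranked[0][1] == pytest.approx(500)

    def test_all_equal_preserves_input_order(self):
        chain = simple_chain(3)
        alloc = PointAllocation("c", {(f"s{i}", "anthroponotic"): 1.0
                                      for i in range(3)})
        p = preventable_deaths(chain, alloc, {"anthroponotic": 9.0},
                               categories=("anthroponotic",))
        assert [s for s, _ in rank_sccps(p)] == ["s0", "s1", "s2"]

    def test_top_is_argmax_on_random_instances(self):
        for seed in range(30):
            chain, alloc, expected = generate_sccp_scenario(seed=seed)
            deaths = {c: 50.0 for c in CATS}
            exp = preventable_deaths_oracle(chain, alloc, deaths, CATS)
            p = preventable_deaths(chain, alloc, deaths)
            ranked = rank_sccps(p)
            brute = {s: sum(exp[(s, c)] for c in CATS) for s in chain.sccp_ids}
            assert ranked[0][1] == pytest.approx(max(brute.values()))


class TestSunburst:
    def test_three_level_path_single_cell(self):
        chain = simple_chain(1)
        alloc = PointAllocation("c", {("s0", "anthroponotic"): 1.0})
        p = preventable_deaths(chain, alloc, {"anthroponotic": 42.0},
                               categories=("anthroponotic",))
        tree = sunburst_hierarchy(chain, p)
        assert tree["value"] == pytest.approx(42.0)
        stage = tree["children"][0]
        sccp = stage["children"][0]
        leaf = next(l for l in sccp["children"] if l["name"] == "anthroponotic")
        assert stage["value"] == sccp["value"] == leaf["value"] == 42.0

    def test_level_sums_conserved_on_random_instances(self):
        for seed in range(20):
            chain, alloc, _ = generate_sccp_scenario(seed=seed)
            deaths = {c: float(100 + seed * 7 + i) for i, c in enumerate(CATS)}
            p = preventable_deaths(chain, alloc, deaths)
            tree = sunburst_hierarchy(chain, p)
            assert tree["value"] == pytest.approx(p.total, rel=1e-9)
            for stage in tree["children"]:
                assert stage["value"] == pytest.approx(
                    sum(n["value"] for n in stage["children"]), rel=1e-9)
                for sccp in stage["children"]:
                    assert sccp["value"] == pytest.approx(
                        sum(l["value"] for l in sccp["children"]), rel=1e-9)

    def test_round_trip_serialization(self, tmp_path):
        chain, alloc, _ = generate_sccp_scenario(seed=1)
        p = preventable_deaths(chain, alloc, {c: 10.0 for c in CATS})
        tree = sunburst_hierarchy(chain, p)
        path = tmp_path / "sunburst.json"
        prio.write_sunburst(tree, path)
        assert prio.read_sunburst(path) == tree


class TestEthiopiaChains:
    def test_published_sccp_counts(self, chains_and_allocations):
        chains, allocs = chains_and_allocations
        counts = {c.chain_id: len(c.sccps) for c in chains}
        assert counts == {"vegetables": 7, "dairy": 10, "poultry_eggs": 20,
                          "beef_small_ruminant": 10}
        assert set(allocs) == set(counts)

    def test_replay_chain_totals_match_published_rows(
            self, chains_and_allocations, attributed_deaths_fixture, retained):
        from fbdrank.attribution import aggregate_by_category
        chains, allocs = chains_and_allocations
        table = aggregate_by_category(attributed_deaths_fixture, retained)
        merged = prio.merge_food_groups(table, chains)
        assert merged.loc["vegetables", "total"] == 1920
        assert merged.loc["dairy", "total"] == 1862
        assert merged.loc["poultry_eggs", "total"] == 2112
        assert merged.loc["beef_small_ruminant", "total"] == 2261
        # preventable deaths conserve each chain's published total
        for chain in chains:
            p = preventable_deaths(chain, allocs[chain.chain_id],
                                   merged.loc[chain.chain_id].to_dict())
            assert p.total == pytest.approx(
                merged.loc[chain.chain_id, "total"], rel=1e-9)
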