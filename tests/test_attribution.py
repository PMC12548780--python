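"""Delphi aggregation, fixed/restricted food groups, death attribution."""

import numpy as np
import pandas as pd
import pytest

from fbdrank import attribution as attr
from fbdrank.attribution import AttributionMatrix, ExpertResponse
from fbdrank.errors import AttributionError
from fbdrank.hazard_registry import Hazard
from fbdrank.synthetic import generate_attribution_truth, generate_expert_panel


def resp(expert, hz, round_, **props):
    return ExpertResponse(expert_id=expert, round=round_, hazard_id=hz,
                          proportions=props)


def matrix(data, deaths=None, groups=None):
    frame = pd.DataFrame.from_dict(data, orient="index")
    if groups:
        frame.columns = groups
    s = pd.Series(deaths) if deaths is not None else None
    return AttributionMatrix(proportions=frame, deaths=s)


class TestNormalizeResponse:
    def test_rescaling(self):
        r = attr.normalize_response(resp("e", "h", 1, a=2.0, b=1.0, c=1.0))
        assert r.proportions == {"a": 0.5, "b": 0.25, "c": 0.25}

    def test_already_normalized_unchanged(self):
        r = attr.normalize_response(resp("e", "h", 1, a=0.6, b=0.4))
        assert r.proportions == {"a": 0.6, "b": 0.4}

    def test_all_zero_names_expert_and_hazard(self):
        with pytest.raises(AttributionError, match="'e1'.*'hz9'"):
            attr.normalize_response(resp("e1", "hz9", 1, a=0.0, b=0.0))


class TestDelphiAggregate:
    def test_single_expert_is_their_normalized_vector(self):
        m = attr.delphi_aggregate([resp("e", "h", 1, a=2.0, b=2.0)])
        assert m.proportions.loc["h"].tolist() == [0.5, 0.5]

    def test_mean_of_two_experts(self):
        m = attr.delphi_aggregate([
            resp("e1", "h", 1, a=0.8, b=0.2),
            resp("e2", "h", 1, a=0.6, b=0.4),
        ])
        assert m.proportions.loc["h", "a"] == pytest.approx(0.7)
        assert m.proportions.loc["h", "b"] == pytest.approx(0.3)

    def test_round2_revision_overrides_round1(self):
        m = attr.delphi_aggregate([
            resp("A", "h", 1, a=1.0, b=0.0),
            resp("A", "h", 2, a=0.5, b=0.5),
            resp("B", "h", 1, a=0.5, b=0.5),
        ])
        assert m.proportions.loc["h"].tolist() == pytest.approx([0.5, 0.5])

    def test_team_pseudo_expert_weighting(self):
        m = attr.delphi_aggregate(
            [resp("e", "h", 1, a=1.0, b=0.0)],
            team_estimates={"h": {"a": 0.0, "b": 1.0}}, team_weight=1.0)
        assert m.proportions.loc["h"].tolist() == pytest.approx([0.5, 0.5])
        m3 = attr.delphi_aggregate(
            [resp("e", "h", 1, a=1.0, b=0.0)],
            team_estimates={"h": {"a": 0.0, "b": 1.0}}, team_weight=3.0)
        assert m3.proportions.loc["h", "b"] == pytest.approx(0.75)

    def test_order_and_split_invariance(self):
        responses = [
            resp("e1", "h1", 1, a=0.2, b=0.8), resp("e2", "h1", 1, a=0.6, b=0.4),
            resp("e1", "h2", 1, a=1.0, b=0.0), resp("e2", "h2", 1, a=0.5, b=0.5),
        ]
        m1 = attr.delphi_aggregate(responses)
        m2 = attr.delphi_aggregate(list(reversed(responses)))
        pd.testing.assert_frame_equal(m1.proportions, m2.proportions)


class TestFixedAndRestricted:
    REGISTRY = [
        Hazard(id="m_bovis", name="M. bovis", hazard_class="bacterium",
               origin="FERG", ecology="zoonotic", fixed_food_group="dairy"),
        Hazard(id="nts", name="NTS", hazard_class="bacterium", origin="FERG",
               ecology="zoonotic"),
    ]

    def test_fixed_row_becomes_point_mass(self):
        m = matrix({"m_bovis": {"dairy": 0.3, "beef": 0.7},
                    "nts": {"dairy": 0.5, "beef": 0.5}})
        out = attr.apply_fixed_attributions(m, self.REGISTRY)
        assert out.proportions.loc["m_bovis"].tolist() == [1.0, 0.0]
        assert out.proportions.loc["nts"].tolist() == [0.5, 0.5]

    def test_no_fixed_hazards_unchanged(self):
        m = matrix({"nts": {"dairy": 0.5, "beef": 0.5}})
        out = attr.apply_fixed_attributions(m, [self.REGISTRY[1]])
        pd.testing.assert_frame_equal(out.proportions, m.proportions)

    def test_missing_fixed_group_errors(self):
        m = matrix({"m_bovis": {"beef": 1.0}})
        with pytest.raises(AttributionError, match="dairy"):
            attr.apply_fixed_attributions(m, self.REGISTRY)

    def test_restrict_renormalizes(self):
        m = matrix({"h": {"pork": 0.5, "beef": 0.5}})
        out = attr.restrict_food_groups(m, {"pork"})
        assert out.proportions.loc["h"].tolist() == [1.0]

    def test_restrict_zero_column_no_change(self):
        m = matrix({"h": {"pork": 0.0, "beef": 1.0}})
        out = attr.restrict_food_groups(m, {"pork"})
        assert out.proportions.loc["h", "beef"] == 1.0

    def test_row_losing_all_mass_errors(self):
        m = matrix({"h": {"pork": 1.0, "beef": 0.0}})
        with pytest.raises(AttributionError, match="h"):
            attr.restrict_food_groups(m, {"pork"})


class TestAttributeDeaths:
    def test_proportional_split(self):
        m = matrix({"h": {"a": 0.6, "b": 0.3, "c": 0.1}}, deaths={"h": 100.0})
        out = attr.attribute_deaths(m)
        assert out.deaths.loc["h"].tolist() == pytest.approx([60, 30, 10])

    def test_zero_death_hazard_zero_row(self):
        m = matrix({"h": {"a": 0.5, "b": 0.5}}, deaths={"h": 0.0})
        assert attr.attribute_deaths(m).deaths.loc["h"].sum() == 0.0

    def test_conservation_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_h, n_g = rng.integers(2, 8), rng.integers(2, 6)
            props = rng.dirichlet(np.ones(n_g), size=n_h)
            deaths = rng.uniform(0, 5000, n_h)
            m = AttributionMatrix(
                proportions=pd.DataFrame(
                    props, index=[f"h{i}" for i in range(n_h)]),
                deaths=pd.Series(deaths, index=[f"h{i}" for i in range(n_h)]),
            )
            out = attr.attribute_deaths(m)
            np.testing.assert_allclose(
                out.by_hazard.to_numpy(), deaths, rtol=1e-9)


class TestAggregateByCategory:
    REGISTRY = [
        Hazard(id=f"h{i}", name=f"h{i}", hazard_class="bacterium",
               origin="FERG", ecology=eco)
        for i, eco in enumerate(
            ["anthroponotic", "anthroponotic", "zoonotic", "chemical"])
    ]

    def test_sums_within_category(self):
        deaths = pd.DataFrame(
            {"veg": [100.0, 200.0, 50.0, 25.0], "dairy": [0.0, 10.0, 5.0, 1.0]},
            index=[f"h{i}" for i in range(4)])
        table = attr.aggregate_by_category(
            attr.AttributedDeaths(deaths=deaths), self.REGISTRY)
        assert table.loc["veg", "anthroponotic"] == 300.0
        assert table.loc["veg", "zoonotic"] == 50.0
        assert table.loc["veg", "total"] == 375.0

    def test_permutation_invariance(self):
        deaths = pd.DataFrame(
            {"veg": [1.0, 2.0, 3.0, 4.0]}, index=[f"h{i}" for i in range(4)])
        a = attr.aggregate_by_category(
            attr.AttributedDeaths(deaths=deaths), self.REGISTRY)
        b = attr.aggregate_by_category(
            attr.AttributedDeaths(deaths=deaths.iloc[::-1]), self.REGISTRY)
        pd.testing.assert_frame_equal(a, b)

    def test_unassigned_ecology_rejected(self):
        registry = [Hazard(id="h0", name="x", hazard_class="bacterium",
                           origin="FERG")]  # ecology unassigned
        deaths = pd.DataFrame({"veg": [1.0]}, index=["h0"])
        with pytest.raises(AttributionError, match="ecology"):
            attr.aggregate_by_category(
                attr.AttributedDeaths(deaths=deaths), registry)

    def test_ethiopia_fixture_reproduces_published_totals(
            self, attributed_deaths_fixture, retained):
        table = attr.aggregate_by_category(attributed_deaths_fixture, retained)
        merged = {
            "vegetables": table.loc["vegetables"],
            "dairy": table.loc["dairy"],
            "poultry_eggs": table.loc["poultry"] + table.loc["eggs"],
            "beef_smr": table.loc["beef"] + table.loc["small_ruminant_meat"],
        }
        assert merged["vegetables"]["total"] == 1920
        assert merged["dairy"]["total"] == 1862
        assert merged["poultry_eggs"]["total"] == 2112
        assert merged["beef_smr"]["total"] == 2261
        # grand total conserves the per-hazard totals
        assert table["total"].sum() == pytest.approx(
            attributed_deaths_fixture.total)


class TestDelphiRecovery:
    def test_rmse_decreases_with_expert_count(self):
        truth = generate_attribution_truth(
            [f"h{i}" for i in range(6)],
            ["veg", "dairy", "poultry", "beef"], seed=0, alpha=2.0)
        rmse = {}
        for n_experts in (3, 15, 50):
            errs = []
            for seed in range(20):
                panel = generate_expert_panel(
                    truth, n_experts=n_experts, concentration=100.0,
                    seed=seed, n_revising=0)
                agg = attr.delphi_aggregate(panel)
                diff = (agg.proportions[truth.columns].loc[truth.index]
                        - truth).to_numpy()
                errs.append(np.sqrt((diff ** 2).mean()))
            rmse[n_experts] = np.mean(errs)
        assert rmse[3] > rmse[15] > rmse[50]


class TestBootstrap:
    def test_interval_brackets_point_estimate(self):
        truth = generate_attribution_truth(["h0", "h1"], ["a", "b", "c"],
                                           seed=1)
        panel = generate_expert_panel(truth, n_experts=10, concentration=50.0,
                                      seed=2, n_revising=0)
        point = attr.delphi_aggregate(panel)
        bands = attr.bootstrap_attribution(panel, n_boot=100, seed=3)
        assert (bands["lower95"].to_numpy()
                <= point.proportions.to_numpy() + 1e-9).all()
        assert (bands["upper95"].to_numpy()
                >= point.proportions.to_numpy() - 1e-9).all()
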