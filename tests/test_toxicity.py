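"""Consensus LD50 resolution, preference hierarchy, and imputation."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beeload import toxicity
from beeload.keys import CompoundKey
from beeload.toxicity import (
    ConsensusLD50,
    ToxicityEndpoint,
    consensus_for_compound,
    filter_acute_adult,
    impute_unresolved,
)


def ep(value, qualifier="point", regulatory=False, route="contact",
       days=2.0, stage="adult", compound="X"):
    return ToxicityEndpoint(
        compound=compound,
        route=route,
        value_ug_per_bee=value,
        qualifier=qualifier,
        regulatory=regulatory,
        exposure_days=days,
        life_stage=stage,
        source="ecotox",
    )


# --- independent brute-force oracle for the consensus rules ---------------

def oracle_consensus(endpoints, route):
    """Literal restatement of the resolution rules, no shared code paths."""
    eps = [e for e in endpoints
           if e.route == route and e.life_stage == "adult" and e.exposure_days <= 4]
    if not eps:
        return None
    points = [e.value_ug_per_bee for e in eps if e.qualifier == "point"]
    reg_points = [e.value_ug_per_bee for e in eps
                  if e.qualifier == "point" and e.regulatory]
    if points:
        tier = reg_points if reg_points else points
        product = 1.0
        for v in tier:
            product *= v
        return (product ** (1.0 / len(tier)), "point_consensus")
    less = [e.value_ug_per_bee for e in eps if e.qualifier == "less_than"]
    greater = [e.value_ug_per_bee for e in eps if e.qualifier == "greater_than"]
    if less:
        return (min(less), "bound_min")
    return (max(greater), "bound_max")


class TestFilterAcuteAdult:
    def test_acute_adult_contact_retained(self):
        assert filter_acute_adult([ep(1.0, days=2)]) == [ep(1.0, days=2)]

    def test_chronic_dropped(self):
        assert filter_acute_adult([ep(1.0, days=10, route="oral")]) == []

    def test_mixed_list_counts(self):
        eps = [
            ep(1.0),                      # keep
            ep(2.0, route="oral"),        # keep
            ep(3.0, stage="larva"),
            ep(4.0, stage="larva"),
            ep(5.0, route="other"),
        ]
        assert len(filter_acute_adult(eps)) == 2


class TestConsensus:
    def test_equal_points(self):
        cons = consensus_for_compound([ep(4.0), ep(4.0)], "contact")
        assert cons.ld50_ug_per_bee == pytest.approx(4.0)
        assert cons.basis == "point_consensus"

    def test_geometric_mean_of_spread_points(self):
        cons = consensus_for_compound([ep(1.0), ep(100.0)], "contact")
        assert cons.ld50_ug_per_bee == pytest.approx(10.0)

    def test_greater_than_bounds_take_maximum(self):
        cons = consensus_for_compound(
            [ep(10.0, "greater_than"), ep(20.0, "greater_than")], "contact"
        )
        assert cons.ld50_ug_per_bee == 20.0
        assert cons.basis == "bound_max"

    def test_point_beats_bound(self):
        cons = consensus_for_compound([ep(5.0), ep(100.0, "greater_than")], "contact")
        assert cons.ld50_ug_per_bee == pytest.approx(5.0)
        assert cons.basis == "point_consensus"

    def test_regulatory_points_out_tier_others(self):
        cons = consensus_for_compound(
            [ep(2.0, regulatory=True), ep(8.0, regulatory=True), ep(1000.0)], "contact"
        )
        assert cons.ld50_ug_per_bee == pytest.approx(4.0)
        assert cons.n_endpoints_used == 2

    def test_mixed_bounds_prefer_less_than_and_flag(self):
        cons = consensus_for_compound(
            [ep(50.0, "less_than"), ep(10.0, "greater_than")], "contact"
        )
        assert cons.basis == "bound_min"
        assert cons.ld50_ug_per_bee == 50.0
        assert cons.mixed_bounds

    def test_no_endpoints_unresolved(self):
        assert consensus_for_compound([ep(1.0, route="oral")], "contact") is None

    def test_nonpositive_value_is_hard_error(self):
        with pytest.raises(toxicity.ToxicityError):
            ep(-1.0)

    @given(
        points=st.lists(st.floats(0.001, 1e4), max_size=4),
        bounds_gt=st.lists(st.floats(0.001, 1e4), max_size=3),
        bounds_lt=st.lists(st.floats(0.001, 1e4), max_size=3),
        reg_flags=st.lists(st.booleans(), min_size=4, max_size=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, points, bounds_gt, bounds_lt, reg_flags):
        eps = [ep(v, regulatory=reg_flags[i % 4]) for i, v in enumerate(points)]
        eps += [ep(v, "greater_than") for v in bounds_gt]
        eps += [ep(v, "less_than") for v in bounds_lt]
        expected = oracle_consensus(eps, "contact")
        got = consensus_for_compound(filter_acute_adult(eps), "contact")
        if expected is None:
            assert got is None
        else:
            assert got.basis == expected[1]
            assert got.ld50_ug_per_bee == pytest.approx(expected[0], rel=1e-12)

    @given(st.lists(st.floats(0.01, 1e3), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_point_consensus_brackets_points(self, values):
        cons = consensus_for_compound([ep(v) for v in values], "contact")
        assert min(values) * (1 - 1e-12) <= cons.ld50_ug_per_bee <= max(values) * (1 + 1e-12)

    @given(st.lists(st.floats(0.01, 1e3), min_size=1, max_size=5),
           st.floats(0.01, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_adding_bound_never_changes_point_consensus(self, values, bound):
        eps = [ep(v) for v in values]
        before = consensus_for_compound(eps, "contact")
        after = consensus_for_compound(eps + [ep(bound, "greater_than")], "contact")
        assert after.ld50_ug_per_bee == before.ld50_ug_per_bee

    def test_order_invariance(self):
        eps = [ep(2.0), ep(8.0, regulatory=True), ep(1.0, "less_than")]
        forward = consensus_for_compound(eps, "contact")
        backward = consensus_for_compound(list(reversed(eps)), "contact")
        assert forward == backward


def key(name, category="insecticide", moa="4A"):
    return CompoundKey(name, None, category, moa)


def resolved(name, value, route="contact"):
    return ConsensusLD50(name, route, value, "point_consensus", 1)


class TestImputation:
    def test_moa_group_median_odd_count(self):
        cons = [resolved("A", 1.0), resolved("B", 2.0), resolved("C", 3.0)]
        cks = [key(n) for n in "ABC"] + [key("D")]
        out = impute_unresolved(cons, cks, "contact")
        d = next(c for c in out if c.compound == "D")
        assert d.ld50_ug_per_bee == 2.0
        assert d.basis == "moa_median"

    def test_global_median_even_count(self):
        cons = [resolved(n, v) for n, v in zip("ABCD", [0.1, 1.0, 10.0, 100.0])]
        cks = [key(n) for n in "ABCD"] + [key("E", moa="9Z")]  # empty group
        out = impute_unresolved(cons, cks, "contact")
        e = next(c for c in out if c.compound == "E")
        assert e.ld50_ug_per_bee == pytest.approx(5.5)
        assert e.basis == "global_median"

    def test_all_resolved_is_identity(self):
        cons = [resolved("A", 1.0), resolved("B", 2.0)]
        out = impute_unresolved(cons, [key("A"), key("B")], "contact")
        assert sorted(out, key=lambda c: c.compound) == cons

    def test_empty_resolved_set_is_hard_error(self):
        with pytest.raises(toxicity.ToxicityError, match="empty set"):
            impute_unresolved([], [key("A")], "contact")

    @given(st.lists(st.floats(0.01, 1e3), min_size=1, max_size=9))
    @settings(max_examples=100, deadline=None)
    def test_imputed_value_is_a_median_of_observed(self, values):
        cons = [resolved(f"R{i}", v) for i, v in enumerate(values)]
        cks = [key(f"R{i}") for i in range(len(values))] + [key("MISS", moa="9Z")]
        out = impute_unresolved(cons, cks, "contact")
        imputed = next(c for c in out if c.compound == "MISS")
        assert imputed.ld50_ug_per_bee == pytest.approx(statistics.median(values))


class TestBuildTable:
    def test_complete_bundle_covers_every_compound_both_routes(self, clean_bundle, clean_result):
        _, truth = clean_bundle
        table = clean_result.ld50_table
        assert len(table) == len(truth.true_ld50)
        assert set(table["basis_contact"]) == {"point_consensus"}
        assert set(table["basis_oral"]) == {"point_consensus"}

    def test_consensus_recovers_planted_ld50(self, clean_bundle, clean_result):
        _, truth = clean_bundle
        merged = clean_result.ld50_table.merge(
            truth.true_ld50, on="compound", suffixes=("", "_true")
        )
        for route in ("contact", "oral"):
            col = f"ld50_{route}_ug_bee"
            np.testing.assert_allclose(merged[col], merged[f"{col}_true"], rtol=1e-12)

    def test_category_summary_shape(self, clean_result):
        summary = toxicity.ld50_category_summary(clean_result.ld50_table, "oral")
        assert set(summary["category"]) == {"insecticide", "fungicide", "herbicide"}
        ins = summary.set_index("category").loc["insecticide"]
        assert ins["q25"] <= ins["median"] <= ins["q75"]
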