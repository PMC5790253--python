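"""Per-transect biological indicators: examples, properties, brute force."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_records
from mpaeval import (
    ValidationError,
    compute_indicator_table,
    mature_fraction,
    mean_trophic_level,
    shannon_index,
    species_richness,
    total_density,
    transect_biomass,
)

counts_strategy = st.dictionaries(
    st.sampled_from(list("ABCDEFGH")), st.integers(1, 500),
    min_size=1, max_size=8,
)


class TestShannon:
    @pytest.mark.parametrize("counts, expected", [
        ({"A": 10, "B": 10}, math.log(2)),
        ({"A": 7}, 0.0),
        # direct summation over p = 1/6, 1/3, 1/2
        ({"A": 1, "B": 2, "C": 3},
         -(1/6*math.log(1/6) + 1/3*math.log(1/3) + 1/2*math.log(1/2))),
    ])
    def test_known_values(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-12)

    def test_derived_value_frozen(self):
        # oracle value computed by direct summation, frozen here
        assert shannon_index({"A": 1, "B": 2, "C": 3}) == pytest.approx(
            1.0114, abs=5e-5)

    def test_empty_transect_is_undefined(self):
        assert math.isnan(shannon_index({"NONE": 0}))
        assert math.isnan(shannon_index({}))

    @given(counts_strategy)
    @settings(max_examples=100, deadline=None)
    def test_bounds_zero_to_log_richness(self, counts):
        h = shannon_index(counts)
        s = species_richness(counts)
        assert -1e-12 <= h <= math.log(s) + 1e-12


class TestRichnessDensity:
    @pytest.mark.parametrize("counts, expected", [
        ({"A": 1, "B": 2, "C": 3}, 3),
        ({"NONE": 0}, 0),
        ({"A": 100}, 1),
    ])
    def test_richness(self, counts, expected):
        assert species_richness(counts) == expected

    def test_density_all_and_scoped(self):
        assert total_density({"A": 4, "B": 6}) == 10
        assert total_density({"A": 4, "B": 6}, scope="A") == 4
        assert total_density({"NONE": 0}) == 0

    @given(counts_strategy)
    @settings(max_examples=50, deadline=None)
    def test_density_additive_over_species(self, counts):
        total = total_density(counts)
        parts = sum(total_density(counts, scope=s) for s in counts)
        assert total == parts


class TestMatureFraction:
    @pytest.mark.parametrize("lengths, maturity, expected", [
        ([10, 20, 30], 15, 100 * 2 / 3),
        ([5, 6], 15, 0.0),
        ([15.0, 20.0], 15, 100.0),  # tie at maturity counts as mature
    ])
    def test_known_values(self, lengths, maturity, expected):
        assert mature_fraction(lengths, maturity) == pytest.approx(expected)

    def test_no_lengths_undefined(self):
        assert math.isnan(mature_fraction([], 15))

    def test_negative_length_rejected(self):
        with pytest.raises(ValidationError):
            mature_fraction([10, -1], 15)

    @given(st.lists(st.floats(1, 100), min_size=1, max_size=30),
           st.floats(1, 120), st.floats(0.1, 50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_nonincreasing_in_maturity(self, lengths, m, bump):
        assert mature_fraction(lengths, m) >= mature_fraction(lengths, m + bump)
        assert 0 <= mature_fraction(lengths, m) <= 100


class TestTrophicAndBiomass:
    def test_mean_trophic_level(self):
        assert mean_trophic_level({"A": 1, "B": 1}, {"A": 2, "B": 4}) == 3.0
        assert mean_trophic_level({"A": 3, "B": 1}, {"A": 2, "B": 4}) == 2.5
        assert mean_trophic_level({"A": 5}, {"A": 3.2}) == pytest.approx(3.2)

    def test_trophic_undefined_without_traits(self):
        assert math.isnan(mean_trophic_level({"A": 5}, {}))

    def test_biomass_single_and_sum(self):
        lw = {"A": (0.01, 3.0)}
        assert transect_biomass([("A", 10.0)], lw) == pytest.approx(0.01)
        assert transect_biomass([("A", 10.0), ("A", 20.0)], lw) == \
            pytest.approx(0.09)
        assert transect_biomass([], lw) == 0.0

    def test_biomass_no_traits_undefined(self):
        assert math.isnan(transect_biomass([("X", 10.0)], {}))

    def test_biomass_imputes_species_mean_length(self):
        lw = {"A": (0.01, 3.0)}
        # unmeasured organism uses mean of measured lengths (10, 20) -> 15
        got = transect_biomass([("A", 10.0), ("A", 20.0), ("A", float("nan"))], lw)
        assert got == pytest.approx((10 + 80 + 33.75) / 1000)

    @given(st.floats(0.001, 0.1), st.floats(2, 4),
           st.lists(st.floats(5, 80), min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_biomass_homogeneous_in_lw_a(self, a, b, lengths):
        obs = [("A", L) for L in lengths]
        w1 = transect_biomass(obs, {"A": (a, b)})
        w2 = transect_biomass(obs, {"A": (2 * a, b)})
        assert w2 == pytest.approx(2 * w1, rel=1e-9)


class TestIndicatorTable:
    def test_cardinality_two_indicators(self, toy_records):
        tab = compute_indicator_table(toy_records, indicators=("B2", "B4"))
        # 16 transect-units x 2 indicators (invertebrate community only)
        assert len(tab) == 32

    def test_cardinality_with_target(self, toy_records):
        tab = compute_indicator_table(
            toy_records, indicators=("B4",), target_species=("snail",))
        assert len(tab) == 32  # all + snail scope
        assert set(tab["scope"]) == {"all", "snail"}

    def test_biomass_without_traits_skipped(self, toy_records, caplog):
        tab = compute_indicator_table(toy_records, indicators=("B7",))
        assert len(tab) == 0

    def test_empty_transect_zero_density_undefined_diversity(
            self, empty_transect_records):
        tab = compute_indicator_table(
            empty_transect_records, indicators=("B1", "B2", "B4"))
        t2 = tab[tab["transect"] == "T2"].set_index("indicator")["value"]
        assert t2["B4"] == 0
        assert t2["B2"] == 0
        assert math.isnan(t2["B1"])

    def test_agrees_with_bruteforce_on_random_fixture(self, traits_df):
        rng = np.random.default_rng(123)
        rows = []
        species = [("kelp_bass", "fish"), ("sheephead", "fish"),
                   ("snail", "invertebrate"), ("urchin", "invertebrate")]
        for zone in ("control", "reserve"):
            for year in (2005, 2007):
                for t in range(5):
                    for sp, g in species:
                        c = int(rng.integers(0, 6))
                        if c == 0:
                            continue
                        if g == "fish":
                            for _ in range(c):
                                rows.append((f"{zone}_s", zone, year, f"T{t}",
                                             g, sp, 1,
                                             float(rng.uniform(5, 40)),
                                             18.0, 8.0, 10.0))
                        else:
                            rows.append((f"{zone}_s", zone, year, f"T{t}",
                                         g, sp, c, None, 18.0, 8.0, 10.0))
        rec = make_records(rows)
        tab = compute_indicator_table(rec, traits=traits_df)

        keys = ["site", "zone", "year", "transect"]
        lw = {r.species: (r.lw_a, r.lw_b) for r in traits_df.itertuples()
              if not np.isnan(r.lw_a)}
        tl = {r.species: r.trophic_level for r in traits_df.itertuples()}
        mat = {r.species: r.length_at_maturity_cm
               for r in traits_df.itertuples()}
        for key, grp in rec.groupby(keys):
            sel = dict(zip(keys, key))
            for g in ("fish", "invertebrate"):
                sub = grp[grp["group"] == g]
                if sub.empty:
                    continue
                counts = sub.groupby("species")["count"].sum().to_dict()

                def got(ind, scope="all"):
                    q = tab
                    for k, v in sel.items():
                        q = q[q[k] == v]
                    q = q[(q["indicator"] == ind) & (q["community"] == g)
                          & (q["scope"] == scope)]
                    return q["value"].iloc[0]

                assert got("B4") == pytest.approx(total_density(counts))
                assert got("B2") == species_richness(counts)
                h = shannon_index(counts)
                if math.isnan(h):
                    assert math.isnan(got("B1"))
                else:
                    assert got("B1") == pytest.approx(h)
                if g == "fish":
                    assert got("B6") == pytest.approx(
                        mean_trophic_level(counts, tl))
                    obs = list(zip(sub["species"], sub["length_cm"]))
                    assert got("B7") == pytest.approx(
                        transect_biomass(obs, lw), rel=1e-9)
                    lengths = sub["length_cm"].dropna()
                    mature = sum(
                        int(l >= mat[s]) for s, l in
                        zip(sub["species"], sub["length_cm"])
                        if not np.isnan(l))
                    if len(lengths):
                        assert got("B3") == pytest.approx(
                            100 * mature / len(lengths))
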