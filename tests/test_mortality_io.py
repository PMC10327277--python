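"""Dataset construction, tidy/WHO readers, pooling and rates."""

import numpy as np
import pandas as pd
import pytest

from lifegap.agegrid import AgeGrid, default_grid
from lifegap.errors import FormatError, ValidationError
from lifegap.mortality_io import (
    MortalityDataset,
    aggregate_years,
    dataset_from_frames,
    death_rates,
    read_tidy_csv,
    read_who_mdb,
    write_tidy,
)


def make_dataset(deaths_cells, pop=100.0, grid=None):
    """Dataset from {(sex, age_label, cause): count} with flat exposure."""
    grid = grid or default_grid()
    sexes = ("male", "female")
    causes = tuple(sorted({c for (_, _, c) in deaths_cells}))
    D = np.zeros((2, grid.n_groups, len(causes)))
    for (sex, age, cause), n in deaths_cells.items():
        D[sexes.index(sex), grid.index_of(age), causes.index(cause)] = n
    P = np.full((2, grid.n_groups), float(pop))
    return MortalityDataset(grid, sexes, causes, D, P)


class TestAgeGrid:
    def test_default_grid_has_19_groups_with_canonical_labels(self, grid):
        assert grid.n_groups == 19
        assert grid.labels[:3] == ("<1", "1-4", "5-9")
        assert grid.labels[-2:] == ("80-84", "85+")
        assert grid.widths[0] == 1 and grid.widths[1] == 4
        assert np.isinf(grid.widths[-1])

    def test_lower_bounds_must_increase(self):
        with pytest.raises(ValidationError):
            AgeGrid((0.0, 5.0, 5.0))

    def test_unknown_label_rejected(self, grid):
        with pytest.raises(ValidationError):
            grid.index_of("85-89")


class TestValidation:
    def test_negative_deaths_rejected(self, grid):
        df = pd.DataFrame(
            [("male", "<1", "I21", -1.0)], columns=["sex", "age_group", "cause", "deaths"]
        )
        pop = pd.DataFrame(
            [("male", "<1", 100.0)], columns=["sex", "age_group", "person_years"]
        )
        with pytest.raises(ValidationError):
            dataset_from_frames(df, pop, grid)

    def test_deaths_without_population_rejected(self, grid):
        D = np.zeros((1, grid.n_groups, 1))
        D[0, 0, 0] = 3.0
        with pytest.raises(ValidationError, match="zero population"):
            MortalityDataset(grid, ("male",), ("I21",), D, np.zeros((1, grid.n_groups)))

    def test_unknown_sex_codes_dropped_with_warning(self, grid, caplog):
        df = pd.DataFrame(
            [("male", "<1", "I21", 1.0), ("unknown", "<1", "I21", 5.0)],
            columns=["sex", "age_group", "cause", "deaths"],
        )
        pop = pd.DataFrame(
            [("male", "<1", 100.0)], columns=["sex", "age_group", "person_years"]
        )
        with caplog.at_level("WARNING"):
            ds = dataset_from_frames(df, pop, grid)
        assert ds.sexes == ("male",)
        assert ds.total_deaths() == 1.0


class TestTidyRoundTrip:
    def test_round_trip_identity(self, tmp_path, demo_dataset_poisson):
        write_tidy(demo_dataset_poisson, tmp_path / "d.csv", tmp_path / "p.csv")
        back = read_tidy_csv(tmp_path / "d.csv", tmp_path / "p.csv")
        assert set(back.causes) == set(demo_dataset_poisson.causes)
        assert back.sexes == demo_dataset_poisson.sexes
        order = [back.causes.index(c) for c in demo_dataset_poisson.causes]
        np.testing.assert_allclose(back.deaths[:, :, order], demo_dataset_poisson.deaths)
        np.testing.assert_allclose(back.population, demo_dataset_poisson.population)

    def test_two_row_csv_and_open_interval_label(self, tmp_path):
        (tmp_path / "d.csv").write_text(
            "sex,age_group,cause,deaths\nmale,85+,I21,4\nfemale,60-64,C34,2\n"
        )
        (tmp_path / "p.csv").write_text(
            "sex,age_group,person_years\nmale,85+,50\nfemale,60-64,80\n"
        )
        ds = read_tidy_csv(tmp_path / "d.csv", tmp_path / "p.csv")
        g = ds.grid
        assert ds.deaths[ds.sex_index("male"), g.index_of("85+"), ds.causes.index("I21")] == 4
        assert g.index_of("85+") == g.n_groups - 1


class TestAggregateYears:
    def test_pooling_preserves_common_rate(self):
        ds = make_dataset({("male", "60-64", "I21"): 3.0}, pop=100.0)
        pooled = aggregate_years([ds, ds])
        assert pooled.total_deaths() == 6.0
        assert pooled.population[0, 0] == 200.0
        m = death_rates(pooled, "male").m
        assert m[pooled.grid.index_of("60-64"), 0] == pytest.approx(0.03)

    def test_single_dataset_identity(self):
        ds = make_dataset({("male", "60-64", "I21"): 3.0})
        pooled = aggregate_years([ds])
        np.testing.assert_array_equal(pooled.deaths, ds.deaths)

    def test_pooled_rate_is_sum_ratio(self):
        a = make_dataset({("male", "60-64", "I21"): 3.0}, pop=100.0)
        b = make_dataset({("male", "60-64", "I21"): 5.0}, pop=300.0)
        m = death_rates(aggregate_years([a, b]), "male").m
        assert m[a.grid.index_of("60-64"), 0] == pytest.approx(8.0 / 400.0)

    def test_associative_and_commutative(self):
        rng = np.random.default_rng(7)
        dss = [
            make_dataset(
                {("female", "20-24", "V89"): float(rng.integers(1, 50)),
                 ("male", "20-24", "V89"): float(rng.integers(1, 50))},
                pop=float(rng.integers(100, 1000)),
            )
            for _ in range(3)
        ]
        a = aggregate_years([aggregate_years(dss[:2]), dss[2]])
        b = aggregate_years([dss[0], aggregate_years(dss[1:])])
        c = aggregate_years(dss[::-1])
        for other in (b, c):
            np.testing.assert_allclose(a.deaths, other.deaths)
            np.testing.assert_allclose(a.population, other.population)

    def test_mismatched_causes_rejected(self):
        a = make_dataset({("male", "60-64", "I21"): 3.0})
        b = make_dataset({("male", "60-64", "C34"): 3.0})
        with pytest.raises(ValidationError):
            aggregate_years([a, b])


class TestDeathRates:
    def test_simple_ratio_and_row_sum(self):
        ds = make_dataset(
            {("male", "60-64", "I21"): 5.0, ("male", "60-64", "C34"): 2.0}, pop=1000.0
        )
        rm = death_rates(ds, "male")
        i = ds.grid.index_of("60-64")
        assert rm.m[i, ds.causes.index("I21")] == pytest.approx(0.005)
        np.testing.assert_allclose(rm.all_cause(), rm.m.sum(axis=1))

    def test_scale_invariance(self, demo_dataset_poisson):
        ds = demo_dataset_poisson
        scaled = MortalityDataset(
            ds.grid, ds.sexes, ds.causes, ds.deaths * 7.0, ds.population * 7.0
        )
        np.testing.assert_allclose(
            death_rates(scaled, "female").m, death_rates(ds, "female").m
        )

    def test_poisson_counts_recover_rate_within_3_se(self):
        # D ~ Poisson(P*m) at large P: empirical rate within 3 sqrt(m/P)
        rng = np.random.default_rng(42)
        m_true, P = 0.01, 1e6
        D = rng.poisson(m_true * P)
        assert abs(D / P - m_true) < 3 * np.sqrt(m_true / P)


# ---------------------------------------------------------------------
# WHO Mortality Database flat files
# ---------------------------------------------------------------------

def _who_cols(prefix):
    return ["Country", "Year", "List", "Cause", "Sex", "Frmat"] + [
        f"{prefix}{i}" for i in range(1, 27)
    ]


def who_deaths_row(country, year, cause, sex, frmat, bands, unknown=0.0):
    """bands: {exact column index (2..25): count}."""
    row = {c: 0.0 for c in _who_cols("Deaths")}
    row.update(Country=country, Year=year, List="103", Cause=cause, Sex=sex, Frmat=frmat)
    for col, v in bands.items():
        row[f"Deaths{col}"] = v
    row["Deaths26"] = unknown
    row["Deaths1"] = sum(bands.values()) + unknown
    return row


def who_pop_row(country, year, sex, frmat, bands):
    row = {c: 0.0 for c in _who_cols("Pop") if c not in ("List", "Cause")}
    row.update(Country=country, Year=year, Sex=sex, Frmat=frmat)
    for col, v in bands.items():
        row[f"Pop{col}"] = v
    row["Pop1"] = sum(bands.values())
    return row


@pytest.fixture()
def who_files(tmp_path):
    def write(deaths_rows, pop_rows):
        dp, pp = tmp_path / "mort.csv", tmp_path / "pop.csv"
        pd.DataFrame(deaths_rows).to_csv(dp, index=False)
        pd.DataFrame(pop_rows).to_csv(pp, index=False)
        return dp, pp

    return write


class TestWhoReader:
    def test_single_record_identity(self, who_files):
        # band column 18 under format 2 is ages 60-64
        dp, pp = who_files(
            [who_deaths_row("364", 2015, "I21", 1, 2, {18: 3.0})],
            [who_pop_row("364", 2015, 1, 2, {18: 1000.0, 2: 500.0})],
        )
        ds = read_who_mdb(dp, pp, "364", [2015])
        g = ds.grid.index_of("60-64")
        assert ds.deaths[ds.sex_index("male"), g, ds.causes.index("I21")] == 3.0
        assert ds.population[ds.sex_index("male"), g] == 1000.0

    def test_unknown_age_redistributed_proportionally(self, who_files):
        # known deaths split 3:1 across two bands; 2 unknown-age deaths
        # must land 1.5 / 0.5, conserving the total
        dp, pp = who_files(
            [who_deaths_row("364", 2015, "I21", 1, 2, {17: 3.0, 18: 1.0}, unknown=2.0)],
            [who_pop_row("364", 2015, 1, 2, {17: 1000.0, 18: 1000.0})],
        )
        ds = read_who_mdb(dp, pp, "364", [2015])
        s = ds.sex_index("male")
        c = ds.causes.index("I21")
        assert ds.deaths[s, ds.grid.index_of("55-59"), c] == pytest.approx(3.0 + 1.5)
        assert ds.deaths[s, ds.grid.index_of("60-64"), c] == pytest.approx(1.0 + 0.5)
        assert ds.total_deaths() == pytest.approx(6.0)

    def test_years_pooled_and_format_1_infant_ages(self, who_files):
        # format 1 splits ages 1-4 into single years (cols 3-6)
        rows = [
            who_deaths_row("364", y, "V89", 2, 1, {3: 1.0, 4: 1.0, 5: 0.0, 6: 2.0})
            for y in (2015, 2016)
        ]
        pops = [who_pop_row("364", y, 2, 1, {3: 100.0, 4: 100.0, 5: 100.0, 6: 100.0})
                for y in (2015, 2016)]
        dp, pp = who_files(rows, pops)
        ds = read_who_mdb(dp, pp, "364", [2015, 2016])
        s = ds.sex_index("female")
        assert ds.deaths[s, ds.grid.index_of("1-4"), 0] == 8.0
        assert ds.population[s, ds.grid.index_of("1-4")] == 800.0

    def test_missing_country_or_year_errors(self, who_files):
        dp, pp = who_files(
            [who_deaths_row("364", 2015, "I21", 1, 2, {18: 3.0})],
            [who_pop_row("364", 2015, 1, 2, {18: 1000.0})],
        )
        with pytest.raises(ValidationError, match="not found"):
            read_who_mdb(dp, pp, "999", [2015])
        with pytest.raises(ValidationError, match="not found"):
            read_who_mdb(dp, pp, "364", [2015, 2016])

    def test_unsupported_age_format_named_in_error(self, who_files):
        dp, pp = who_files(
            [who_deaths_row("364", 2015, "I21", 1, 7, {18: 3.0})],
            [who_pop_row("364", 2015, 1, 2, {18: 1000.0})],
        )
        with pytest.raises(FormatError, match="7"):
            read_who_mdb(dp, pp, "364", [2015])

    def test_who_round_trip_through_tidy(self, who_files, tmp_path):
        dp, pp = who_files(
            [who_deaths_row("364", 2015, "I21", 1, 2, {18: 3.0}),
             who_deaths_row("364", 2015, "C34", 2, 2, {2: 1.0, 20: 2.0})],
            [who_pop_row("364", 2015, 1, 2, {2: 100.0, 18: 1000.0, 20: 400.0}),
             who_pop_row("364", 2015, 2, 2, {2: 100.0, 18: 1000.0, 20: 400.0})],
        )
        ds = read_who_mdb(dp, pp, "364", [2015])
        write_tidy(ds, tmp_path / "td.csv", tmp_path / "tp.csv")
        back = read_tidy_csv(tmp_path / "td.csv", tmp_path / "tp.csv")
        assert back.causes == ds.causes
        np.testing.assert_allclose(back.deaths, ds.deaths)
        np.testing.assert_allclose(back.population, ds.population)
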