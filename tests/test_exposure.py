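"""Record-to-CWS estimation: censoring substitution, units, averaging rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cwsfluoride import exposure
from conftest import make_records


class TestSubstitution:
    def test_nondetect_imputed_at_lod_over_sqrt2(self):
        rec = make_records(
            [
                ("A", "2006-01-01", np.nan, "mg/L", 0.2, False, "treated"),
                ("A", "2006-02-01", 0.5, "mg/L", 0.2, True, "treated"),
                ("B", "2006-03-01", np.nan, "ug/L", 100.0, False, "treated"),
            ]
        )
        out, n_bad = exposure.substitute_nondetects(rec)
        assert n_bad == 0
        assert out["value"].iloc[0] == pytest.approx(0.2 / math.sqrt(2), abs=1e-12)
        assert out["value"].iloc[1] == 0.5  # detected untouched
        assert out["value"].iloc[2] == pytest.approx(70.71067811865475, abs=1e-9)

    def test_nondetect_with_bad_lod_rejected_and_counted(self):
        rec = make_records(
            [
                ("A", "2006-01-01", np.nan, "ug/L", -1.0, False, "treated"),
                ("A", "2006-02-01", np.nan, "ug/L", np.nan, False, "treated"),
                ("A", "2006-03-01", 400.0, "ug/L", 100.0, True, "treated"),
            ]
        )
        out, n_bad = exposure.substitute_nondetects(rec)
        assert n_bad == 2
        assert len(out) == 1


class TestUnits:
    def test_mg_per_l_scaled_by_1000(self):
        rec = make_records(
            [
                ("A", "2006-01-01", 0.7, "mg/L", 0.1, True, "treated"),
                ("A", "2006-02-01", 700.0, "ug/L", 100.0, True, "treated"),
                ("A", "2006-03-01", 4.0, "mg/L", 0.1, True, "treated"),
            ]
        )
        out = exposure.standardize_units(rec)
        assert out["value"].tolist() == [700.0, 700.0, 4000.0]
        assert out["lod"].tolist() == [100.0, 100.0, 100.0]

    def test_unknown_unit_rejected_with_record_named(self):
        rec = make_records([("SYS9", "2006-01-01", 1.0, "ppm", 0.1, True, "treated")])
        with pytest.raises(ValueError, match="SYS9"):
            exposure.standardize_units(rec)


class TestYearlyAverage:
    @pytest.mark.parametrize(
        "treated, raw, expect_mean, expect_flag",
        [
            ([400.0, 600.0], [900.0], 500.0, True),   # raw higher -> treated only
            ([500.0], [300.0], 400.0, False),         # raw not higher -> all samples
            ([], [800.0], 800.0, False),              # raw-only year: no comparator
            ([250.0, 350.0], [], 300.0, False),
        ],
    )
    def test_treated_raw_reconciliation(self, treated, raw, expect_mean, expect_flag):
        rows = [("A", "2006-01-01", v, "ug/L", 1.0, True, "treated") for v in treated]
        rows += [("A", "2006-02-01", v, "ug/L", 1.0, True, "raw") for v in raw]
        mean, flag = exposure.yearly_average(make_records(rows))
        assert mean == pytest.approx(expect_mean)
        assert flag is expect_flag

    def test_empty_year_rejected(self):
        with pytest.raises(ValueError):
            exposure.yearly_average(make_records([]))

    def test_vectorized_matches_scalar_rule(self):
        rng = np.random.default_rng(7)
        rows = []
        for sys in ["A", "B", "C"]:
            for year in (2006, 2007, 2008):
                for _ in range(rng.integers(1, 5)):
                    rows.append(
                        (
                            sys,
                            f"{year}-{rng.integers(1, 13):02d}-01",
                            float(rng.uniform(50, 2000)),
                            "ug/L",
                            50.0,
                            True,
                            "raw" if rng.random() < 0.4 else "treated",
                        )
                    )
        rec = make_records(rows)
        vec = exposure.yearly_averages(rec).set_index(["system_id", "year"])
        rec["year"] = pd.to_datetime(rec["sample_date"]).dt.year
        for (sys, year), grp in rec.groupby(["system_id", "year"]):
            mean, flag = exposure.yearly_average(grp)
            assert vec.loc[(sys, year), "yearly_mean"] == pytest.approx(mean)
            assert bool(vec.loc[(sys, year), "treated_only"]) is flag

    def test_override_never_increases_yearly_mean(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(2, 8)
            rows = [
                (
                    "A",
                    "2006-01-01",
                    float(rng.lognormal(6, 0.8)),
                    "ug/L",
                    1.0,
                    True,
                    "raw" if rng.random() < 0.5 else "treated",
                )
                for _ in range(n)
            ]
            rec = make_records(rows)
            mean, _ = exposure.yearly_average(rec)
            assert mean <= rec["value"].mean() + 1e-12


class TestChronicAverage:
    def test_window_mean_and_filtering(self):
        yearly = pd.DataFrame(
            {
                "system_id": ["A", "A", "B", "B"],
                "year": [2006, 2009, 2008, 2010],
                "yearly_mean": [400.0, 600.0, 350.0, 800.0],
                "treated_only": [False, True, False, False],
            }
        )
        est = exposure.chronic_average(yearly).set_index("system_id")
        assert est.loc["A", "mean_6yr"] == 500.0
        assert bool(est.loc["A", "any_raw_override"]) is True
        est_late = exposure.chronic_average(yearly, (2009, 2011)).set_index("system_id")
        assert est_late.loc["B", "mean_6yr"] == 800.0
        assert "A" in est_late.index and est_late.loc["A", "mean_6yr"] == 600.0

    def test_single_year_identity(self):
        yearly = pd.DataFrame(
            {"system_id": ["A"], "year": [2008], "yearly_mean": [350.0], "treated_only": [False]}
        )
        assert exposure.chronic_average(yearly)["mean_6yr"].iloc[0] == 350.0


class TestExceedances:
    def test_direct_counts(self):
        est = pd.DataFrame({"mean_6yr": [500.0, 800.0, 1600.0, 4200.0]})
        tab = exposure.count_exceedances(est)
        assert tab["n_exceed"].tolist() == [3, 2, 1]

    @given(
        st.lists(st.floats(min_value=1.0, max_value=10_000.0), min_size=1, max_size=60),
        st.lists(st.floats(min_value=10.0, max_value=9000.0), min_size=1, max_size=4, unique=True),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_counts_non_increasing_in_threshold(self, values, thresholds):
        est = pd.DataFrame({"mean_6yr": values})
        tab = exposure.count_exceedances(est, sorted(thresholds))
        counts = tab["n_exceed"].tolist()
        assert counts == sorted(counts, reverse=True)


class TestSubgroups:
    def test_disjoint_constant_groups(self):
        est = pd.DataFrame({"system_id": ["A", "B", "C", "D"], "mean_6yr": [100.0] * 2 + [900.0] * 2})
        systems = pd.DataFrame(
            {
                "system_id": ["A", "B", "C", "D"],
                "county_id": ["X"] * 4,
                "population_served": [10] * 4,
                "source_type": ["groundwater", "groundwater", "surface", "surface"],
            }
        )
        tab = exposure.summarize_subgroups(est, systems, "source_type").set_index("group")
        assert tab.loc["groundwater", "mean"] == 100.0
        assert tab.loc["surface", "p90"] == 900.0
        assert tab.loc["groundwater", "n_exceed_700"] == 0
        assert tab.loc["surface", "n_exceed_700"] == 2

    def test_multi_cluster_system_counted_once_per_cluster(self):
        est = pd.DataFrame({"system_id": ["A", "B"], "mean_6yr": [100.0, 200.0]})
        systems = pd.DataFrame(
            {
                "system_id": ["A", "A", "B"],
                "county_id": ["X", "Y", "X"],
                "population_served": [10, 10, 20],
                "cluster": ["Semi-Urban, Hispanic", "Young, Urban, Mid/High SES", "Semi-Urban, Hispanic"],
                "source_type": ["groundwater"] * 3,
            }
        )
        tab = exposure.summarize_subgroups(est, systems, "cluster")
        assert tab["n_systems"].sum() == 3  # 2 systems, one duplicated across clusters
        by_source = exposure.summarize_subgroups(est, systems, "source_type")
        assert by_source["n_systems"].sum() == 2


class TestKruskalWallis:
    def test_hand_computed_two_groups(self):
        # ranks 1..6; H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2) = 27/7
        h, p = exposure.kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert h == pytest.approx(27.0 / 7.0, abs=1e-12)

    def test_identical_values_convention(self):
        assert exposure.kruskal_wallis([5.0] * 6, ["a"] * 3 + ["b"] * 3) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            exposure.kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestPercentOfTotal:
    @pytest.mark.parametrize(
        "count, total, expect",
        [(1456, 32495, 4.5), (4992, 32495, 15.4), (99, 32495, 0.3), (178704, 256237, 69.7), (0, 100, 0.0)],
    )
    def test_one_decimal_half_even(self, count, total, expect):
        assert exposure.percent_of_total(count, total) == expect

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            exposure.percent_of_total(1, 0)


class TestPipelineInvariants:
    def test_unit_invariance(self):
        rng = np.random.default_rng(3)
        rows_ug, rows_mg = [], []
        for i in range(40):
            sys = f"S{i % 8}"
            year = 2006 + i % 6
            val = float(rng.lognormal(6, 0.7))
            detected = val > 200
            rows_ug.append(
                (sys, f"{year}-06-15", val if detected else np.nan, "ug/L", 200.0, detected, "treated")
            )
            rows_mg.append(
                (sys, f"{year}-06-15", val / 1000 if detected else np.nan, "mg/L", 0.2, detected, "treated")
            )
        est_ug, _ = exposure.cws_estimates(make_records(rows_ug))
        est_mg, _ = exposure.cws_estimates(make_records(rows_mg))
        np.testing.assert_allclose(
            est_ug["mean_6yr"].to_numpy(), est_mg["mean_6yr"].to_numpy(), rtol=1e-9
        )

    def test_mean_equals_groupby_average_without_censoring(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(12):
            sys = f"S{i % 4}"
            year = 2006 + i % 3
            rows.append((sys, f"{year}-03-01", float(rng.uniform(100, 900)), "ug/L", 10.0, True, "treated"))
        rec = make_records(rows)
        est, _ = exposure.cws_estimates(rec)
        rec["year"] = pd.to_datetime(rec["sample_date"]).dt.year
        oracle = rec.groupby(["system_id", "year"])["value"].mean().groupby("system_id").mean()
        for sys, val in oracle.items():
            assert est.set_index("system_id").loc[sys, "mean_6yr"] == pytest.approx(val)

    def test_all_estimates_positive_and_qc_counts(self, hand_fixture):
        records, _, _, _ = hand_fixture
        est, qc = exposure.cws_estimates(records)
        assert (est["mean_6yr"] > 0).all()
        assert qc.n_records_used == 10
        assert est["n_nondetect"].sum() == 2
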