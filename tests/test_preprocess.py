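"""Sample construction: binning, trimming, dedup, filters, residualization, pairing."""

import numpy as np
import pandas as pd
import pytest

import twinace as t
from twinace.preprocess import DEFAULT_HARD_BOUNDS


def make_table(rows):
    defaults = dict(
        family_id=0, twin_order=1, cohort="C0", region="Europe", zygosity="MZ",
        sex="M", birth_year=1990, exact_age=10.0, height_cm=140.0,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestBinAge:
    @pytest.mark.parametrize(
        "age, expected",
        [
            (0.5, 1),       # lower edge of the analysis window
            (1.4999, 1),    # just inside bin 1
            (1.5, 2),       # half-open boundary: belongs to bin 2
            (10.0, 10),
            (19.4999, 19),
            (19.5, None),   # outside the window
            (0.4999, None),
            (float("nan"), None),
        ],
    )
    def test_half_open_bins(self, age, expected):
        assert t.bin_age(age) == expected

    def test_non_numeric_raises(self):
        with pytest.raises(t.DataError):
            t.bin_age("tall")

    def test_vectorized_binning_agrees_with_scalar(self):
        ages = np.linspace(0.0, 20.0, 401)
        tab = make_table([{"exact_age": a, "family_id": i} for i, a in enumerate(ages)])
        binned = t.assign_age_groups(tab)
        expect = {i: t.bin_age(a) for i, a in enumerate(ages)}
        kept = {i for i, v in expect.items() if v is not None}
        assert set(binned["family_id"]) == kept
        for _, row in binned.iterrows():
            assert row["age_group"] == expect[row["family_id"]]


class TestTrimOutliers:
    def test_single_gross_outlier_removed(self):
        rng = np.random.default_rng(0)
        h = np.r_[140 + rng.standard_normal(200), 140 + 10.0]
        tab = t.assign_age_groups(make_table([{"height_cm": v, "family_id": i} for i, v in enumerate(h)]))
        out, report = t.trim_outliers(tab, z_max=4.0, hard_bounds=(-np.inf, np.inf))
        assert report["n_removed"] == 1
        assert 150.0 not in out["height_cm"].to_numpy()

    def test_clean_normal_data_removal_below_one_percent(self):
        # iterated trimming at z_max=3.5 on clean normal data removes << 1%
        rng = np.random.default_rng(1)
        rows = [
            {"height_cm": 140 + 6 * z, "family_id": i}
            for i, z in enumerate(rng.standard_normal(20_000))
        ]
        tab = t.assign_age_groups(make_table(rows))
        _, report = t.trim_outliers(tab, z_max=3.5)
        assert report["fraction"] < 0.01

    def test_empty_table(self):
        out, report = t.trim_outliers(pd.DataFrame(columns=["age_group", "sex", "height_cm"]))
        assert out.empty and report["n_removed"] == 0

    def test_hard_bounds_applied_before_z_rule(self):
        tab = t.assign_age_groups(
            make_table([{"height_cm": v, "family_id": i} for i, v in enumerate([140] * 20 + [500.0])])
        )
        with pytest.warns(RuntimeWarning):
            # constant stratum: sd=0 stops z iteration, bound does the work
            out, report = t.trim_outliers(tab, hard_bounds=DEFAULT_HARD_BOUNDS, min_stratum_n=30)
        assert report["n_hard_bounds"] == 1
        assert len(out) == 20


class TestSelectOnePerIndividual:
    def test_nearest_to_bin_centre_kept(self):
        tab = t.assign_age_groups(
            make_table([{"exact_age": 6.9, "height_cm": 1.0}, {"exact_age": 7.3, "height_cm": 2.0}])
        )
        out = t.select_one_per_individual_per_age(tab)
        assert len(out) == 1 and out["height_cm"].iloc[0] == 1.0  # |6.9-7| < |7.3-7|

    def test_single_record_unchanged(self):
        tab = t.assign_age_groups(make_table([{"exact_age": 12.2}]))
        out = t.select_one_per_individual_per_age(tab)
        pd.testing.assert_frame_equal(out, tab.reset_index(drop=True))

    def test_idempotent_and_duplicate_invariant(self):
        rng = np.random.default_rng(3)
        rows = [
            {"family_id": int(f), "twin_order": int(o), "exact_age": float(a)}
            for f, o, a in zip(rng.integers(0, 10, 60), rng.integers(1, 3, 60), rng.uniform(5, 9, 60))
        ]
        tab = t.assign_age_groups(make_table(rows))
        once = t.select_one_per_individual_per_age(tab)
        twice = t.select_one_per_individual_per_age(once)
        pd.testing.assert_frame_equal(once, twice)
        # brute-force oracle: smallest distance (first occurrence on ties) per key
        for (f, o, g), sub in tab.groupby(["family_id", "twin_order", "age_group"]):
            best = (sub["exact_age"] - g).abs().idxmin()
            kept = once[(once["family_id"] == f) & (once["twin_order"] == o) & (once["age_group"] == g)]
            assert len(kept) == 1
            assert kept["exact_age"].iloc[0] == tab.loc[best, "exact_age"]
        doubled = t.select_one_per_individual_per_age(pd.concat([tab, tab], ignore_index=True))
        pd.testing.assert_frame_equal(
            doubled.reset_index(drop=True), once.reset_index(drop=True)
        )


class TestFilterMinCohort:
    @pytest.mark.parametrize("n, kept", [(49, 0), (50, 50), (51, 51)])
    def test_threshold_boundary_inclusive(self, n, kept):
        tab = make_table([{"family_id": i, "cohort": "A"} for i in range(n)])
        assert len(t.filter_min_cohort(tab, min_n=50)) == kept

    def test_all_small_warns_empty(self):
        tab = make_table([{"family_id": i} for i in range(5)])
        with pytest.warns(RuntimeWarning):
            out = t.filter_min_cohort(tab, min_n=50)
        assert out.empty


class TestResidualize:
    def test_intercept_only_stratum_mean(self):
        rows = [{"family_id": i, "height_cm": h, "exact_age": 10.0} for i, h in enumerate([10.0, 20.0, 30.0])]
        tab = t.assign_age_groups(make_table(rows))
        out = t.residualize(tab, mode="moderation")  # birth year constant -> intercept only
        np.testing.assert_allclose(out["y"], [-10.0, 0.0, 10.0], atol=1e-10)

    def test_birth_year_signal_removed(self):
        rng = np.random.default_rng(4)
        by = rng.integers(1960, 2000, 4000)
        noise = rng.standard_normal(4000)
        rows = [
            {"family_id": i, "birth_year": int(b), "height_cm": 2.0 * (b - 2000) + 140 + z}
            for i, (b, z) in enumerate(zip(by, noise))
        ]
        tab = t.assign_age_groups(make_table(rows))
        out = t.residualize(tab, mode="univariate")
        # residual variance equals the noise variance (direct OLS oracle)
        X = np.column_stack([np.ones(4000), by, tab["exact_age"]])
        beta, *_ = np.linalg.lstsq(X, tab["height_cm"].to_numpy(), rcond=None)
        oracle = tab["height_cm"].to_numpy() - X @ beta
        np.testing.assert_allclose(out["y"].to_numpy(), oracle, atol=1e-8)
        assert np.var(out["y"]) == pytest.approx(np.var(noise), rel=0.05)

    def test_residuals_sum_to_zero_per_stratum(self, small_cohort):
        tab = t.assign_age_groups(small_cohort)
        out = t.residualize(tab, mode="univariate")
        sums = out.groupby(["sex", "age_group"])["y"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-6)

    def test_rank_deficient_cohort_warns(self):
        rows = [{"family_id": i, "cohort": "A" if i % 2 else "B", "birth_year": 1990} for i in range(20)]
        tab = t.assign_age_groups(make_table(rows))
        tab.loc[:, "cohort"] = "A"  # single cohort + constant birth year: collinear
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            t.residualize(tab.assign(extra=1), mode="univariate")


class TestMakePairs:
    def test_complete_pair_joined(self):
        tab = t.assign_age_groups(
            make_table([{"twin_order": 1, "height_cm": 1.0}, {"twin_order": 2, "height_cm": 2.0}])
        )
        pairs = t.make_pairs(tab)
        assert len(pairs) == 1
        assert pairs["group"].iloc[0] == "MZM"
        assert (pairs["y1"].iloc[0], pairs["y2"].iloc[0]) == (1.0, 2.0)

    def test_missing_cotwin_dropped(self):
        tab = t.assign_age_groups(make_table([{"twin_order": 1}]))
        assert t.make_pairs(tab).empty

    def test_os_pairs_male_first(self):
        tab = t.assign_age_groups(
            make_table(
                [
                    {"twin_order": 1, "zygosity": "DZ", "sex": "F", "height_cm": 1.0},
                    {"twin_order": 2, "zygosity": "DZ", "sex": "M", "height_cm": 2.0},
                ]
            )
        )
        pairs = t.make_pairs(tab)
        assert pairs["group"].iloc[0] == "OS"
        assert pairs["y1"].iloc[0] == 2.0  # male phenotype first

    def test_mz_sex_discordant_excluded_and_reported(self):
        tab = t.assign_age_groups(
            make_table(
                [
                    {"twin_order": 1, "sex": "M"},
                    {"twin_order": 2, "sex": "F"},
                    {"family_id": 1, "twin_order": 1, "sex": "M"},
                    {"family_id": 1, "twin_order": 2, "sex": "M"},
                ]
            )
        )
        report = {}
        with pytest.warns(RuntimeWarning, match="discordant"):
            pairs = t.make_pairs(tab, report=report)
        assert len(pairs) == 1
        assert report["n_mz_sex_discordant"] == 1

    def test_three_twin_orders_raise(self):
        tab = t.assign_age_groups(
            make_table([{"twin_order": o} for o in (1, 2, 3)])
        )
        with pytest.raises(t.DataError):
            t.make_pairs(tab)


class TestPipelineProperties:
    def test_deterministic_and_row_counts_non_increasing(self, small_cohort):
        p1, r1 = t.run_preprocess(small_cohort, mode="univariate")
        p2, r2 = t.run_preprocess(small_cohort, mode="univariate")
        pd.testing.assert_frame_equal(p1, p2)
        assert r1 == r2
        assert r1["n_raw"] >= r1["n_in_window"] >= r1["n_after_dedup"] >= r1["n_after_cohort_filter"]

    def test_residualization_preserves_pair_structure(self, small_cohort):
        tab = t.assign_age_groups(small_cohort)
        tab = t.select_one_per_individual_per_age(tab)
        raw_pairs = t.make_pairs(tab)
        res_pairs = t.make_pairs(t.residualize(tab, mode="univariate"))
        assert len(raw_pairs) == len(res_pairs)
        pd.testing.assert_series_equal(raw_pairs["group"], res_pairs["group"])
        pd.testing.assert_series_equal(raw_pairs["family_id"], res_pairs["family_id"])
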