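"""Zero-intercept recalibration: exact-fit property, shift diagnostics, consistency."""
import numpy as np
import pandas as pd
import pytest

import solvcoef as sc
from solvcoef.errors import DegeneratePopulationError, InvalidInputError
from solvcoef.io import PAIRED_COLUMNS


class TestRecalibrateSolvent:
    def test_exact_fit_when_c_is_zero(self, original_rows, population):
        # sulfolane's published intercept is exactly zero: the regression target
        # already lies in the design's column space, so any full-rank population
        # returns the same weights
        sulfolane = sc.find_solvent(original_rows, "sulfolane")
        refit = sc.recalibrate_solvent(sulfolane, population)
        assert np.allclose(refit.as_array(), sulfolane.as_array(), atol=1e-10)
        assert refit.convention == sc.ZERO_INTERCEPT

    def test_exact_fit_matches_published_row_to_rounding(self, original_rows, zero_rows):
        # the published zero-intercept sulfolane row was rounded independently;
        # 3-decimal agreement is the most the table supports
        for seed in (1, 2):
            pop = sc.make_solute_population(sc.SynthesisConfig(n=100, seed=seed))
            refit = sc.recalibrate_solvent(sc.find_solvent(original_rows, "sulfolane"), pop)
            published = sc.find_solvent(zero_rows, "sulfolane")
            assert np.allclose(refit.as_array(), published.as_array(), atol=1.5e-3)
            assert round(refit.e, 3) == 0.147

    def test_water_maps_to_zero(self, original_rows, population):
        water = sc.find_solvent(original_rows, "water")
        assert np.allclose(sc.recalibrate_solvent(water, population).as_array(), 0.0, atol=1e-12)

    def test_idempotent_on_zero_intercept_rows(self, zero_rows, population):
        row = sc.find_solvent(zero_rows, "methanol")
        assert sc.recalibrate_solvent(row, population) is row

    def test_methanol_against_fixed_population_matches_normal_equations_oracle(
        self, original_rows
    ):
        # frozen once from an independent normal-equations solve on the
        # n=200/seed=17 population
        pop = sc.make_solute_population(sc.SynthesisConfig(n=200, seed=17))
        refit = sc.recalibrate_solvent(sc.find_solvent(original_rows, "methanol"), pop)
        expected = [0.3869008581, -0.6302360655, 0.3079640046, -3.2588792288, 3.6164176932]
        assert np.allclose(refit.as_array(), expected, atol=1e-9)

    def test_exact_fit_property_for_random_zero_intercept_rows(self, population):
        rng = np.random.default_rng(0)
        for _ in range(20):
            row = sc.SolventCoefficients("random", *rng.normal(0, 2, 5), c=0.0)
            refit = sc.recalibrate_solvent(row, population)
            assert np.allclose(refit.as_array(), row.as_array(), atol=1e-10)

    def test_rank_deficient_population_rejected(self):
        frame = pd.DataFrame({
            "name": [f"m{i}" for i in range(10)],
            "E": np.linspace(0.1, 1, 10), "S": np.linspace(0.1, 1, 10),  # S == E
            "A": np.linspace(0, 0.5, 10), "B": np.linspace(0, 0.9, 10),
            "V": np.linspace(0.5, 2, 10),
        })
        frame["S"] = frame["E"]
        with pytest.raises(DegeneratePopulationError):
            sc.SolutePopulation(frame)

    def test_empty_population_rejected(self):
        frame = pd.DataFrame(columns=["name", "E", "S", "A", "B", "V"])
        with pytest.raises(InvalidInputError):
            sc.SolutePopulation(frame)


class TestRecalibrateTable:
    def test_three_row_table_preserves_order_and_exact_fit_rows(
        self, original_rows, population
    ):
        rows = [sc.find_solvent(original_rows, n) for n in ("water", "sulfolane", "methanol")]
        paired = sc.recalibrate_table(rows, population)
        assert paired["name"].tolist() == ["water", "sulfolane", "methanol"]
        assert np.allclose(paired.loc[0, ["e0", "s0", "a0", "b0", "v0"]].astype(float), 0.0)
        assert np.allclose(
            paired.loc[1, ["e0", "s0", "a0", "b0", "v0"]].astype(float),
            rows[1].as_array(), atol=1e-10,
        )
        # methanol has c = 0.276: its weights must actually move
        assert not np.allclose(
            paired.loc[2, ["e0", "s0", "a0", "b0", "v0"]].astype(float),
            rows[2].as_array(), atol=1e-3,
        )

    def test_empty_table_gives_empty_frame(self, population):
        paired = sc.recalibrate_table([], population)
        assert len(paired) == 0
        assert list(paired.columns) == PAIRED_COLUMNS

    def test_zero_intercept_input_rejected_with_name(self, zero_rows, population):
        with pytest.raises(InvalidInputError, match="methanol"):
            sc.recalibrate_table([sc.find_solvent(zero_rows, "methanol")], population)

    def test_full_table_tracks_published_zero_intercept_side(
        self, original_rows, table1, table1_consistent
    ):
        # the packaged synthetic population differs from the original descriptor
        # database, so agreement is bounded, not exact; tolerances frozen from
        # the packaged default population (seed 2015)
        pop = sc.make_solute_population(sc.SynthesisConfig(seed=2015))
        paired = sc.recalibrate_table(original_rows, pop)
        merged = paired.merge(
            table1_consistent, on="name", suffixes=("_new", "_pub")
        )
        tolerance = {"e": 0.20, "s": 0.08, "a": 0.12, "b": 0.30, "v": 0.22}
        for k, tol in tolerance.items():
            gap = (merged[f"{k}0_new"] - merged[f"{k}0_pub"]).abs().max()
            assert gap <= tol, f"{k}0 deviates by {gap}"


class TestSignShift:
    def test_published_consistent_pairs_all_pass(self, table1_consistent):
        report = sc.sign_shift_check(table1_consistent)
        assert report["passed"].all()
        assert report.loc[report["c"] == 0, "exempt"].all()

    def test_zero_intercept_rows_are_exempt(self):
        paired = pd.DataFrame([{
            "name": "x", "c": 0.0, "e": 1, "s": 1, "a": 1, "b": 1, "v": 1,
            "e0": 9, "s0": 9, "a0": 9, "b0": 9, "v0": 9,
        }])
        report = sc.sign_shift_check(paired)
        assert report["exempt"].iloc[0] and report["passed"].iloc[0]

    def test_constructed_violation_is_flagged(self):
        # c < 0 requires e to increase; here it decreases
        paired = pd.DataFrame([{
            "name": "bad", "c": -0.5, "e": 1.0, "s": 1, "a": 1, "b": 1, "v": 1,
            "e0": 0.5, "s0": 0.9, "a0": 0.9, "b0": 1.1, "v0": 0.9,
        }])
        assert not sc.sign_shift_check(paired)["passed"].iloc[0]

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            sc.sign_shift_check(pd.DataFrame(columns=PAIRED_COLUMNS))


class TestShiftReport:
    def test_hand_computed_two_row_oracle(self):
        paired = pd.DataFrame([
            {"name": "p", "c": 0.1, "e": 0.0, "s": 0.2, "a": 0.1, "b": -0.05, "v": 0.1,
             "e0": 0.1, "s0": 0.0, "a0": 0.1, "b0": 0.0, "v0": 0.0},
            {"name": "q", "c": -0.2, "e": 0.3, "s": 0.1, "a": 0.0, "b": 0.15, "v": -0.3,
             "e0": 0.0, "s0": 0.1, "a0": 0.1, "b0": 0.0, "v0": 0.0},
        ])
        report = sc.shift_report(paired)
        # AAE: e (0.1+0.3)/2=0.2, s (0.2+0)/2=0.1, a (0+0.1)/2=0.05,
        #      b (0.05+0.15)/2=0.1, v (0.1+0.3)/2=0.2
        assert report.aae == pytest.approx({"e": 0.2, "s": 0.1, "a": 0.05, "b": 0.1, "v": 0.2})
        assert report.scaled["e"] == pytest.approx(0.2 * 0.884)
        assert report.scaled["a"] == pytest.approx(0.05 * 0.173)
        assert report.ranking == ("v", "e", "s", "b", "a")

    def test_identical_sides_give_zero_shifts(self, table1):
        paired = table1.copy()
        for k in "esabv":
            paired[k + "0"] = paired[k]
        report = sc.shift_report(paired)
        assert all(v == 0 for v in report.scaled.values())

    def test_published_pairs_reproduce_printed_scaled_shifts(self, table1_consistent):
        report = sc.shift_report(table1_consistent)
        assert report.scaled["v"] == pytest.approx(0.124, abs=0.005)
        assert report.scaled["s"] == pytest.approx(0.043, abs=0.005)
        assert report.scaled["e"] == pytest.approx(0.013, abs=0.005)
        assert report.scaled["b"] == pytest.approx(0.011, abs=0.005)
        assert report.scaled["a"] == pytest.approx(0.010, abs=0.005)
        assert report.ranking == ("v", "s", "e", "b", "a")


class TestConsistencyFlag:
    def test_single_anomalous_row_in_packaged_table(self, table1):
        # one published zero-intercept row breaks the shared Delta = c*beta law
        # by over an order of magnitude; every other row obeys it
        flags = sc.flag_inconsistent_pairs(table1)
        assert table1.loc[flags, "name"].tolist() == ["tributyl phosphate"]

    def test_self_recalibrated_table_is_fully_consistent(self, original_rows, population):
        paired = sc.recalibrate_table(original_rows[:20], population)
        assert not sc.flag_inconsistent_pairs(paired).any()
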