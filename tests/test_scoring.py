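"""Per-cell/per-well statistics: outlier fences, DPR calls, well
summaries, 2-SD filters and the Z' gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nctscreen import (DprThresholds, call_dpr_positive, default_screen_layout,
                       flag_wells, qc_plate, remove_gfp_outliers,
                       summarize_wells, z_prime, z_prime_from_stats)
from nctscreen.plates import PlateLayout
from nctscreen.scoring import ControlError


def make_cells(circle, ring=None, well="A01", valid=True):
    circle = np.asarray(circle, dtype=float)
    ring = np.asarray(ring, dtype=float) if ring is not None else np.zeros_like(circle)
    return pd.DataFrame({
        "cell_id": np.arange(len(circle)), "plate": "P1", "well": well,
        "is_valid": valid, "circle_gfp": circle, "ring_gfp": ring,
        "translocation_index": circle - ring,
    })


def brute_force_outliers(circle, ring, k=3.0):
    """Independent oracle: explicit loops over the fence definition."""
    flags = [False] * len(circle)
    for values in (circle, ring):
        n = len(values)
        mu = sum(values) / n
        sd = (sum((v - mu) ** 2 for v in values) / (n - 1)) ** 0.5
        if sd == 0:
            continue
        for i, v in enumerate(values):
            if v < mu - k * sd or v > mu + k * sd:
                flags[i] = True
    return flags


class TestRemoveGfpOutliers:
    def test_identical_cells_no_outliers(self):
        out = remove_gfp_outliers(make_cells([50.0] * 20))
        assert not out.is_outlier.any()

    def test_planted_extreme_cell_flagged(self, rng):
        circle = rng.normal(50, 5, size=100)
        sd = circle.std(ddof=1)
        circle = np.append(circle, circle.mean() + 6 * sd)
        out = remove_gfp_outliers(make_cells(circle))
        expected = brute_force_outliers(list(circle), [0.0] * len(circle))
        assert list(out.is_outlier) == expected
        assert out.is_outlier.iloc[-1]
        assert out.is_outlier.sum() == sum(expected)

    def test_infinite_fence_flags_nothing(self, rng):
        out = remove_gfp_outliers(make_cells(rng.normal(50, 5, 50)), k=np.inf)
        assert not out.is_outlier.any()

    def test_matches_brute_force_on_random_wells(self, rng):
        for _ in range(200):
            n = rng.integers(2, 30)
            circle = rng.normal(rng.uniform(20, 80), rng.uniform(0.1, 20), n)
            ring = rng.normal(rng.uniform(10, 40), rng.uniform(0.1, 10), n)
            out = remove_gfp_outliers(make_cells(circle, ring))
            assert list(out.is_outlier) == brute_force_outliers(
                list(circle), list(ring))

    def test_fences_computed_per_well(self, rng):
        # a value extreme for one well but typical for another
        a = make_cells(rng.normal(50, 1, 50).tolist() + [80.0], well="A01")
        b = make_cells(rng.normal(80, 20, 50), well="A02")
        out = remove_gfp_outliers(pd.concat([a, b], ignore_index=True))
        assert out[out.well == "A01"].is_outlier.iloc[-1]
        assert not out[out.well == "A02"].is_outlier.any()

    def test_order_invariance(self, rng):
        cells = make_cells(rng.normal(50, 5, 60))
        shuffled = cells.sample(frac=1, random_state=3)
        out1 = remove_gfp_outliers(cells).set_index("cell_id").is_outlier
        out2 = remove_gfp_outliers(shuffled).set_index("cell_id").is_outlier
        assert out1.sort_index().equals(out2.sort_index())


class TestCallDprPositive:
    def test_zero_thresholds_all_positive(self, null_plate):
        cells, _ = null_plate
        out = call_dpr_positive(cells, DprThresholds(0, 0))
        assert out.is_dpr_positive.all()

    def test_separable_thresholds_recover_transfection(self):
        # noise-free DPR levels: positives at 150, background at 20
        from nctscreen import PlateSimParams, simulate_plate
        params = PlateSimParams(layout=default_screen_layout("P1"),
                                cells_per_well=100, seed=3,
                                dpr_pos_sd=0.0, dpr_bg_sd=0.0,
                                transfection_efficiency=0.5)
        cells, _ = simulate_plate(params)
        pr_cells = cells[cells.role.isin(["pr_control", "test"])]
        out = call_dpr_positive(pr_cells, DprThresholds(circle_min=85, ring_min=1e9))
        assert (out.is_dpr_positive == (out.circle_dpr >= 85)).all()
        # exactly the transfected cells sit at the high level
        assert set(out[out.is_dpr_positive].circle_dpr.round(6)) == {150.0}

    def test_missing_channel_rejected(self):
        cells = make_cells([1.0, 2.0])
        with pytest.raises(ValueError, match="DPR"):
            call_dpr_positive(cells, DprThresholds(10, 10))

    def test_both_rule_stricter_than_either(self, null_plate):
        cells, _ = null_plate
        either = call_dpr_positive(cells, DprThresholds(80, 10, rule="either"))
        both = call_dpr_positive(cells, DprThresholds(80, 10, rule="both"))
        assert both.is_dpr_positive.sum() <= either.is_dpr_positive.sum()


def tiny_layout(roles_wells):
    wells = pd.DataFrame(roles_wells, columns=["well", "role"])
    wells["compound_id"] = None
    wells["dose"] = None
    return PlateLayout(plate="P1", wells=wells)


class TestSummarizeWells:
    def test_mean_of_retained_indices(self):
        cells = make_cells([10.0, 20.0, 30.0] * 4)
        layout = tiny_layout([("A01", "test")])
        wells = summarize_wells(cells, layout, min_cells=3)
        assert wells.ti_raw.iloc[0] == pytest.approx(20.0)

    def test_all_invalid_well_excluded(self):
        cells = make_cells([10.0] * 20, valid=False)
        layout = tiny_layout([("A01", "test")])
        wells = summarize_wells(cells, layout)
        assert wells.excluded.iloc[0] and np.isnan(wells.ti_raw.iloc[0])

    def test_outliers_excluded_from_mean(self):
        cells = make_cells([10.0] * 10 + [1000.0])
        cells["is_outlier"] = [False] * 10 + [True]
        wells = summarize_wells(cells, tiny_layout([("A01", "test")]))
        assert wells.ti_raw.iloc[0] == pytest.approx(10.0)

    def test_unknown_well_rejected(self):
        cells = make_cells([1.0] * 12, well="B05")
        with pytest.raises(ValueError, match="B05"):
            summarize_wells(cells, tiny_layout([("A01", "test")]))

    def test_null_plate_test_wells_match_pr_wells(self, null_plate, layout):
        from scipy import stats
        cells, _ = null_plate
        wells = summarize_wells(cells, layout)
        t, p = stats.ttest_ind(wells[wells.role == "test"].ti_raw,
                               wells[wells.role == "pr_control"].ti_raw)
        assert p > 0.01


class TestFlagWells:
    def _wells(self, n_invalid, n_dpr):
        n = len(n_invalid)
        return pd.DataFrame({
            "plate": "P1", "well": [f"W{i:02d}" for i in range(n)],
            "role": "test", "compound_id": None, "dose": None,
            "n_cells_valid": 100, "n_invalid": n_invalid,
            "n_dpr_positive": n_dpr, "ti_raw": 1.0, "ti_norm": np.nan,
            "excluded": False, "toxic": False, "low_expression": False,
        })

    def test_identical_counts_no_flags(self):
        wells = flag_wells(self._wells([5] * 20, [70] * 20))
        assert not wells.toxic.any() and not wells.low_expression.any()

    def test_planted_toxic_well(self):
        n_inv = [5] * 95 + [50]
        wells = flag_wells(self._wells(n_inv, [70] * 96))
        mu, sd = np.mean(n_inv), np.std(n_inv, ddof=1)
        expected = [v > mu + 2 * sd for v in n_inv]
        assert list(wells.toxic) == expected
        assert wells.toxic.sum() == 1 and wells.toxic.iloc[-1]

    def test_uniform_high_expression_no_low_flags(self, rng):
        wells = flag_wells(self._wells(rng.poisson(5, 96), [400] * 96))
        assert not wells.low_expression.any()

    def test_too_few_wells_warns(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            flag_wells(self._wells([1, 2], [3, 4]))


class TestZPrime:
    def test_printed_formula_value(self):
        assert z_prime_from_stats(10, 5 / 6, 0, 5 / 6) == pytest.approx(0.5, abs=1e-12)

    def test_noise_free_limit_is_one(self):
        assert z_prime_from_stats(10, 0, 0, 0) == 1.0
        assert z_prime([3.0, 3.0], [9.0, 9.0]) == 1.0

    def test_equal_means_rejected(self):
        with pytest.raises(ControlError, match="not separated"):
            z_prime([1.0, 3.0], [3.0, 1.0])

    def test_orientation_free(self):
        assert z_prime([0.0, 1.0], [10.0, 11.0]) == pytest.approx(
            z_prime([10.0, 11.0], [0.0, 1.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=10),
           st.lists(st.floats(200, 400), min_size=2, max_size=10),
           st.floats(0.01, 50), st.floats(-10, 10))
    def test_bounded_and_affine_invariant(self, pos, neg, a, b):
        zp = z_prime(pos, neg)
        assert zp <= 1.0
        scaled = z_prime([a * x + b for x in pos], [a * x + b for x in neg])
        assert scaled == pytest.approx(zp, rel=1e-9, abs=1e-9)

    def test_decreasing_in_sigma(self):
        z1 = z_prime_from_stats(10, 1.0, 0, 1.0)
        z2 = z_prime_from_stats(10, 2.0, 0, 1.0)
        z3 = z_prime_from_stats(10, 1.0, 0, 2.0)
        assert z2 < z1 and z3 < z1


class TestQcPlate:
    def _wells(self, pos_vals, neg_vals):
        n = len(pos_vals) + len(neg_vals)
        return pd.DataFrame({
            "plate": "P1", "well": [f"W{i:02d}" for i in range(n)],
            "role": ["lmb_pos"] * len(pos_vals) + ["vehicle_neg"] * len(neg_vals),
            "compound_id": None, "dose": None, "n_cells_valid": 100,
            "n_invalid": 0, "n_dpr_positive": 0,
            "ti_raw": list(pos_vals) + list(neg_vals), "ti_norm": np.nan,
            "excluded": False, "toxic": False, "low_expression": False,
        })

    def test_separated_controls_pass(self, null_plate, layout):
        cells, _ = null_plate
        report = qc_plate(flag_wells(summarize_wells(cells, layout)))
        assert report.passed and report.z_prime >= 0.5

    def test_zero_sd_gives_one(self):
        report = qc_plate(self._wells([10.0, 10.0], [0.0, 0.0]))
        assert report.z_prime == 1.0 and report.passed

    def test_identical_controls_error(self):
        with pytest.raises(ControlError):
            qc_plate(self._wells([1.0, 2.0], [2.0, 1.0]))

    def test_missing_arm_error(self):
        wells = self._wells([1.0, 2.0], [0.0, 0.5])
        wells = wells[wells.role != "vehicle_neg"]
        with pytest.raises(ControlError, match="control arm"):
            qc_plate(wells)

    def test_overlapping_controls_fail_gate(self, rng):
        pos = rng.normal(0, 1, 8)
        neg = rng.normal(0.1, 1, 8)
        report = qc_plate(self._wells(pos, neg))
        assert not report.passed
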