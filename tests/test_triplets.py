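"""Tests for outlier exclusion, triplet extraction and the regressions."""

import numpy as np
import pandas as pd
import pytest

from piece import (
    binned_regression,
    bivariate_regression,
    exclude_outliers,
    extract_triplets,
    group_stats,
    lag2_residual,
    simulate_participant,
)
from piece.params import PieceParams
from piece.triplets import participant_coefficients

from conftest import make_trials


def normal_equations(y, X):
    """Independent OLS oracle: solve (X'X) beta = X'y directly."""
    A = np.c_[np.ones(len(X)), np.asarray(X, dtype=float)]
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, dtype=float))


class TestExcludeOutliers:
    def test_equal_angles_no_exclusions(self):
        tr = make_trials([0] * 20, [1.0] * 20)
        with pytest.warns(UserWarning):
            out = exclude_outliers(tr)
        assert not out["excluded"].any()

    def test_single_extreme_trial_flagged(self):
        hand = np.zeros(100)
        hand[1:100:7] += 0.01  # tiny spread so the SD is finite
        hand[50] = 100.0
        out = exclude_outliers(make_trials([0] * 100, hand))
        assert out["excluded"].sum() == 1
        assert bool(out.loc[50, "excluded"])

    def test_gaussian_exclusion_rate_is_tiny(self):
        rng = np.random.default_rng(0)
        hand = rng.normal(0, 1, 40_000)
        out = exclude_outliers(make_trials([0] * 40_000, hand))
        frac = out["excluded"].mean()
        assert frac == pytest.approx(4.65e-4, abs=4e-4)  # 2*Phi(-3.5)


class TestExtractTriplets:
    def test_adaptation_arithmetic(self):
        tr = make_trials([0, 2, 0, 4, 0], [1.0, 0.0, -2.0, 0.5, 3.0])
        trip = extract_triplets(tr).set_index("center_index")
        assert trip.loc[1, "adaptation"] == pytest.approx(-3.0)  # -2 - 1
        assert trip.loc[3, "adaptation"] == pytest.approx(5.0)   # 3 - (-2)
        assert trip.loc[1, "ege"] == 2.0 and trip.loc[1, "ige"] == 0.0

    def test_equal_flankers_give_zero_adaptation(self):
        tr = make_trials([0, 2, 0], [1.0, 5.0, 1.0])
        assert extract_triplets(tr)["adaptation"].iloc[0] == 0.0

    def test_excluding_a_flanker_removes_only_that_triplet(self):
        tr = make_trials([0, 2, 0, 4, 0], [1.0, 0.0, -2.0, 0.5, 3.0])
        tr.loc[4, "excluded"] = True
        trip = extract_triplets(tr)
        assert list(trip["center_index"]) == [1]

    def test_measured_trial_without_null_neighbour_skipped(self):
        tr = make_trials([0, 2, 0], [0.0, 1.0, 2.0])
        tr.loc[0, "trial_type"] = "measured"
        trip = extract_triplets(tr)
        assert list(trip["center_index"]) == []


class TestBinnedRegression:
    def _synthetic(self, slope_ege=-0.6, const=0.0, n_per_level=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        idx = 0
        for ege in (-4, -2, 0, 2, 4):
            for _ in range(n_per_level):
                ige = rng.normal(0, 2)
                rows.append(("P1", idx, ege, ige, slope_ege * ege + const, 0.0, 0.0))
                idx += 1
        return pd.DataFrame(rows, columns=["participant_id", "center_index", "ege",
                                           "ige", "adaptation", "hand_pre", "hand_post"])

    def test_pure_ege_dependence_recovered_exactly(self):
        trip = self._synthetic(slope_ege=-0.6)
        vs_ege, vs_ige, bins = binned_regression(trip)
        assert vs_ege.slope("ege") == pytest.approx(-0.6, abs=1e-12)
        assert vs_ege.r_squared == pytest.approx(1.0, abs=1e-12)
        assert abs(vs_ige.slope("ige")) < 0.05
        assert len(bins) == 25

    def test_constant_adaptation_gives_zero_slopes(self):
        trip = self._synthetic(slope_ege=0.0, const=1.3)
        vs_ege, vs_ige, _ = binned_regression(trip)
        assert vs_ege.slope("ege") == pytest.approx(0.0, abs=1e-12)
        assert vs_ige.slope("ige") == pytest.approx(0.0, abs=1e-10)
        assert vs_ege.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_piece_participant_has_flat_ige_binned_slope(self, piece_trials):
        trip = extract_triplets(exclude_outliers(piece_trials))
        _, vs_ige, _ = binned_regression(trip)
        assert abs(vs_ige.slope("ige")) < 0.1

    def test_too_few_triplets_rejected(self):
        trip = self._synthetic(n_per_level=1)
        with pytest.raises(ValueError):
            binned_regression(trip.head(4))


class TestBivariateRegression:
    def test_exact_recovery_on_noiseless_data(self):
        rng = np.random.default_rng(1)
        ege = rng.choice([-4, -2, 0, 2, 4], 200).astype(float)
        ige = rng.normal(0, 2, 200)
        trip = pd.DataFrame({
            "participant_id": "P1", "center_index": np.arange(200),
            "ege": ege, "ige": ige, "adaptation": -0.5 * ege - 0.1 * ige,
        })
        summ = bivariate_regression(trip)  # sign-flipped
        assert summ.slope("ege") == pytest.approx(0.5, abs=1e-10)
        assert summ.slope("ige") == pytest.approx(0.1, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        trip = pd.DataFrame({
            "participant_id": "P1", "center_index": np.arange(50),
            "ege": rng.choice([-4, -2, 0, 2, 4], 50).astype(float),
            "ige": rng.normal(0, 2, 50),
        })
        trip["adaptation"] = rng.normal(0, 1, 50)
        summ = bivariate_regression(trip, sign_flip=False)
        beta = normal_equations(trip["adaptation"], trip[["ege", "ige"]])
        assert summ.intercept == pytest.approx(beta[0], abs=1e-10)
        assert summ.slope("ege") == pytest.approx(beta[1], abs=1e-10)
        assert summ.slope("ige") == pytest.approx(beta[2], abs=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        trip = pd.DataFrame({
            "participant_id": "P1", "center_index": np.arange(60),
            "ege": rng.choice([-4, -2, 0, 2, 4], 60).astype(float),
            "ige": rng.normal(0, 2, 60),
        })
        trip["adaptation"] = -0.4 * trip["ege"] + rng.normal(0, 1, 60)
        a = bivariate_regression(trip)
        b = bivariate_regression(trip.sample(frac=1, random_state=0))
        assert a.slope("ege") == pytest.approx(b.slope("ege"))
        assert a.slope("ige") == pytest.approx(b.slope("ige"))

    def test_collinear_predictors_rejected(self):
        trip = pd.DataFrame({
            "participant_id": "P1", "center_index": np.arange(10),
            "ege": np.arange(10, dtype=float), "ige": 2.0 * np.arange(10),
            "adaptation": np.zeros(10),
        })
        with pytest.raises(ValueError):
            bivariate_regression(trip)

    def test_piece_data_ege_dominates_ige(self, piece_trials):
        trip = extract_triplets(exclude_outliers(piece_trials))
        summ = bivariate_regression(trip)
        assert summ.slope("ege") > abs(summ.slope("ige"))


class TestGroupStats:
    def test_identical_pairs_guard(self):
        coefs = pd.DataFrame({
            "participant_id": list("abcd"),
            "coef_ege": [0.6] * 4, "coef_ige": [0.6] * 4,
        })
        out = group_stats(coefs, n_boot=200, seed=0)
        assert out["paired_t"]["p"] == 1.0

    def test_bootstrap_ci_contains_sample_mean(self):
        rng = np.random.default_rng(4)
        coefs = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(16)],
            "coef_ege": rng.normal(0.6, 0.05, 16),
            "coef_ige": rng.normal(0.0, 0.05, 16),
        })
        out = group_stats(coefs, n_boot=2000, seed=0)
        lo, hi = out["ci_ege"]
        assert lo <= out["mean_coef_ege"] <= hi

    def test_power_against_zero_for_tight_coefficients(self):
        # n=16 participants with mean 0.6, SD 0.05: one-sample t rejects at 1e-3
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(50):
            coefs = pd.DataFrame({
                "participant_id": [f"p{i}" for i in range(16)],
                "coef_ege": rng.normal(0.6, 0.05, 16),
                "coef_ige": rng.normal(0.0, 0.05, 16),
            })
            out = group_stats(coefs, n_boot=50, seed=0)
            rejections += out["one_sample_ege"]["p"] < 1e-3
        assert rejections == 50

    def test_single_participant_rejected(self):
        coefs = pd.DataFrame({"participant_id": ["a"], "coef_ege": [1.0],
                              "coef_ige": [0.0]})
        with pytest.raises(ValueError):
            group_stats(coefs)


class TestLag2Residual:
    def test_no_memory_simulation_has_flat_lag2_slope(self, piece_trials):
        summ = lag2_residual(exclude_outliers(piece_trials))
        assert abs(summ.slope("ege")) < 0.15

    def test_injected_one_trial_memory_detected(self, protocol):
        # counterexample: make the lag-2 null inherit half the update
        p = PieceParams(sigma_h=0.5)
        tr = simulate_participant("PIECE", p, protocol, seed=17).copy()
        tr = tr.sort_values("trial_index").reset_index(drop=True)
        ttype = tr["trial_type"].to_numpy()
        rot = tr["rotation_deg"].to_numpy()
        for t in np.flatnonzero(ttype == "measured"):
            if t + 2 < len(tr):
                tr.loc[t + 2, "hand_angle_deg"] += -0.5 * rot[t]
        tr["excluded"] = False
        summ = lag2_residual(tr)
        assert summ.slope("ege") < -0.3

    def test_constant_data_gives_zero(self):
        ttype = ["null", "measured", "null", "null",
                 "null", "measured", "null", "null",
                 "null", "measured", "null", "null"]
        tr = make_trials([0, 2, 0, 0, 0, 4, 0, 0, 0, -2, 0, 0], [1.0] * 12, ttype=ttype)
        summ = lag2_residual(tr)
        assert summ.slope("ege") == pytest.approx(0.0, abs=1e-12)


class TestParticipantCoefficients:
    def test_one_row_per_participant(self, piece_trials):
        two = pd.concat([
            piece_trials,
            piece_trials.assign(participant_id="S02"),
        ], ignore_index=True)
        coefs = participant_coefficients(exclude_outliers(two))
        assert list(coefs["participant_id"]) == ["S01", "S02"]
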