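"""Triplet-based behavioural analysis of error parsing.

Each rotation (measured) trial is flanked by null trials, forming a
triplet.  Single-trial adaptation is the reach-angle change from the
pre-null to the post-null, adaptation_t = hand_{t+1} - hand_{t-1}, which
keeps the outcome measure free of the measured trial's own reach angle —
the internally generated error (IGE) — and so avoids spurious
regression-to-the-mean correlations.  The externally generated error
(EGE) is the rotation imposed on the measured trial; the IGE is that
trial's hand angle.

The analyses mirror standard practice for this paradigm: per-participant
outlier exclusion on reach-angle z-scores, a 5 (EGE level) x 5 (IGE
quintile) binned regression, a bivariate OLS regression of unbinned
adaptation on EGE and IGE jointly (coefficients reported sign-flipped, so
positive values mean corrective adaptation), group-level paired and
one-sample t-tests, and bootstrap confidence intervals resampling
participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionSummary",
    "exclude_outliers",
    "extract_triplets",
    "binned_regression",
    "bivariate_regression",
    "group_stats",
    "lag2_residual",
]


@dataclass(frozen=True)
class RegressionSummary:
    """Coefficients and fit diagnostics of one OLS regression."""

    slopes: dict          # predictor name -> coefficient
    intercept: float
    r_squared: float
    ci_low: dict          # per-coefficient 95% CI bounds
    ci_high: dict
    n: int

    def slope(self, name: str) -> float:
        return self.slopes[name]


def exclude_outliers(trials: pd.DataFrame, z_threshold: float = 3.5) -> pd.DataFrame:
    """Flag trials whose reach angle is a per-participant z-score outlier.

    The z-score uses each participant's own main-phase mean and SD (one
    pass); trials with |z| > ``z_threshold`` get ``excluded=True``.  A
    participant with zero reach-angle variance yields no exclusions (with
    a warning).  Returns a copy.
    """
    out = trials.copy()
    out["excluded"] = False
    for pid, grp in out[out["phase"] == "main"].groupby("participant_id"):
        angles = grp["hand_angle_deg"].to_numpy()
        sd = angles.std(ddof=1) if len(angles) > 1 else 0.0
        if sd == 0.0:
            warnings.warn(f"participant {pid}: zero reach variance, no exclusions")
            continue
        z = (angles - angles.mean()) / sd
        out.loc[grp.index[np.abs(z) > z_threshold], "excluded"] = True
    return out


def extract_triplets(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per usable (pre-null, measured, post-null) trial triplet.

    A triplet is kept when the measured trial's immediate neighbours exist
    and are null trials and none of the three is excluded.  Target-jump
    trials are never triplet centers.  Columns: participant_id,
    center_index, ege (rotation), ige (measured-trial hand angle),
    adaptation (hand_{t+1} - hand_{t-1}), plus pre/post reach angles.
    """
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial_index").reset_index(drop=True)
        ttype = grp["trial_type"].to_numpy()
        hand = grp["hand_angle_deg"].to_numpy()
        rot = grp["rotation_deg"].to_numpy()
        excl = grp["excluded"].to_numpy(dtype=bool)
        tidx = grp["trial_index"].to_numpy()
        centers = np.flatnonzero(ttype == "measured")
        for t in centers:
            if t == 0 or t == len(grp) - 1:
                continue
            if ttype[t - 1] != "null" or ttype[t + 1] != "null":
                continue
            if excl[t - 1] or excl[t] or excl[t + 1]:
                continue
            rows.append(
                (pid, int(tidx[t]), rot[t], hand[t], hand[t + 1] - hand[t - 1],
                 hand[t - 1], hand[t + 1])
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "center_index", "ege", "ige", "adaptation",
                 "hand_pre", "hand_post"],
    )


def _ols_summary(y, X: pd.DataFrame) -> RegressionSummary:
    model = sm.OLS(np.asarray(y, dtype=float), sm.add_constant(X)).fit()
    ci = model.conf_int()
    names = [c for c in X.columns]
    rsq = float(model.rsquared)
    if not np.isfinite(rsq):  # zero-variance outcome: nothing to explain
        rsq = 0.0
    return RegressionSummary(
        slopes={k: float(model.params[k]) for k in names},
        intercept=float(model.params["const"]),
        r_squared=rsq,
        ci_low={k: float(ci.loc[k, 0]) for k in names},
        ci_high={k: float(ci.loc[k, 1]) for k in names},
        n=int(model.nobs),
    )


def _bin_participant(trip: pd.DataFrame, n_ige_bins: int) -> pd.DataFrame:
    """5 x n_ige_bins bin means for one participant's triplets."""
    parts = []
    for ege, grp in trip.groupby("ege"):
        g = grp.sort_values("center_index").reset_index(drop=True)
        # quintile edges from this cell's empirical IGE distribution;
        # boundary ties broken by stable rank order
        rank = g["ige"].rank(method="first") - 1
        qbin = np.floor(rank * n_ige_bins / len(g)).astype(int)
        for q in range(n_ige_bins):
            sel = g[qbin == q]
            if len(sel) == 0:
                warnings.warn(f"empty IGE bin {q} at EGE {ege}; dropped")
                continue
            parts.append(
                (ege, q, sel["ige"].mean(), sel["adaptation"].mean(), len(sel))
            )
    return pd.DataFrame(parts, columns=["ege", "ige_bin", "ige", "adaptation", "n"])


def binned_regression(
    triplets: pd.DataFrame, n_ige_bins: int = 5
) -> tuple[RegressionSummary, RegressionSummary, pd.DataFrame]:
    """Binned (5 EGE levels x IGE quintiles) regressions of adaptation.

    Per participant, triplets are split by EGE level and quintile-binned
    by IGE within level; bin-mean adaptation is then regressed onto EGE
    and, separately, onto IGE.  With several participants the bins are
    first averaged across participants (per EGE level x quintile cell)
    and the regression run on the averaged grid.

    Returns ``(summary_vs_ege, summary_vs_ige, bins)`` where ``bins`` is
    the bin-mean table the regressions used.
    """
    if len(triplets) < n_ige_bins * triplets["ege"].nunique():
        raise ValueError("too few triplets for the binned analysis")
    per_part = (
        triplets.groupby("participant_id", sort=False)
        .apply(_bin_participant, n_ige_bins, include_groups=False)
        .reset_index(level=0)
    )
    bins = (
        per_part.groupby(["ege", "ige_bin"], as_index=False)[["ige", "adaptation"]]
        .mean()
    )
    vs_ege = _ols_summary(bins["adaptation"], bins[["ege"]])
    vs_ige = _ols_summary(bins["adaptation"], bins[["ige"]])
    return vs_ege, vs_ige, bins


def bivariate_regression(triplets: pd.DataFrame, sign_flip: bool = True) -> RegressionSummary:
    """OLS of unbinned adaptation on EGE and IGE jointly.

    Coefficients (and their CIs) are sign-flipped by default so that
    positive values read as corrective sensitivity to each error source.
    """
    if len(triplets) < 3:
        raise ValueError("need at least 3 triplets")
    X = triplets[["ege", "ige"]].astype(float)
    if np.linalg.matrix_rank(np.c_[np.ones(len(X)), X.to_numpy()]) < 3:
        raise ValueError("collinear predictors: EGE and IGE are not separable")
    summ = _ols_summary(triplets["adaptation"], X)
    if not sign_flip:
        return summ
    return RegressionSummary(
        slopes={k: -v for k, v in summ.slopes.items()},
        intercept=summ.intercept,
        r_squared=summ.r_squared,
        ci_low={k: -summ.ci_high[k] for k in summ.slopes},
        ci_high={k: -summ.ci_low[k] for k in summ.slopes},
        n=summ.n,
    )


def participant_coefficients(trials: pd.DataFrame) -> pd.DataFrame:
    """Sign-flipped bivariate (EGE, IGE) coefficients per participant."""
    rows = []
    trip = extract_triplets(trials)
    for pid, grp in trip.groupby("participant_id", sort=False):
        summ = bivariate_regression(grp)
        rows.append((pid, summ.slope("ege"), summ.slope("ige")))
    return pd.DataFrame(rows, columns=["participant_id", "coef_ege", "coef_ige"])


def group_stats(
    coefs: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> dict:
    """Group-level inference on per-participant (EGE, IGE) coefficients.

    Paired t-test of EGE versus IGE coefficients, one-sample t-tests of
    each against zero, and bootstrap 95% CIs of the means obtained by
    resampling participants with replacement.
    """
    if len(coefs) < 2:
        raise ValueError("need at least 2 participants")
    a = coefs["coef_ege"].to_numpy(dtype=float)
    b = coefs["coef_ige"].to_numpy(dtype=float)
    diff = a - b
    if np.allclose(diff, diff[0]):
        paired = {"t": 0.0 if diff[0] == 0 else np.inf, "p": 1.0 if diff[0] == 0 else 0.0}
    else:
        t, p = stats.ttest_rel(a, b)
        paired = {"t": float(t), "p": float(p)}

    def one_sample(x):
        if np.allclose(x, x[0]):
            return {"t": 0.0 if x[0] == 0 else np.inf, "p": 1.0 if x[0] == 0 else 0.0}
        t, p = stats.ttest_1samp(x, 0.0)
        return {"t": float(t), "p": float(p)}

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(a), size=(n_boot, len(a)))

    def boot_ci(x):
        means = x[idx].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return [float(lo), float(hi)]

    return {
        "n": int(len(a)),
        "mean_coef_ege": float(a.mean()),
        "mean_coef_ige": float(b.mean()),
        "mean_difference": float(diff.mean()),
        "paired_t": paired,
        "one_sample_ege": one_sample(a),
        "one_sample_ige": one_sample(b),
        "ci_ege": boot_ci(a),
        "ci_ige": boot_ci(b),
        "ci_difference": boot_ci(diff),
    }


def lag2_residual(trials: pd.DataFrame) -> RegressionSummary:
    """Residual adaptation two trials after a rotation.

    Regresses hand_{t+2} - hand_{t-1} on the rotation at t, restricted to
    schedules where trial t+2 is a null and no involved trial is excluded.
    Under the no-memory assumption the slope is ~0; a one-trial memory
    process leaves a signed residual here.
    """
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial_index").reset_index(drop=True)
        ttype = grp["trial_type"].to_numpy()
        hand = grp["hand_angle_deg"].to_numpy()
        rot = grp["rotation_deg"].to_numpy()
        excl = grp["excluded"].to_numpy(dtype=bool)
        for t in np.flatnonzero(ttype == "measured"):
            if t < 1 or t + 2 >= len(grp):
                continue
            if ttype[t - 1] != "null" or ttype[t + 1] != "null" or ttype[t + 2] != "null":
                continue
            if excl[t - 1] or excl[t] or excl[t + 1] or excl[t + 2]:
                continue
            rows.append((rot[t], hand[t + 2] - hand[t - 1]))
    if len(rows) < 3:
        warnings.warn("too few eligible lag-2 schedules; returning empty summary")
        return RegressionSummary({}, np.nan, np.nan, {}, {}, len(rows))
    df = pd.DataFrame(rows, columns=["ege", "lag2"])
    return _ols_summary(df["lag2"], df[["ege"]])
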