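"""Maximum-likelihood fitting, BIC comparison and recovery analyses.

The module is organised around two objects, in the style of statsmodels:

- :class:`AdaptationModel` — built from one participant's trial table
  (``from_dataframe``).  Subclasses (:class:`PieceModel`,
  :class:`PremoModel`, :class:`PeaModel`, :class:`RemModel`) supply the
  single-trial predictor; the base class owns the likelihood, the
  multi-start bounded optimisation, and simulation at given parameters.
- :class:`AdaptationResults` — returned by ``fit()``; carries the MLE
  parameters, negative log-likelihood, BIC, optimizer diagnostics, a
  ``summary()`` table, and ``simulate()`` / ``posterior_predictive()``
  hooks.

Likelihood: each usable triplet contributes the Gaussian likelihood of
the observed post-null reach, hand_{t+1} ~ N(model prediction on
(rotation_t, hand_t), sigma_h^2), with sigma_h fixed from baseline
reaches and trials treated as independent (no memory across trials).
0-degree rotation triplets are included.  Two documented switches cover
the underdetermined alternatives: ``target="adaptation"`` models the
pre-to-post difference with variance 2*sigma_h^2, and
``include_null_terms=True`` adds N(b, sigma_h^2) terms for null reaches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import triplets as tri
from .observer import predict_response
from .params import (
    N_FREE,
    PARAM_CLASSES,
    PeaParams,
    PieceParams,
    PremoParams,
    RemParams,
)
from .protocol import baseline_sigma, simulate_participant
from .rivals import rival_predict

_LOG2PI = float(np.log(2.0 * np.pi))

DEFAULT_BOUNDS = {
    "PIECE": {"sigma_r": (0.1, 50.0), "bias_b": (-10.0, 10.0), "sigma_combined": (0.01, 20.0)},
    "PReMo": {
        "beta_v": (0.0, 1.0),
        "gamma_v": (0.1, 30.0),
        "beta_p": (0.0, 1.0),
        "gamma_p": (0.1, 30.0),
        "eta": (0.0, 2.0),
        "bias_b": (-10.0, 10.0),
    },
    "PEA": {"sigma_p": (0.01, 20.0), "sigma_u": (0.01, 20.0), "bias_b": (-10.0, 10.0)},
    "REM": {
        "eta": (0.0, 2.0),
        "sigma_rel": (0.1, 50.0),
        "p_rel": (0.01, 0.99),
        "bias_b": (-10.0, 10.0),
    },
}


class FitError(RuntimeError):
    """Raised when no optimisation start converges."""


@dataclass
class AdaptationResults:
    """MLE fit of one adaptation model to one participant's data."""

    model: "AdaptationModel"
    params: object                 # fitted parameter dataclass
    free: pd.Series                # named free-parameter estimates
    nll: float
    n_obs: int
    k_params: int
    converged: bool
    n_starts: int
    best_start: int
    optimizer_message: str = ""

    @property
    def bic(self) -> float:
        """k*ln(n) + 2*nll (lower is better)."""
        return self.k_params * np.log(self.n_obs) + 2.0 * self.nll

    @property
    def participant_id(self) -> str:
        return self.model.participant_id

    @property
    def model_name(self) -> str:
        return self.model.model_name

    def summary(self) -> str:
        lines = [
            f"{self.model_name} maximum-likelihood fit",
            f"  participant: {self.participant_id}",
            f"  n obs (triplets): {self.n_obs}   free params: {self.k_params}",
            f"  nll: {self.nll:.4f}   BIC: {self.bic:.4f}",
            f"  converged: {self.converged} (best of {self.n_starts} starts: #{self.best_start})",
            f"  sigma_h (fixed): {self.model.sigma_h:.4f} deg",
            "  estimates:",
        ]
        for name, val in self.free.items():
            lines.append(f"    {name:>16s} = {val: .5f}")
        return "\n".join(lines)

    def simulate(self, protocol: pd.DataFrame, seed: int, **kw) -> pd.DataFrame:
        """Simulate a synthetic participant at the fitted parameters."""
        return simulate_participant(
            self.model_name, self.params, protocol, seed=seed,
            participant_id=self.participant_id, **kw,
        )

    def posterior_predictive(self, protocol: pd.DataFrame, seed: int) -> dict:
        """Posterior predictive check at the MLE (see module function)."""
        return posterior_predictive_check(self, protocol, seed)

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "model": self.model_name,
            "nll": self.nll,
            "n_obs": self.n_obs,
            "k_params": self.k_params,
            "bic": self.bic,
            "converged": self.converged,
        }
        row.update({f"param_{k}": v for k, v in self.free.items()})
        return row


class AdaptationModel:
    """Base class: one participant's triplet likelihood for one model.

    Parameters
    ----------
    trials : DataFrame
        Trial table (TrialRecord rows) for a single participant.  If an
        ``excluded`` column is absent, per-participant z-score exclusion
        (threshold 3.5) is applied first.
    sigma_h : float, optional
        Fixed response-noise SD.  Defaults to the sample SD of the last
        50 baseline reaches.
    target : {"next_hand", "adaptation"}
        Likelihood target; see module docstring.
    include_null_terms : bool
        Add N(b, sigma_h^2) likelihood terms for null-trial reaches.
    """

    model_name: str = ""
    param_class = None

    def __init__(self, trials: pd.DataFrame, sigma_h: float | None = None,
                 target: str = "next_hand", include_null_terms: bool = False,
                 **fixed):
        pids = trials["participant_id"].unique()
        if len(pids) != 1:
            raise ValueError("AdaptationModel fits one participant at a time")
        self.participant_id = str(pids[0])
        if "excluded" not in trials.columns:
            trials = tri.exclude_outliers(trials)
        self.trials = trials
        if target not in ("next_hand", "adaptation"):
            raise ValueError("target must be 'next_hand' or 'adaptation'")
        self.target = target
        self.include_null_terms = include_null_terms
        self.sigma_h = float(sigma_h) if sigma_h is not None else baseline_sigma(trials)
        if self.sigma_h <= 0:
            raise ValueError("sigma_h must be strictly positive")
        self._fixed = dict(fixed)
        self._template = self.param_class(sigma_h=self.sigma_h, **fixed)

        trip = tri.extract_triplets(trials)
        # only full-feedback centers inform the model (no cue, no update)
        fb = trials.set_index("trial_index")["feedback"]
        keep = fb.loc[trip["center_index"]].to_numpy() == "full"
        trip = trip[keep]
        if len(trip) < 3:
            raise ValueError("too few usable triplets to fit")
        self._rot = trip["ege"].to_numpy(dtype=float)
        self._hand = trip["ige"].to_numpy(dtype=float)
        self._post = trip["hand_post"].to_numpy(dtype=float)
        self._pre = trip["hand_pre"].to_numpy(dtype=float)
        if include_null_terms:
            m = trials[(trials["trial_type"] == "null") & (trials["phase"] == "main")
                       & (~trials["excluded"].astype(bool))]
            self._null_angles = m["hand_angle_deg"].to_numpy(dtype=float)
        else:
            self._null_angles = np.empty(0)

    # -- interface -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, **kw) -> "AdaptationModel":
        return cls(trials, **kw)

    @property
    def free_names(self) -> tuple:
        return self.param_class.FREE

    @property
    def k_params(self) -> int:
        return len(self.free_names)

    @property
    def nobs(self) -> int:
        return len(self._rot) + len(self._null_angles)

    def params_from_vector(self, x):
        return self._template.with_free(x)

    def predict(self, params, rotation, hand):
        """Model mean next-trial reach; implemented by subclasses."""
        raise NotImplementedError

    # -- likelihood ------------------------------------------------------

    def nll(self, params) -> float:
        """Negative log-likelihood of the observed post-null reaches."""
        mean = np.asarray(self.predict(params, self._rot, self._hand), dtype=float)
        if not np.all(np.isfinite(mean)):
            bad = int(np.flatnonzero(~np.isfinite(mean))[0])
            raise FloatingPointError(
                f"non-finite prediction at triplet {bad} "
                f"(rotation {self._rot[bad]}, hand {self._hand[bad]})"
            )
        if self.target == "next_hand":
            resid, var = self._post - mean, self.sigma_h**2
        else:
            resid = (self._post - self._pre) - (mean - params.bias_b)
            var = 2.0 * self.sigma_h**2
        out = 0.5 * np.sum(_LOG2PI + np.log(var) + resid**2 / var)
        if self._null_angles.size:
            rn = self._null_angles - params.bias_b
            out += 0.5 * np.sum(_LOG2PI + np.log(self.sigma_h**2) + rn**2 / self.sigma_h**2)
        return float(out)

    def _nll_vector(self, x) -> float:
        try:
            return self.nll(self.params_from_vector(x))
        except (ValueError, FloatingPointError):
            return 1e12

    # -- fitting ---------------------------------------------------------

    def fit(self, n_starts: int = 20, seed: int = 0, bounds: dict | None = None,
            tol: float = 1e-8) -> AdaptationResults:
        """Multi-start bounded MLE (L-BFGS-B over Latin-hypercube starts)."""
        bdict = dict(DEFAULT_BOUNDS[self.model_name])
        if bounds:
            bdict.update(bounds)
        lo = np.array([bdict[k][0] for k in self.free_names])
        hi = np.array([bdict[k][1] for k in self.free_names])
        sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
        starts = qmc.scale(sampler.random(n_starts), lo, hi)

        best = None
        best_i = -1
        for i, x0 in enumerate(starts):
            res = optimize.minimize(
                self._nll_vector, x0, method="L-BFGS-B",
                bounds=list(zip(lo, hi)), options={"ftol": tol, "maxiter": 500},
            )
            if not res.success:
                continue
            if best is None or res.fun < best.fun:
                best, best_i = res, i
        if best is None:
            raise FitError(
                f"no start converged for {self.model_name} "
                f"({self.participant_id}); last message: {res.message}"
            )
        params = self.params_from_vector(best.x)
        return AdaptationResults(
            model=self,
            params=params,
            free=pd.Series(best.x, index=list(self.free_names)),
            nll=float(best.fun),
            n_obs=self.nobs,
            k_params=self.k_params,
            converged=True,
            n_starts=n_starts,
            best_start=best_i,
            optimizer_message=str(best.message),
        )


class PieceModel(AdaptationModel):
    """PIECE causal-inference observer (free: sigma_r, bias_b, sigma_combined)."""

    model_name = "PIECE"
    param_class = PieceParams

    def predict(self, params, rotation, hand):
        return predict_response(rotation, hand, params)


class PremoModel(AdaptationModel):
    """PReMo saturating-recalibration model (6 free parameters)."""

    model_name = "PReMo"
    param_class = PremoParams

    def predict(self, params, rotation, hand):
        return rival_predict("PReMo", rotation, hand, params)


class PeaModel(AdaptationModel):
    """PEA precision-weighted perceptual-error model (3 free parameters)."""

    model_name = "PEA"
    param_class = PeaParams

    def predict(self, params, rotation, hand):
        return rival_predict("PEA", rotation, hand, params)


class RemModel(AdaptationModel):
    """REM relevance-estimation model (4 free parameters)."""

    model_name = "REM"
    param_class = RemParams

    def predict(self, params, rotation, hand):
        return rival_predict("REM", rotation, hand, params)


MODEL_CLASSES = {
    "PIECE": PieceModel,
    "PReMo": PremoModel,
    "PEA": PeaModel,
    "REM": RemModel,
}


def negative_log_likelihood(model: str, params, trials: pd.DataFrame, **kw) -> float:
    """nll of ``trials`` under ``model`` at the given parameters."""
    return MODEL_CLASSES[model](trials, sigma_h=params.sigma_h, **kw).nll(params)


def fit_mle(model: str, trials: pd.DataFrame, n_starts: int = 20, seed: int = 0,
            bounds: dict | None = None, **kw) -> AdaptationResults:
    """Convenience one-call MLE fit of ``model`` to one participant."""
    return MODEL_CLASSES[model](trials, **kw).fit(n_starts=n_starts, seed=seed, bounds=bounds)


def bic_compare(fits: list[AdaptationResults], reference: str = "PReMo") -> pd.DataFrame:
    """Per-participant BIC table with deltas against a reference model.

    ``fits`` holds one result per participant x model.  Returns a tidy
    DataFrame with columns participant_id, model, nll, bic, delta_bic
    (BIC - BIC(reference)) and winner (the participant's argmin-BIC model).
    """
    df = pd.DataFrame([f.to_row() for f in fits])
    out = []
    for pid, grp in df.groupby("participant_id", sort=False):
        if reference not in set(grp["model"]):
            raise ValueError(f"participant {pid}: missing reference model {reference}")
        ref = float(grp.loc[grp["model"] == reference, "bic"].iloc[0])
        grp = grp.copy()
        grp["delta_bic"] = grp["bic"] - ref
        grp["winner"] = grp.loc[grp["bic"].idxmin(), "model"]
        out.append(grp)
    return pd.concat(out, ignore_index=True)[
        ["participant_id", "model", "nll", "n_obs", "k_params", "bic", "delta_bic", "winner"]
    ]


def posterior_predictive_check(result: AdaptationResults, protocol: pd.DataFrame,
                               seed: int) -> dict:
    """Simulate the fitted model over the schedule and compare regressions.

    Returns observed versus simulated sign-flipped bivariate (EGE, IGE)
    coefficients plus the simulated trial table, the standard check that a
    fitted model reproduces the structure of the data it was fitted to.
    """
    sim = result.simulate(protocol, seed=seed)
    sim = tri.exclude_outliers(sim)
    obs_coef = tri.bivariate_regression(tri.extract_triplets(result.model.trials))
    sim_coef = tri.bivariate_regression(tri.extract_triplets(sim))
    return {
        "observed": {"ege": obs_coef.slope("ege"), "ige": obs_coef.slope("ige")},
        "simulated": {"ege": sim_coef.slope("ege"), "ige": sim_coef.slope("ige")},
        "simulated_trials": sim,
    }


def parameter_recovery(grid: list[PieceParams], protocol: pd.DataFrame, n_rep: int,
                       seed: int, n_starts: int = 8) -> pd.DataFrame:
    """Simulate-and-refit PIECE at each grid point, ``n_rep`` times.

    Returns a tidy table of generating versus recovered free parameters,
    one row per (grid point, replicate).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g, params in enumerate(grid):
        for rep in range(n_rep):
            s = int(rng.integers(2**31 - 1))
            trials = simulate_participant("PIECE", params, protocol, seed=s,
                                          participant_id=f"G{g}R{rep}")
            res = PieceModel(trials).fit(n_starts=n_starts, seed=s)
            row = {"grid_point": g, "replicate": rep, "seed": s}
            for name in PieceParams.FREE:
                row[f"true_{name}"] = getattr(params, name)
                row[f"est_{name}"] = float(res.free[name])
            rows.append(row)
    return pd.DataFrame(rows)


def model_recovery(params_by_model: dict, protocol: pd.DataFrame, n_per_model: int,
                   seed: int, n_starts: int = 8) -> pd.DataFrame:
    """BIC-winner confusion matrix across generating models.

    For each generating model, simulates ``n_per_model`` synthetic
    participants, fits all four models to each, and counts the BIC winner.
    Returns a DataFrame indexed by generating model with one column per
    fitted model; rows sum to ``n_per_model``.
    """
    rng = np.random.default_rng(seed)
    names = list(params_by_model)
    counts = pd.DataFrame(0, index=names, columns=list(MODEL_CLASSES), dtype=int)
    for gen in names:
        for rep in range(n_per_model):
            s = int(rng.integers(2**31 - 1))
            trials = simulate_participant(gen, params_by_model[gen], protocol, seed=s,
                                          participant_id=f"{gen}-{rep}")
            bics = {}
            for name, cls in MODEL_CLASSES.items():
                try:
                    bics[name] = cls(trials).fit(n_starts=n_starts, seed=s).bic
                except FitError:
                    warnings.warn(f"{name} failed to converge on {gen}-{rep}")
                    bics[name] = np.inf
            counts.loc[gen, min(bics, key=bics.get)] += 1
    counts.index.name = "generating_model"
    return counts
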