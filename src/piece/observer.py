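"""The PIECE causal-inference observer.

PIECE (Parsing of Internal and External Causes of Error) treats single-trial
visuomotor adaptation as Bayesian causal inference followed by state
estimation.  On each feedback trial the observer receives a visual cue of
the cursor angle, ``x_v``, and a fused internal cue of the hand angle,
``x_c`` (proprioception + efference-copy motor prediction, experimentally
inseparable).  It computes the posterior probability that the feedback was
externally perturbed, estimates the perturbation magnitude with a
precision-weighted (Kalman) gain, and corrects its next reach by the
belief-weighted estimate:

    r_hat = p(pert | cues) * K * z,      next reach mean = -r_hat + b.

Because the perturbation observation ``z`` is centred on the rotation
itself (not on the hand), the deterministic observer never adapts to
internally generated error — the model-level statement of IGE-insensitivity.

All angles in degrees, target at 0 deg, counter-clockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .params import ParameterError, PieceParams

_LOG_FLOOR = -690.0  # ~log(1e-300); linear-space densities floored there

__all__ = [
    "CueSet",
    "CausalPosterior",
    "PerturbationEstimate",
    "visual_uncertainty",
    "log_marginal_likelihoods",
    "marginal_likelihoods",
    "causal_posterior",
    "kalman_gain",
    "estimate_perturbation",
    "predict_response",
    "posterior_curve",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class CueSet:
    """Sensory evidence available to the observer on one feedback trial.

    ``x_v`` is the visual measurement of the cursor angle, ``x_c`` the
    combined internal (proprioceptive + motor-prediction) measurement of
    the hand angle, ``e`` the cursor-to-target distance used for the
    visual-uncertainty function, and ``sigma_v`` the resulting trial
    visual SD.
    """

    x_v: float
    x_c: float
    e: float
    sigma_v: float

    def __post_init__(self):
        if self.e < 0:
            raise ParameterError("target error e must be non-negative")
        if self.sigma_v <= 0:
            raise ParameterError("sigma_v must be strictly positive")

    @classmethod
    def from_trial(cls, rotation: float, hand: float, params: PieceParams) -> "CueSet":
        """Cues at their experimenter-visible values (deterministic mode)."""
        e = abs(hand + rotation)
        return cls(
            x_v=hand + rotation,
            x_c=hand,
            e=e,
            sigma_v=visual_uncertainty(e, params),
        )


@dataclass(frozen=True)
class CausalPosterior:
    """Normalized degree of belief over {perturbed, unperturbed}."""

    p_pert: float
    p_nopert: float

    def __post_init__(self):
        if not (-1e-12 <= self.p_pert <= 1 + 1e-12):
            raise ParameterError("p_pert outside [0, 1]")
        if abs(self.p_pert + self.p_nopert - 1.0) > 1e-12:
            raise ParameterError("causal posterior must sum to 1")


@dataclass(frozen=True)
class PerturbationEstimate:
    """Belief-weighted state estimate of the perturbation on one trial."""

    gain_K: float
    z: float
    r_hat: float


def visual_uncertainty(e, params: PieceParams):
    """Trial visual SD, a linear function of the cursor-to-target distance.

    sigma_v(e) = alpha + beta * e, with e >= 0 in degrees.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ParameterError("target error e must be non-negative")
    out = params.alpha + params.beta * e
    return float(out) if out.ndim == 0 else out


def _log_bvn(x, y, mu, var_x, var_y, cov):
    """Log-density of a bivariate normal with common mean ``mu``."""
    det = var_x * var_y - cov**2
    dx = x - mu
    dy = y - mu
    quad = (var_y * dx**2 - 2.0 * cov * dx * dy + var_x * dy**2) / det
    return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


def log_marginal_likelihoods(x_v, x_c, sigma_v, params: PieceParams):
    """Log evidence of the cues under the unperturbed and perturbed causes.

    Marginalizing the latent hand position (prior N(b, sigma_h^2)) and, in
    the perturbed branch, the rotation (prior N(0, sigma_r^2)) analytically
    leaves bivariate Gaussians over (x_v, x_c):

    - unperturbed: means (b, b), Var(x_v) = sigma_h^2 + sigma_v^2,
      Var(x_c) = sigma_h^2 + sigma_c^2, Cov = sigma_h^2 (shared hand).
    - perturbed: identical except Var(x_v) inflated by sigma_r^2.

    Returns ``(log_nopert, log_pert)``; broadcasts over array inputs.
    """
    x_v = np.asarray(x_v, dtype=float)
    x_c = np.asarray(x_c, dtype=float)
    sigma_v = np.asarray(sigma_v, dtype=float)
    if np.any(sigma_v <= 0):
        raise ParameterError("sigma_v must be strictly positive")
    vh = params.sigma_h**2
    vc = vh + params.sigma_combined**2
    vv = vh + sigma_v**2
    log_nopert = _log_bvn(x_v, x_c, params.bias_b, vv, vc, vh)
    log_pert = _log_bvn(x_v, x_c, params.bias_b, vv + params.sigma_r**2, vc, vh)
    return log_nopert, log_pert


def marginal_likelihoods(cues: CueSet, params: PieceParams):
    """Evidence densities ``(density_nopert, density_pert)`` for one cue set.

    Linear-space values are floored at 1e-300; posterior arithmetic uses
    the unfloored log densities (log-sum-exp), so extreme cues degrade
    neither normalization nor the evidence ratio.
    """
    ln, lp = log_marginal_likelihoods(cues.x_v, cues.x_c, cues.sigma_v, params)
    floor = np.exp(_LOG_FLOOR)
    return max(float(np.exp(ln)), floor), max(float(np.exp(lp)), floor)


def log_causal_posterior(x_v, x_c, sigma_v, params: PieceParams):
    """Log posterior probability of the perturbed cause (vectorized)."""
    log_nopert, log_pert = log_marginal_likelihoods(x_v, x_c, sigma_v, params)
    a = np.log(params.p_pert_prior) + log_pert
    b = np.log(params.p_nopert_prior) + log_nopert
    denom = logsumexp(np.stack([a, b]), axis=0)
    return a - denom


def causal_posterior(cues: CueSet, params: PieceParams) -> CausalPosterior:
    """Posterior belief that the feedback was perturbed, given the cues.

    Computed in log-space (log-sum-exp), so it never returns NaN even when
    both evidence terms underflow in linear space.
    """
    lp = float(log_causal_posterior(cues.x_v, cues.x_c, cues.sigma_v, params))
    p = float(np.exp(lp))
    return CausalPosterior(p_pert=p, p_nopert=1.0 - p)


def kalman_gain(sigma_v, sigma_r):
    """Precision-weighted learning rate K = (1/sv^2) / (1/sv^2 + 1/sr^2).

    Decreases with visual uncertainty, increases with the width of the
    prior over plausible rotations (environment volatility).
    """
    sigma_v = np.asarray(sigma_v, dtype=float)
    sigma_r = np.asarray(sigma_r, dtype=float)
    if np.any(sigma_v <= 0) or np.any(sigma_r <= 0):
        raise ParameterError("SDs must be strictly positive")
    out = sigma_r**2 / (sigma_r**2 + sigma_v**2)
    return float(out) if out.ndim == 0 else out


def estimate_perturbation(z, gain_K, posterior: CausalPosterior) -> PerturbationEstimate:
    """Belief-weighted perturbation estimate r_hat = p_pert * K * z.

    The unperturbed branch contributes zero by definition (r = 0 there),
    so the linear combination across causes collapses to the perturbed
    term weighted by the causal posterior.
    """
    r_hat = posterior.p_pert * gain_K * z
    return PerturbationEstimate(gain_K=float(gain_K), z=float(z), r_hat=float(r_hat))


def predict_response(
    rotation_r,
    hand_t,
    params: PieceParams,
    mode: str = "deterministic",
    rng=None,
    feedback=True,
):
    """Mean (or sample) of the next-trial reach angle after one feedback trial.

    Deterministic mode sets all cues at their experimenter-visible values:
    x_v = hand + rotation, x_c = hand, z = rotation, e = |hand + rotation|;
    residual internal-cue variability is absorbed into the sigma_h response
    noise.  Stochastic mode additionally samples x_v, x_c and z from their
    generative distributions and adds motor noise N(0, sigma_h^2).

    On feedback-absent trials there is nothing to learn from: the response
    is the bias b (plus noise in stochastic mode).  Vectorized over
    ``rotation_r`` / ``hand_t`` / ``feedback``.
    """
    rotation_r = np.asarray(rotation_r, dtype=float)
    hand_t = np.asarray(hand_t, dtype=float)
    rotation_r, hand_t = np.broadcast_arrays(rotation_r, hand_t)
    feedback = np.broadcast_to(np.asarray(feedback, dtype=bool), rotation_r.shape)

    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "stochastic" and rng is None:
        raise ValueError("stochastic mode requires an explicit rng (seed policy)")

    cursor = hand_t + rotation_r
    e = np.abs(cursor)
    sigma_v = params.alpha + params.beta * e

    if mode == "deterministic":
        x_v, x_c, z = cursor, hand_t, rotation_r
    else:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        x_v = rng.normal(cursor, sigma_v)
        x_c = rng.normal(hand_t, params.sigma_combined)
        z = rng.normal(rotation_r, sigma_v)

    p_pert = np.exp(log_causal_posterior(x_v, x_c, sigma_v, params))
    K = kalman_gain(sigma_v, params.sigma_r)
    r_hat = np.where(feedback, p_pert * K * z, 0.0)
    resp = -r_hat + params.bias_b
    if mode == "stochastic":
        resp = resp + rng.normal(0.0, params.sigma_h, size=resp.shape)
    return float(resp) if resp.ndim == 0 else resp


def posterior_curve(params: PieceParams, protocol, seed: int):
    """Mean causal posterior per rotation (EGE) level over a simulated run.

    Simulates one participant on ``protocol`` (a schedule DataFrame from
    :mod:`piece.protocol`), records p(pert | cues) on every measured trial
    and aggregates by rotation level.  Returns a DataFrame with columns
    ``ege`` and ``mean_p_pert``.
    """
    import pandas as pd

    from .protocol import simulate_participant

    trials = simulate_participant("PIECE", params, protocol, seed=seed)
    m = trials[(trials["trial_type"] == "measured") & (trials["feedback"] == "full")]
    p_pert = np.exp(
        log_causal_posterior(
            m["hand_angle_deg"].to_numpy() + m["rotation_deg"].to_numpy(),
            m["hand_angle_deg"].to_numpy(),
            params.alpha
            + params.beta * np.abs(m["hand_angle_deg"].to_numpy() + m["rotation_deg"].to_numpy()),
            params,
        )
    )
    out = (
        pd.DataFrame({"ege": m["rotation_deg"].to_numpy(), "p_pert": p_pert})
        .groupby("ege", as_index=False)["p_pert"]
        .mean()
        .rename(columns={"p_pert": "mean_p_pert"})
    )
    return out


def sensitivity_sweep(params: PieceParams, rotation_grid):
    """Deterministic adaptation -r_hat(r) across a grid of rotation sizes.

    Evaluated at hand_t = b (a typical unbiased reach).  With a rising
    visual-uncertainty function the learning rate falls with |r|, so the
    adaptive response saturates — and can become non-monotonic — as the
    perturbation grows.  Returns a DataFrame with columns ``rotation`` and
    ``adaptation``.
    """
    import pandas as pd

    grid = np.asarray(rotation_grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("rotation grid must be finite")
    resp = predict_response(grid, np.full_like(grid, params.bias_b), params)
    return pd.DataFrame({"rotation": grid, "adaptation": np.asarray(resp) - params.bias_b})
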