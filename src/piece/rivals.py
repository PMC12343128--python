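"""Hand-to-target alignment models of implicit adaptation: PReMo, PEA, REM.

All three frame adaptation as re-aligning the (perceived or estimated)
hand position with the movement goal.  Their single-trial error signal
therefore contains the hand angle itself, so — unlike PIECE — they predict
adaptation in response to internally generated error (motor noise) even on
unperturbed trials.  That structural property, not any particular
parameter value, is what the model comparison discriminates.

Each model is exposed as a deterministic single-trial predictor
``*_predict(rotation, hand, params) -> mean next-trial reach angle`` with
the same signature and response-noise convention as the PIECE observer,
so the simulator, fitter and recovery harness treat all four models
interchangeably.

The forms below are the canonical published single-trial versions,
restricted to what a randomized (memoryless) perturbation schedule can
identify, with free-parameter counts 6 (PReMo), 3 (PEA) and 4 (REM):

- PReMo: sequential saturating recalibration.  The perceived cursor is
  drawn toward the predicted hand (the motor goal) by a capped visual
  shift; the felt hand is drawn toward that perceived cursor by a capped
  proprioceptive shift; adaptation is proportional to the felt-hand error.
- PEA: optimal (precision-weighted) fusion of the visual cue at the
  cursor, the proprioceptive cue at the hand, and a motor prediction
  centred on the goal, with the same error-dependent visual uncertainty
  sigma_v(e) = alpha + beta*e as PIECE; adaptation cancels the perceived
  hand position.
- REM: causal inference over whether the visual error is relevant to the
  hand (narrow Gaussian) or an irrelevant outlier (broad uniform);
  adaptation corrects a learning-rate-scaled, relevance-weighted share of
  the cursor-to-target error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import PeaParams, PremoParams, RemParams

__all__ = ["premo_predict", "pea_predict", "rem_predict", "rem_relevance", "rival_predict", "rival_simulate"]


def _clip_shift(x, cap):
    """Saturating shift: linear up to ±cap, constant beyond."""
    return np.clip(x, -cap, cap)


def premo_predict(rotation_r, hand_t, params: PremoParams):
    """PReMo mean next-trial reach after one feedback trial.

    Sequential saturating recalibration with the saturation applied to the
    cross-sensory discrepancies (the canonical form): the perceived cursor
    is shifted toward the predicted hand (at the goal) by beta_v times the
    goal-to-cursor discrepancy clipped at ±gamma_v, the felt hand is
    shifted toward that perceived cursor by beta_p times the clipped
    cursor-to-hand discrepancy (±gamma_p), and the response cancels an
    eta-scaled share of the felt-hand error:

        c_hat = c + beta_v * clip(0 - c, ±gamma_v),        c = hand + r
        p_hat = hand + beta_p * clip(c_hat - hand, ±gamma_p)
        mean  = -eta * p_hat + b
    """
    if not isinstance(params, PremoParams):
        raise TypeError("premo_predict requires PremoParams")
    rotation_r = np.asarray(rotation_r, dtype=float)
    hand_t = np.asarray(hand_t, dtype=float)
    cursor = hand_t + rotation_r
    c_hat = cursor + params.beta_v * _clip_shift(0.0 - cursor, params.gamma_v)
    p_hat = hand_t + params.beta_p * _clip_shift(c_hat - hand_t, params.gamma_p)
    out = -params.eta * p_hat + params.bias_b
    return float(out) if out.ndim == 0 else out


def pea_predict(rotation_r, hand_t, params: PeaParams):
    """PEA mean next-trial reach after one feedback trial.

    The perceived hand is the precision-weighted average of the cursor
    (visual, SD alpha + beta*|cursor|), the true hand (proprioception,
    SD sigma_p) and the goal (motor prediction, SD sigma_u); the response
    cancels it: mean = -perceived_hand + b.
    """
    if not isinstance(params, PeaParams):
        raise TypeError("pea_predict requires PeaParams")
    rotation_r = np.asarray(rotation_r, dtype=float)
    hand_t = np.asarray(hand_t, dtype=float)
    cursor = hand_t + rotation_r
    sigma_v = params.alpha + params.beta * np.abs(cursor)
    w_v = 1.0 / sigma_v**2
    w_p = 1.0 / params.sigma_p**2
    w_u = 1.0 / params.sigma_u**2
    perceived = (w_v * cursor + w_p * hand_t + w_u * 0.0) / (w_v + w_p + w_u)
    out = -perceived + params.bias_b
    return float(out) if out.ndim == 0 else out


def rem_relevance(error, params: RemParams):
    """Posterior probability that a visual error is relevant to the hand.

    Relevant errors follow N(0, sigma_rel^2) (the scale of self-generated
    errors); irrelevant ones are uniform over ±irrelevant_halfwidth.
    Relevance declines monotonically for implausibly large errors.
    """
    error = np.asarray(error, dtype=float)
    dens_rel = np.exp(-0.5 * (error / params.sigma_rel) ** 2) / (
        np.sqrt(2.0 * np.pi) * params.sigma_rel
    )
    dens_irr = 1.0 / (2.0 * params.irrelevant_halfwidth)
    num = params.p_rel * dens_rel
    out = num / (num + (1.0 - params.p_rel) * dens_irr)
    return float(out) if out.ndim == 0 else out


def rem_predict(rotation_r, hand_t, params: RemParams):
    """REM mean next-trial reach after one feedback trial.

    The cursor-to-target error is corrected in proportion to the learning
    rate and its inferred relevance: mean = -eta * w(error) * error + b.
    """
    if not isinstance(params, RemParams):
        raise TypeError("rem_predict requires RemParams")
    rotation_r = np.asarray(rotation_r, dtype=float)
    hand_t = np.asarray(hand_t, dtype=float)
    error = hand_t + rotation_r
    out = -params.eta * rem_relevance(error, params) * error + params.bias_b
    return float(out) if out.ndim == 0 else out


_PREDICTORS = {"PReMo": premo_predict, "PEA": pea_predict, "REM": rem_predict}


def rival_predict(model: str, rotation_r, hand_t, params):
    """Dispatch to the named rival model's single-trial predictor."""
    try:
        fn = _PREDICTORS[model]
    except KeyError:
        raise ValueError(f"unknown rival model {model!r}; expected one of {tuple(_PREDICTORS)}")
    return fn(rotation_r, hand_t, params)


def rival_simulate(model: str, params, protocol: pd.DataFrame, seed: int,
                   participant_id: str = "S01") -> pd.DataFrame:
    """Trial-by-trial simulation of a rival model over a schedule.

    Thin wrapper over :func:`piece.protocol.simulate_participant` kept for
    symmetry with the PIECE observer's simulation entry point.
    """
    from .protocol import simulate_participant

    return simulate_participant(model, params, protocol, seed=seed,
                                participant_id=participant_id)
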