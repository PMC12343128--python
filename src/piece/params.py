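"""Parameter containers for the PIECE observer and the rival adaptation models.

All angles are in degrees, counter-clockwise positive, with the target at 0°.
The cursor angle on a perturbed trial is hand angle + rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import ClassVar, Mapping


class ParameterError(ValueError):
    """Raised when a model parameter violates its domain constraint."""


@dataclass(frozen=True)
class PieceParams:
    """Parameters of the PIECE causal-inference observer.

    Free parameters (fitted per participant): ``sigma_r``, ``bias_b``,
    ``sigma_combined``.  ``sigma_h`` is the participant's intrinsic motor
    variability, measured from baseline reaches and held fixed during
    fitting; ``alpha``/``beta`` define the error-dependent visual
    uncertainty sigma_v(e) = alpha + beta*e and are likewise fixed.

    Attributes
    ----------
    sigma_r : float
        SD (deg) of the observer's zero-mean Gaussian prior on the
        rotation magnitude — the range of perturbations deemed plausible.
    bias_b : float
        Intrinsic directional reach bias (deg) relative to the target.
    sigma_combined : float
        SD (deg) of the fused proprioceptive + motor-prediction cue, both
        centred on the true hand position and experimentally inseparable.
    sigma_h : float
        Intrinsic motor variability (deg); fixed from baseline, not fitted.
    alpha, beta : float
        Intercept (deg) and slope (dimensionless) of the visual
        uncertainty function. Defaults are documented placeholders, not
        the empirical psychophysical estimates they stand in for.
    p_pert_prior : float
        Prior probability that the feedback was perturbed; the task
        statistics make it flat (0.5).
    """

    sigma_r: float = 3.0
    bias_b: float = 0.5
    sigma_combined: float = 1.0
    sigma_h: float = 2.5
    alpha: float = 1.0
    beta: float = 0.1
    p_pert_prior: float = 0.5

    # names of the free parameters, in fit order; sigma_h/alpha/beta are fixed
    FREE: ClassVar[tuple] = ("sigma_r", "bias_b", "sigma_combined")

    def __post_init__(self):
        for name in ("sigma_r", "sigma_combined", "sigma_h"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ParameterError("alpha and beta cannot both be zero")
        if not 0 < self.p_pert_prior < 1:
            raise ParameterError("p_pert_prior must lie in (0, 1)")

    @property
    def p_nopert_prior(self) -> float:
        return 1.0 - self.p_pert_prior

    def with_free(self, values) -> "PieceParams":
        """Return a copy with the free parameters replaced (fit order)."""
        return replace(self, **dict(zip(self.FREE, map(float, values))))

    def free_values(self):
        return tuple(getattr(self, name) for name in self.FREE)

    def asdict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def combine_internal_cues(sigma_u: float, sigma_p: float) -> float:
    """SD of the product of the motor-prediction and proprioceptive cues.

    Both cues are Gaussian and centred on the true hand position, so their
    fusion is Gaussian with variance sigma_u^2 sigma_p^2/(sigma_u^2+sigma_p^2).
    """
    if sigma_u <= 0 or sigma_p <= 0:
        raise ParameterError("cue SDs must be strictly positive")
    return float((sigma_u**2 * sigma_p**2 / (sigma_u**2 + sigma_p**2)) ** 0.5)


@dataclass(frozen=True)
class PremoParams:
    """Proprioceptive Re-alignment Model (PReMo) parameters — 6 free.

    The perceived cursor is shifted toward the motor goal by a saturating
    visual shift, the felt hand is shifted toward that perceived cursor by
    a saturating proprioceptive shift, and adaptation is proportional to
    the felt-hand-to-goal misalignment.
    """

    beta_v: float = 0.9     # visual shift rate toward the predicted hand
    gamma_v: float = 1.0    # visual-discrepancy saturation (deg)
    beta_p: float = 0.8     # proprioceptive shift rate toward the cursor
    gamma_p: float = 1.5    # proprioceptive-discrepancy saturation (deg)
    eta: float = 1.2        # adaptation rate on perceived hand error
    bias_b: float = 0.5     # intrinsic reach bias (deg)
    sigma_h: float = 2.5    # fixed response noise SD (deg), as in PIECE

    FREE: ClassVar[tuple] = ("beta_v", "gamma_v", "beta_p", "gamma_p", "eta", "bias_b")

    def __post_init__(self):
        if self.gamma_v <= 0 or self.gamma_p <= 0:
            raise ParameterError("saturation limits must be positive")
        if self.beta_v < 0 or self.beta_p < 0 or self.eta < 0:
            raise ParameterError("rates must be non-negative")
        if self.sigma_h <= 0:
            raise ParameterError("sigma_h must be strictly positive")

    def with_free(self, values):
        return replace(self, **dict(zip(self.FREE, map(float, values))))

    def free_values(self):
        return tuple(getattr(self, name) for name in self.FREE)


@dataclass(frozen=True)
class PeaParams:
    """Perceptual Error Adaptation model (PEA) parameters — 3 free.

    The perceived hand is the precision-weighted fusion of the visual cue
    (at the cursor, with sigma_v(e) = alpha + beta*e shared with PIECE),
    the proprioceptive cue (at the true hand) and a motor prediction
    centred on the motor goal. Adaptation cancels the perceived hand error.
    """

    sigma_p: float = 2.0    # proprioceptive SD (deg)
    sigma_u: float = 2.6    # motor-prediction SD (deg), cue centred on goal
    bias_b: float = 0.5
    sigma_h: float = 2.5
    alpha: float = 1.0      # shared visual-uncertainty intercept (deg)
    beta: float = 0.1       # shared visual-uncertainty slope

    FREE: ClassVar[tuple] = ("sigma_p", "sigma_u", "bias_b")

    def __post_init__(self):
        for name in ("sigma_p", "sigma_u", "sigma_h"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be non-negative")

    def with_free(self, values):
        return replace(self, **dict(zip(self.FREE, map(float, values))))

    def free_values(self):
        return tuple(getattr(self, name) for name in self.FREE)


@dataclass(frozen=True)
class RemParams:
    """Relevance Estimation Model (REM) parameters — 4 free.

    The observer infers whether the cursor-to-target error is relevant to
    the hand (drawn from the narrow distribution of self-generated errors)
    or irrelevant (a broad outlier distribution); adaptation corrects a
    learning-rate-scaled, relevance-weighted share of the error.
    """

    eta: float = 0.7        # learning rate
    sigma_rel: float = 2.0  # SD (deg) of errors deemed relevant
    p_rel: float = 0.6      # prior probability the error is relevant
    bias_b: float = 0.5
    sigma_h: float = 2.5
    irrelevant_halfwidth: float = 90.0  # uniform outlier model, fixed

    FREE: ClassVar[tuple] = ("eta", "sigma_rel", "p_rel", "bias_b")

    def __post_init__(self):
        if self.sigma_rel <= 0 or self.sigma_h <= 0:
            raise ParameterError("SDs must be strictly positive")
        if not 0 < self.p_rel < 1:
            raise ParameterError("p_rel must lie in (0, 1)")
        if self.eta < 0:
            raise ParameterError("eta must be non-negative")

    def with_free(self, values):
        return replace(self, **dict(zip(self.FREE, map(float, values))))

    def free_values(self):
        return tuple(getattr(self, name) for name in self.FREE)


#: number of free parameters per model, used for BIC
N_FREE: Mapping[str, int] = {"PIECE": 3, "PReMo": 6, "PEA": 3, "REM": 4}

PARAM_CLASSES = {
    "PIECE": PieceParams,
    "PReMo": PremoParams,
    "PEA": PeaParams,
    "REM": RemParams,
}
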