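"""Experimental schedule generation and synthetic-participant simulation.

The paradigm: a baseline block of 70 unperturbed (null) reaches with
veridical feedback, then 18 main blocks of 100 trials in which small
visuomotor rotations of 0, ±2 or ±4 degrees (100 trials per level) are
embedded among null trials so that every rotation trial is immediately
preceded and followed by a null trial.  Half of the main-phase null
trials, chosen at random, carry no visual feedback.  Rotation order is
randomized under the flanking-null constraint.

Because the rotations are randomized and small, the single-trial adaptive
response to a rotation is expressed on the immediately following null
trial and — under the no-memory assumption — decays completely thereafter,
which is what makes the triplet analysis in :mod:`piece.triplets` valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import predict_response
from .rivals import rival_predict

MODELS = ("PIECE", "PReMo", "PEA", "REM")

SCHEDULE_COLUMNS = [
    "trial_index",
    "block",
    "phase",
    "trial_type",
    "rotation_deg",
    "feedback",
    "target_jump_deg",
]


class ProtocolError(ValueError):
    """Raised when a schedule configuration is internally inconsistent."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Counts and structure of the randomized-rotation triplet paradigm."""

    n_baseline: int = 70
    n_blocks: int = 18
    block_length: int = 100
    rotation_levels: tuple = (-4.0, -2.0, 0.0, 2.0, 4.0)
    trials_per_level: int = 100
    p_feedback_absent: float = 0.5
    include_target_jumps: bool = False
    jump_levels: tuple = (-4.0, -2.0, 2.0, 4.0)
    jumps_per_level: int = 100

    @property
    def n_main(self) -> int:
        return self.n_blocks * self.block_length

    @property
    def n_measured(self) -> int:
        return len(self.rotation_levels) * self.trials_per_level

    def __post_init__(self):
        if min(self.n_baseline, self.n_blocks, self.block_length) <= 0:
            raise ProtocolError("all counts must be positive")
        if not 0 <= self.p_feedback_absent <= 1:
            raise ProtocolError("p_feedback_absent must lie in [0, 1]")


def build_protocol(config: ProtocolConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Build one randomized trial schedule.

    Rotation trials are placed at randomly chosen, mutually non-adjacent
    main-phase positions (never the first or last trial), which guarantees
    the flanking-null constraint by construction; rotation levels are then
    shuffled across those slots.  When target jumps are enabled the main
    phase strictly alternates null and measured slots and the jump trials
    (rotation 0, target displaced mid-reach) fill the slots left over by
    the rotation trials; jump trials are excluded from all analyses
    downstream.

    Returns a DataFrame with one row per trial and columns
    ``trial_index, block, phase, trial_type, rotation_deg, feedback,
    target_jump_deg``.
    """
    if seed is None:
        raise ProtocolError("an explicit seed is required")
    cfg = config or ProtocolConfig()
    rng = np.random.default_rng(seed)
    n_main = cfg.n_main
    n_rot = cfg.n_measured

    rotations = np.repeat(np.asarray(cfg.rotation_levels, dtype=float), cfg.trials_per_level)
    rng.shuffle(rotations)

    trial_type = np.full(n_main, "null", dtype=object)
    rotation = np.zeros(n_main)
    jump = np.zeros(n_main)

    if cfg.include_target_jumps:
        n_jump = len(cfg.jump_levels) * cfg.jumps_per_level
        measured_pos = np.arange(1, n_main, 2)  # strict alternation, null first
        if n_rot + n_jump > measured_pos.size:
            raise ProtocolError("too many measured trials for strict alternation")
        slots = rng.permutation(measured_pos)[: n_rot + n_jump]
        # the session-final slot (no following null) must not hold a rotation
        last = n_main - 1
        if last in slots[:n_rot]:
            i = int(np.where(slots[:n_rot] == last)[0][0])
            j = n_rot + int(np.where(slots[n_rot:] != last)[0][0])
            slots[i], slots[j] = slots[j], slots[i]
        rot_slots, jump_slots = slots[:n_rot], slots[n_rot:]
        jumps = np.repeat(np.asarray(cfg.jump_levels, dtype=float), cfg.jumps_per_level)
        rng.shuffle(jumps)
        trial_type[rot_slots] = "measured"
        rotation[rot_slots] = rotations
        trial_type[jump_slots] = "target_jump"
        jump[jump_slots] = jumps
    else:
        max_start = n_main - 2 * n_rot  # gap-method upper bound
        if max_start < 1:
            raise ProtocolError("not enough main trials for non-adjacent placement")
        # sorted draws c_1<...<c_k from [1, n_main-1-k] mapped to c_i + i
        # give strictly non-adjacent positions in [2, n_main-2].
        c = np.sort(rng.choice(np.arange(1, n_main - n_rot - 1), size=n_rot, replace=False))
        rot_slots = c + np.arange(n_rot)
        trial_type[rot_slots] = "measured"
        rotation[rot_slots] = rotations

    feedback = np.full(n_main, "full", dtype=object)
    nulls = trial_type == "null"
    feedback[nulls] = np.where(
        rng.random(nulls.sum()) < cfg.p_feedback_absent, "none", "full"
    )

    base = pd.DataFrame(
        {
            "trial_index": np.arange(cfg.n_baseline),
            "block": -1,
            "phase": "baseline",
            "trial_type": "null",
            "rotation_deg": 0.0,
            "feedback": "full",
            "target_jump_deg": 0.0,
        }
    )
    main = pd.DataFrame(
        {
            "trial_index": cfg.n_baseline + np.arange(n_main),
            "block": np.arange(n_main) // cfg.block_length,
            "phase": "main",
            "trial_type": trial_type,
            "rotation_deg": rotation,
            "feedback": feedback,
            "target_jump_deg": jump,
        }
    )
    return pd.concat([base, main], ignore_index=True)[SCHEDULE_COLUMNS]


def simulate_participant(
    model: str,
    params,
    protocol: pd.DataFrame,
    seed: int | None = None,
    participant_id: str = "S01",
    cue_mode: str = "mean",
) -> pd.DataFrame:
    """Simulate one synthetic participant reaching through a schedule.

    Every reach is drawn N(mean, sigma_h^2).  The mean is the intrinsic
    bias b except on the trial immediately following a full-feedback
    measured trial, where it is the model's single-trial response to that
    trial's (rotation, hand angle) pair.  This is the no-memory
    assumption: an update affects only the next trial and then washes
    out, so null-trial reaches otherwise revert to N(b, sigma_h^2).
    Feedback-absent and target-jump trials trigger no update.  The rival
    models' sensitivity to internally generated error is expressed
    through the 0-degree rotation trials, where their error signal —
    which contains the hand angle — is nonzero while PIECE's is not.

    ``cue_mode`` ("mean" or "sample") selects deterministic versus sampled
    internal cues for PIECE; "mean" matches the likelihood used for
    fitting.  Returns a trial table (TrialRecord rows).
    """
    if seed is None:
        raise ProtocolError("an explicit seed is required")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if cue_mode not in ("mean", "sample"):
        raise ValueError("cue_mode must be 'mean' or 'sample'")
    rng = np.random.default_rng(seed)

    n = len(protocol)
    rotation = protocol["rotation_deg"].to_numpy(dtype=float)
    feedback_full = (protocol["feedback"] == "full").to_numpy()
    measured = (protocol["trial_type"] == "measured").to_numpy()

    eps = rng.normal(0.0, params.sigma_h, size=n)
    hand = params.bias_b + eps  # provisional: reaches with no preceding update

    # Measured trials are never adjacent, so every update can be computed
    # from the provisional (pre-update) reach of its own trial.
    idx = np.flatnonzero(measured & feedback_full)
    idx = idx[idx < n - 1]
    if idx.size:
        if model == "PIECE":
            if cue_mode == "sample":
                # stochastic mode samples the cues and the motor noise draw
                hand[idx + 1] = predict_response(
                    rotation[idx], hand[idx], params, mode="stochastic", rng=rng
                )
            else:
                hand[idx + 1] = predict_response(rotation[idx], hand[idx], params) + eps[idx + 1]
        else:
            hand[idx + 1] = rival_predict(model, rotation[idx], hand[idx], params) + eps[idx + 1]

    out = protocol.copy()
    out.insert(0, "participant_id", participant_id)
    out["hand_angle_deg"] = hand
    out["cursor_angle_deg"] = np.where(feedback_full, hand + rotation, np.nan)
    out["excluded"] = False
    return out


def baseline_sigma(trials: pd.DataFrame, n_last: int = 50) -> float:
    """Intrinsic motor variability: sample SD of the last baseline reaches.

    Uses the final ``n_last`` baseline-phase hand angles (ddof=1).
    """
    base = trials[trials["phase"] == "baseline"]
    if len(base) < n_last:
        raise ValueError(f"need at least {n_last} baseline trials, found {len(base)}")
    tail = base.sort_values("trial_index").tail(n_last)
    return float(np.std(tail["hand_angle_deg"].to_numpy(), ddof=1))
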